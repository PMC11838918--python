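"""Expression integration: DE, group tests, sensitive sets, quartile trends."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import anova_f_direct, wilcoxon_exact_p
from slamkinetics.integrate import (
    characterize_sensitive_sets,
    compare_halflife_groups,
    foldchange_by_optimality_quartile,
    multi_group_halflife_test,
    prefilter_counts,
    read_de_table,
    simplified_de,
)
from slamkinetics.synthetic import simulate_expression


class TestPrefilter:
    def test_strict_threshold(self):
        counts = pd.DataFrame({"a": [11, 10], "b": [11, 50]},
                              index=["keep", "drop"])
        out = prefilter_counts(counts, 10)
        assert out.index.tolist() == ["keep"]

    def test_empty_result_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [1]}, index=["g"])
        with pytest.raises(ValueError):
            prefilter_counts(counts, 10)


@pytest.fixture(scope="module")
def de_run():
    counts, samples, truth = simulate_expression(
        2000, frac_up=0.05, frac_down=0.05, fold=4.0, dispersion=0.05, seed=17)
    counts = prefilter_counts(counts, 10)
    de = simplified_de(counts, samples, "s0", "s1")
    return counts, samples, truth, de


class TestSimplifiedDe:
    def test_identical_conditions_call_nothing(self):
        rng = np.random.default_rng(18)
        base = rng.poisson(100, size=(50, 2))
        counts = pd.DataFrame(np.hstack([base, base]),
                              columns=["a1", "a2", "b1", "b2"],
                              index=[f"g{i}" for i in range(50)])
        samples = pd.DataFrame({"sample": ["a1", "a2", "b1", "b2"],
                                "stage": ["A", "A", "B", "B"],
                                "replicate": [1, 2, 1, 2]})
        de = simplified_de(counts, samples, "A", "B")
        assert (de["direction"] == "ns").all()
        assert np.allclose(de["log2fc"], 0.0)

    def test_planted_genes_recovered_in_correct_direction(self, de_run):
        counts, _, truth, de = de_run
        m = de.merge(truth, on="gene")
        planted = m[m["direction_y"] != "none"]
        recovery = (planted["direction_x"] == planted["direction_y"]).mean()
        assert recovery >= 0.90

    def test_size_factor_invariance_to_sample_scaling(self, de_run):
        counts, samples, _, de = de_run
        scaled = counts.copy()
        scaled[scaled.columns[0]] = scaled[scaled.columns[0]] * 10
        de2 = simplified_de(scaled, samples, "s0", "s1")
        assert (de["direction"] == de2["direction"]).all()
        # size factors absorb the scaling up to the pseudocount's influence
        # on low-count genes, so fold changes agree loosely, calls exactly
        assert np.allclose(de["log2fc"], de2["log2fc"], atol=0.1)

    def test_direction_antisymmetry_under_condition_swap(self, de_run):
        counts, samples, _, de = de_run
        swapped = simplified_de(counts, samples, "s1", "s0")
        assert np.allclose(de["log2fc"], -swapped["log2fc"], atol=1e-9)
        assert (de["direction"] == "up").sum() == (swapped["direction"] == "down").sum()
        up = set(de.loc[de["direction"] == "up", "gene"])
        down_sw = set(swapped.loc[swapped["direction"] == "down", "gene"])
        assert up == down_sw

    def test_too_few_replicates_rejected(self):
        counts = pd.DataFrame({"a1": [10], "b1": [10], "b2": [12]}, index=["g"])
        samples = pd.DataFrame({"sample": ["a1", "b1", "b2"],
                                "stage": ["A", "B", "B"], "replicate": [1, 1, 2]})
        with pytest.raises(ValueError):
            simplified_de(counts, samples, "A", "B")


class TestDeImporter:
    def test_round_trip_with_direction(self, tmp_path):
        df = pd.DataFrame({"gene": ["g1", "g2", "g3"],
                           "log2fc": [2.0, -2.0, 0.1],
                           "padj": [0.001, 0.001, 0.9]})
        path = tmp_path / "de.tsv"
        df.to_csv(path, sep="\t", index=False)
        out = read_de_table(path)
        assert out["direction"].tolist() == ["up", "down", "ns"]


class TestRankSum:
    def test_identical_groups(self):
        res = compare_halflife_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert res["p"] == pytest.approx(1.0)
        assert res["median_a"] == res["median_b"]

    def test_large_shift_significant(self):
        rng = np.random.default_rng(19)
        a = rng.normal(5, 1, 200)
        b = a + 2.0
        assert compare_halflife_groups(a, b)["p"] < 1e-6

    def test_matches_exhaustive_enumeration(self):
        """Exact rank-sum p equals brute-force enumeration over C(10,5) labelings."""
        rng = np.random.default_rng(20)
        for _ in range(5):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.8, 1, 5)
            res = compare_halflife_groups(a, b)
            assert res["p"] == pytest.approx(wilcoxon_exact_p(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_halflife_groups([], [1.0])


class TestAnovaTukey:
    def test_identical_groups_flat(self):
        g = [1.0, 1.1, 0.9, 1.05]
        res = multi_group_halflife_test({"a": g, "b": g, "c": g})
        assert res["F"] == pytest.approx(0.0, abs=1e-10)
        assert (res["pairwise"]["reject"] == False).all()  # noqa: E712

    def test_f_matches_direct_sum_of_squares(self):
        rng = np.random.default_rng(21)
        groups = {"a": rng.normal(1, 0.1, 30), "b": rng.normal(1, 0.1, 30),
                  "c": rng.normal(5, 0.1, 30)}
        res = multi_group_halflife_test(groups)
        assert res["F"] == pytest.approx(anova_f_direct(groups.values()), rel=1e-10)
        pw = res["pairwise"].set_index(["group1", "group2"])
        assert pw.loc[("a", "c"), "reject"]
        assert not pw.loc[("a", "b"), "reject"]

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            multi_group_halflife_test({"a": [1.0], "b": [1, 2], "c": [1, 2]})


class TestSensitiveSets:
    def _de(self, directions):
        return pd.DataFrame({"gene": list(directions), "log2fc": 0.0,
                             "p": 1.0, "padj": 1.0,
                             "direction": list(directions.values())})

    def test_identical_contrasts_fully_overlap(self):
        directions = {f"g{i}": d for i, d in
                      enumerate(["up"] * 5 + ["down"] * 5 + ["ns"] * 10)}
        de = self._de(directions)
        expr = pd.Series(100.0, index=list(directions))
        opt = pd.Series(np.linspace(10, 90, 20), index=list(directions))
        summary = characterize_sensitive_sets(de, de, expr, opt)
        assert summary.shared_up == {g for g, d in directions.items() if d == "up"}
        assert summary.shared_down == {g for g, d in directions.items() if d == "down"}

    def test_disjoint_calls_give_empty_shared_sets(self):
        a = self._de({"g1": "up", "g2": "ns"})
        b = self._de({"g1": "ns", "g2": "up"})
        expr = pd.Series(1.0, index=["g1", "g2"])
        opt = pd.Series([1.0, 2.0], index=["g1", "g2"])
        with pytest.raises(ValueError):
            # too-small groups for the ANOVA: empty shared sets surface as errors
            characterize_sensitive_sets(a, b, expr, opt)

    def test_stratified_planting_detected(self):
        """Up-genes drawn from the low-expression, low-optimality stratum."""
        rng = np.random.default_rng(22)
        n = 600
        genes = [f"g{i:03d}" for i in range(n)]
        expr = pd.Series(rng.lognormal(np.log(200), 0.3, n), index=genes)
        opt = pd.Series(rng.normal(50, 8, n), index=genes)
        low_strata = expr.sort_values().index[:100]
        high_strata = expr.sort_values().index[-100:]
        up_genes = set(rng.choice(low_strata, 40, replace=False))
        down_genes = set(rng.choice(high_strata, 40, replace=False))
        opt[list(up_genes)] -= 15   # planted up genes are less optimal
        opt[list(down_genes)] += 15
        directions = {g: ("up" if g in up_genes else
                          "down" if g in down_genes else "ns") for g in genes}
        de = self._de(directions)
        summary = characterize_sensitive_sets(de, de, expr, opt)
        assert summary.expression_test["p"] < 0.001
        assert summary.optimality_test["p"] < 0.001
        assert np.median(summary.expression_groups["up"]) < \
            np.median(summary.expression_groups["ns"])
        assert np.median(summary.optimality_groups["up"]) < \
            np.median(summary.optimality_groups["ns"])


class TestQuartileFoldChange:
    def test_flat_fold_changes_flat_trend(self):
        genes = [f"g{i:02d}" for i in range(40)]
        de = pd.DataFrame({"gene": genes, "log2fc": 0.0, "p": 1.0, "padj": 1.0,
                           "direction": "ns"})
        quart = pd.Series(np.repeat([1, 2, 3, 4], 10), index=genes)
        res = foldchange_by_optimality_quartile(de, quart)
        assert all(m == 0.0 for m in res["medians"].values())

    def test_optimality_coupled_perturbation_gives_decreasing_trend(self):
        """Least-optimal quartile most up-regulated: medians fall from Q1 to Q4."""
        rng = np.random.default_rng(23)
        genes = [f"g{i:03d}" for i in range(400)]
        quart = pd.Series(np.repeat([1, 2, 3, 4], 100), index=genes)
        lfc = {1: 1.5, 2: 0.8, 3: 0.2, 4: -0.5}
        de = pd.DataFrame({
            "gene": genes,
            "log2fc": [lfc[q] + rng.normal(0, 0.2) for q in quart],
            "p": 1.0, "padj": 1.0, "direction": "ns",
        })
        res = foldchange_by_optimality_quartile(de, quart)
        meds = [res["medians"][b] for b in (1, 2, 3, 4)]
        assert all(m1 > m2 for m1, m2 in zip(meds, meds[1:]))
        assert res["trend_rho"] == pytest.approx(-1.0)

    def test_quartile_occupancy_near_equal(self):
        from slamkinetics.codons import quartile_bins

        values = pd.Series(np.arange(101, dtype=float),
                           index=[f"g{i:03d}" for i in range(101)])
        sizes = quartile_bins(values).value_counts()
        assert sizes.max() - sizes.min() <= 1
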