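"""Half-life estimation: rates, scaling, decay fits, QC and replicate logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import grid_search_decay_k, qc_rules
from slamkinetics.halflife import (
    LN2,
    QCThresholds,
    apply_qc,
    compute_conversion_rates,
    fit_decay,
    fit_halflives,
    intersect_replicates,
    scale_to_t0,
    summarize_gene_halflife,
)


def _counts(rows):
    return pd.DataFrame(rows, columns=["gene", "replicate", "stage", "time_h",
                                       "covered_T", "converted_T"])


class TestConversionRates:
    def test_direct_ratio_and_zero(self):
        counts = _counts([("g1", 1, "S", 0.0, 1000, 50),
                          ("g1", 1, "S", 2.0, 1000, 0)])
        rates = compute_conversion_rates(counts)["rate"].tolist()
        assert rates == [0.05, 0.0]

    def test_converted_exceeding_covered_rejected(self):
        counts = _counts([("g1", 1, "S", 0.0, 50, 60)])
        with pytest.raises(ValueError, match="converted_T exceeds covered_T"):
            compute_conversion_rates(counts)

    def test_zero_coverage_gives_missing_rate(self):
        counts = _counts([("g1", 1, "S", 0.0, 0, 0)])
        assert np.isnan(compute_conversion_rates(counts)["rate"]).all()


class TestScaleToT0:
    def test_scaled_profile(self):
        counts = _counts([("g1", 1, "S", 0.0, 1000, 50),
                          ("g1", 1, "S", 2.0, 1000, 25),
                          ("g1", 1, "S", 4.0, 2000, 25)])
        scaled = scale_to_t0(compute_conversion_rates(counts))
        assert np.allclose(scaled["scaled_rate"], [1.0, 0.5, 0.25])

    def test_constant_rates_scale_to_one(self):
        counts = _counts([("g1", 1, "S", t, 1000, 40) for t in (0.0, 2.0, 4.0)])
        scaled = scale_to_t0(compute_conversion_rates(counts))
        assert np.allclose(scaled["scaled_rate"], 1.0)

    def test_zero_t0_rate_flagged_unfittable(self):
        counts = _counts([("g1", 1, "S", 0.0, 1000, 0),
                          ("g1", 1, "S", 2.0, 1000, 25),
                          ("g1", 1, "S", 4.0, 1000, 10)])
        scaled = scale_to_t0(compute_conversion_rates(counts))
        assert scaled["scaled_rate"].isna().all()
        fits = fit_halflives(counts)
        assert not fits["converged"].iloc[0]


class TestFitDecay:
    def test_noiseless_exponential_recovered_exactly(self):
        t = np.array([0.0, 2.0, 4.0, 8.0, 12.0])
        fit = fit_decay(t, np.exp(-0.1 * t))
        assert abs(fit["k_per_h"] - 0.1) < 1e-6
        assert abs(fit["half_life_h"] - LN2 / 0.1) < 1e-4
        assert fit["r_squared"] > 1 - 1e-12

    def test_flat_profile_diverges(self):
        t = np.array([0.0, 2.0, 4.0, 8.0, 12.0])
        fit = fit_decay(t, np.ones_like(t))
        assert abs(fit["k_per_h"]) < 1e-3
        assert not (0 < fit["half_life_h"] < 24)

    def test_matches_grid_search_oracle_on_binomial_counts(self):
        # coverage 10,000, true half-life 4 h
        rng = np.random.default_rng(21)
        t = np.array([0.0, 2.0, 4.0, 8.0, 12.0])
        k_true = LN2 / 4.0
        covered = rng.poisson(10_000, size=t.size)
        converted = rng.binomial(covered, 0.05 * np.exp(-k_true * t))
        rate = converted / covered
        y = rate / rate[0]
        fit = fit_decay(t, y)
        assert abs(fit["half_life_h"] - 4.0) / 4.0 < 0.05
        k_grid = grid_search_decay_k(t, y)
        assert abs(fit["k_per_h"] - k_grid) < 1e-3

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_decay([0.0, 2.0], [1.0, 0.5])

    @given(scale=st.floats(min_value=0.1, max_value=10.0),
           k=st.floats(min_value=0.02, max_value=1.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance_of_raw_rates(self, scale, k):
        """Multiplying raw rates by a constant leaves k unchanged (t0 scaling)."""
        t = np.array([0.0, 2.0, 4.0, 8.0, 12.0])
        raw = 0.05 * np.exp(-k * t)
        fit1 = fit_decay(t, raw / raw[0])
        raw2 = raw * scale
        fit2 = fit_decay(t, raw2 / raw2[0])
        assert abs(fit1["k_per_h"] - fit2["k_per_h"]) < 1e-9


class TestQC:
    def _fit_row(self, min_cov, hl, r2):
        return pd.DataFrame([{"gene": "g1", "replicate": 1, "stage": "S",
                              "min_coverage": min_cov,
                              "k_per_h": LN2 / hl if np.isfinite(hl) and hl > 0 else 0.0,
                              "half_life_h": hl, "r_squared": r2,
                              "converged": True}])

    @pytest.mark.parametrize("min_cov,hl,r2,expected", [
        (501, 5.0, 0.9, True),
        (500, 5.0, 0.9, False),    # coverage boundary is strict
        (501, 5.0, 0.6, False),    # R² boundary is strict
        (501, 5.0, 0.601, True),
        (501, 24.0, 0.9, False),   # half-life upper bound is strict
        (501, 23.9, 0.9, True),
        (501, np.inf, 0.9, False),
        (501, -1.0, 0.9, False),
    ])
    def test_boundaries_match_independent_rule_evaluator(self, min_cov, hl, r2, expected):
        out = apply_qc(self._fit_row(min_cov, hl, r2))
        assert bool(out["qc_pass"].iloc[0]) is expected
        assert qc_rules(min_cov, hl, r2) is expected

    def test_failure_reasons_enumerated(self):
        out = apply_qc(self._fit_row(400, 30.0, 0.5))
        reasons = out["fail_reasons"].iloc[0]
        assert "low_coverage" in reasons
        assert "halflife_out_of_range" in reasons
        assert "low_r_squared" in reasons

    def test_raising_coverage_threshold_never_admits_a_gene(self):
        rng = np.random.default_rng(31)
        fits = pd.DataFrame({
            "gene": [f"g{i}" for i in range(200)],
            "replicate": 1, "stage": "S",
            "min_coverage": rng.integers(300, 800, 200),
            "half_life_h": rng.uniform(0.5, 30, 200),
            "r_squared": rng.uniform(0.3, 1.0, 200),
            "converged": True,
        })
        fits["k_per_h"] = LN2 / fits["half_life_h"]
        loose = apply_qc(fits, QCThresholds(min_coverage=400))
        strict = apply_qc(fits, QCThresholds(min_coverage=600))
        assert not (strict["qc_pass"] & ~loose["qc_pass"]).any()


class TestReplicateIntersection:
    def _three_rep_fits(self, pass_pattern):
        rows = []
        for rep, ok in enumerate(pass_pattern, start=1):
            rows.append({"gene": "g1", "replicate": rep, "stage": "S",
                         "min_coverage": 900, "k_per_h": 0.2,
                         "half_life_h": 4.0 if ok else 30.0,
                         "r_squared": 0.9, "converged": True})
        return apply_qc(pd.DataFrame(rows))

    def test_pass_in_all_replicates_retained(self):
        retained = intersect_replicates(self._three_rep_fits([True, True, True]))
        assert retained["S"] == {"g1"}

    def test_pass_in_two_of_three_dropped(self):
        retained = intersect_replicates(self._three_rep_fits([True, True, False]))
        assert retained["S"] == set()

    def test_requiring_more_replicates_than_available_rejected(self):
        with pytest.raises(ValueError):
            intersect_replicates(self._three_rep_fits([True, True, True]),
                                 required_replicates=4)

    def test_retained_set_matches_bruteforce_rules(self, slam_recovery_run):
        _, counts, _, fits = slam_recovery_run
        retained = intersect_replicates(fits)
        # independent recomputation: evaluate the three rules per replicate row
        by_gene = {}
        for _, row in fits.iterrows():
            ok = qc_rules(row["min_coverage"], row["half_life_h"], row["r_squared"]) \
                and row["converged"]
            by_gene.setdefault(row["gene"], []).append(ok)
        expected = {g for g, oks in by_gene.items() if len(oks) == 3 and all(oks)}
        assert retained["E11.5"] == expected


class TestSummary:
    def _fits(self, halflives):
        rows = [{"gene": "g1", "replicate": r, "stage": "S", "min_coverage": 900,
                 "k_per_h": LN2 / h, "half_life_h": h, "r_squared": 0.95,
                 "converged": True} for r, h in enumerate(halflives, start=1)]
        return apply_qc(pd.DataFrame(rows))

    @pytest.mark.parametrize("values,agg,expected", [
        ((4.0, 4.0, 4.0), "mean", 4.0),
        ((2.0, 4.0, 6.0), "mean", 4.0),
        ((2.0, 4.0, 6.0), "median", 4.0),
    ])
    def test_aggregators(self, values, agg, expected):
        out = summarize_gene_halflife(self._fits(values), aggregator=agg)
        assert out["half_life_h"].iloc[0] == pytest.approx(expected)

    def test_no_passing_replicates_rejected(self):
        fits = self._fits((30.0, 30.0, 30.0))  # all fail the 24 h rule
        with pytest.raises(ValueError):
            summarize_gene_halflife(fits)


class TestParameterRecovery:
    def test_spearman_and_relative_error(self, slam_recovery_run):
        """True vs estimated half-lives agree among QC-passing genes."""
        from scipy.stats import spearmanr

        _, _, truth, fits = slam_recovery_run
        retained = intersect_replicates(fits)["E11.5"]
        summary = summarize_gene_halflife(fits)
        est = summary[summary["gene"].isin(retained)].set_index("gene")["half_life_h"]
        true = truth.set_index("gene")["true_half_life_h"].loc[est.index]
        rho = spearmanr(true, est).statistic
        rel_err = np.median(np.abs(est - true) / true)
        assert rho >= 0.95
        assert rel_err <= 0.10
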