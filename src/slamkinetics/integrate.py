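"""Integration of RNA stability with expression dynamics and gene sets.

Differential expression between stages or genotypes (a deliberately simple
count-based test: median-of-ratios normalization, Welch test on log-scale
replicate values, BH adjustment — external DE tables import as a drop-in),
rank-sum and ANOVA/Tukey comparisons of half-life groups, characterization of
perturbation-sensitive gene sets by baseline expression and codon optimality,
and fold-change trends across optimality quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "prefilter_counts",
    "size_factors",
    "simplified_de",
    "read_de_table",
    "compare_halflife_groups",
    "multi_group_halflife_test",
    "characterize_sensitive_sets",
    "foldchange_by_optimality_quartile",
]

PSEUDOCOUNT = 0.5


def prefilter_counts(counts: pd.DataFrame, min_reads: int = 10) -> pd.DataFrame:
    """Keep genes with strictly more than ``min_reads`` in every sample."""
    keep = (counts > min_reads).all(axis=1)
    out = counts.loc[keep]
    if out.empty:
        raise ValueError("no genes pass the expression prefilter")
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Per sample: the median, over genes with positive geometric mean, of the
    ratio of the sample's count to the gene's across-sample geometric mean.
    """
    log = np.log(counts.where(counts > 0))
    log_geomean = log.mean(axis=1)
    usable = log_geomean.notna() & np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError("no gene has positive counts in every sample")
    ratios = np.exp(log.loc[usable].sub(log_geomean[usable], axis=0))
    return ratios.median(axis=0).rename("size_factor")


def simplified_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    moderate_variance: bool = True,
    prior_df: float = 20.0,
) -> pd.DataFrame:
    """Differential expression of condition_b versus condition_a.

    Counts are normalized by median-of-ratios size factors; log2 fold change
    is the ratio of condition means after a pseudocount; the test is a
    Welch-style unequal-variance t on log2(normalized + pseudocount)
    replicate values with BH adjustment. With ``moderate_variance`` (the
    default) each group's per-gene variance is shrunk toward the across-gene
    mean variance with ``prior_df`` pseudo-observations — per-gene variance
    estimates from 2-3 replicates are too unstable to test against on their
    own. Set ``moderate_variance=False`` for the plain Welch test.
    Direction is ``up``/``down`` only when |fold change| > fc_threshold AND
    adjusted p < alpha, else ``ns``.

    Parameters
    ----------
    counts : DataFrame
        Gene x sample integer counts.
    samples : DataFrame
        Columns sample, stage (the condition label), replicate.

    Returns one row per gene: gene, base_mean, log2fc, p, padj, direction.
    """
    cond = samples.set_index("sample")["stage"]
    a_cols = cond.index[cond == condition_a]
    b_cols = cond.index[cond == condition_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each condition needs at least 2 replicates")

    sf = size_factors(counts[list(a_cols) + list(b_cols)])
    norm = counts[list(a_cols) + list(b_cols)].div(sf, axis=1)

    mean_a = norm[list(a_cols)].mean(axis=1)
    mean_b = norm[list(b_cols)].mean(axis=1)
    log2fc = np.log2((mean_b + PSEUDOCOUNT) / (mean_a + PSEUDOCOUNT))

    log_norm = np.log2(norm + PSEUDOCOUNT)
    la, lb = log_norm[list(a_cols)], log_norm[list(b_cols)]
    na, nb = la.shape[1], lb.shape[1]
    if moderate_variance:
        va, vb = la.var(axis=1, ddof=1), lb.var(axis=1, ddof=1)
        va = (prior_df * va.mean() + (na - 1) * va) / (prior_df + na - 1)
        vb = (prior_df * vb.mean() + (nb - 1) * vb) / (prior_df + nb - 1)
        se = np.sqrt(va / na + vb / nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (lb.mean(axis=1) - la.mean(axis=1)) / se
        dof = 2 * prior_df + na + nb - 2
        p = 2 * stats.t.sf(np.abs(t), dof)
    else:
        t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    _, padj, _, _ = multipletests(p, method="fdr_bh")

    lfc_cut = np.log2(fc_threshold)
    direction = np.where(
        (padj < alpha) & (log2fc > lfc_cut), "up",
        np.where((padj < alpha) & (log2fc < -lfc_cut), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene": counts.index,
            "base_mean": (mean_a + mean_b) / 2,
            "log2fc": log2fc.to_numpy(),
            "p": p,
            "padj": padj,
            "direction": direction,
        }
    ).reset_index(drop=True)


def read_de_table(path, fc_threshold: float = 2.0, alpha: float = 0.05) -> pd.DataFrame:
    """Import an externally computed DE table (gene, log2fc, padj) as a drop-in.

    Direction is derived from the same thresholds as :func:`simplified_de`.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "padj"}
    if not required.issubset(df.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    lfc_cut = np.log2(fc_threshold)
    df["direction"] = np.where(
        (df["padj"] < alpha) & (df["log2fc"] > lfc_cut), "up",
        np.where((df["padj"] < alpha) & (df["log2fc"] < -lfc_cut), "down", "ns"),
    )
    return df


def compare_halflife_groups(
    group_a: np.ndarray, group_b: np.ndarray
) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum comparison of two half-life groups.

    Uses the exact null distribution when both groups are small (min n <= 20)
    and tie-free, otherwise the normal approximation with continuity and tie
    correction. Returns the Mann-Whitney U statistic (of group_a), p-value
    and both group medians.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }


def multi_group_halflife_test(groups: dict[str, np.ndarray]) -> dict[str, object]:
    """One-way ANOVA across >= 3 groups with Tukey HSD post hoc comparisons.

    Returns the ANOVA F and p plus a DataFrame of pairwise Tukey-adjusted
    p-values and mean differences.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    f_stat, p = stats.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * v.size for k, v in arrays.items()])
    tukey = pairwise_tukeyhsd(values, labels)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {"F": float(f_stat), "p": float(p), "pairwise": pairwise}


@dataclass
class SensitiveSetSummary:
    """Shared DE sets from two contrasts and their characterization."""

    shared_up: set[str]
    shared_down: set[str]
    unchanged: set[str]
    expression_groups: dict[str, np.ndarray]
    expression_test: dict[str, object]
    optimality_groups: dict[str, np.ndarray]
    optimality_test: dict[str, object]


def characterize_sensitive_sets(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    baseline_expression: pd.Series,
    percent_optimal: pd.Series,
) -> SensitiveSetSummary:
    """Characterize genes responding in the same direction in two contrasts.

    Shared up / shared down sets are the intersections of direction calls.
    For shared-up, shared-down and all remaining genes of the common universe,
    the distributions of baseline log10 expression and of percent-optimal
    codons are compared with one-way ANOVA + Tukey HSD.
    """
    universe = set(de_a["gene"]) & set(de_b["gene"])
    if not universe:
        raise ValueError("contrasts share no genes")
    dir_a = de_a.set_index("gene")["direction"]
    dir_b = de_b.set_index("gene")["direction"]
    shared_up = {g for g in universe if dir_a[g] == "up" and dir_b[g] == "up"}
    shared_down = {g for g in universe if dir_a[g] == "down" and dir_b[g] == "down"}
    unchanged = universe - shared_up - shared_down

    def _groups(values: pd.Series, log10: bool) -> dict[str, np.ndarray]:
        out = {}
        for name, genes in (("up", shared_up), ("down", shared_down), ("ns", unchanged)):
            v = values.reindex(sorted(genes)).dropna().to_numpy(dtype=float)
            out[name] = np.log10(v + PSEUDOCOUNT) if log10 else v
        return out

    expr = _groups(baseline_expression, log10=True)
    opt = _groups(percent_optimal, log10=False)
    return SensitiveSetSummary(
        shared_up=shared_up,
        shared_down=shared_down,
        unchanged=unchanged,
        expression_groups=expr,
        expression_test=multi_group_halflife_test(expr),
        optimality_groups=opt,
        optimality_test=multi_group_halflife_test(opt),
    )


def foldchange_by_optimality_quartile(
    de: pd.DataFrame, quartiles: pd.Series
) -> dict[str, object]:
    """Log2 fold-change distributions across codon-optimality quartiles.

    Quartile 1 holds the least optimal transcripts. Returns per-quartile
    fold-change arrays, quartile medians, and a monotone-trend summary: the
    Spearman rank correlation between quartile index and median log2FC.
    """
    lfc = de.set_index("gene")["log2fc"]
    shared = lfc.index.intersection(quartiles.index)
    if shared.empty:
        raise ValueError("DE results and quartiles share no genes")
    lfc = lfc.loc[shared]
    q = quartiles.loc[shared]
    per_quartile = {}
    medians = {}
    for b in sorted(q.unique()):
        vals = lfc[q == b].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"quartile {b} is empty")
        per_quartile[int(b)] = vals
        medians[int(b)] = float(np.median(vals))
    bins = sorted(medians)
    med_values = [medians[b] for b in bins]
    if len(set(med_values)) == 1:
        rho = 0.0  # flat medians: no trend
    else:
        rho, _ = stats.spearmanr(bins, med_values)
    return {"per_quartile": per_quartile, "medians": medians, "trend_rho": float(rho)}
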