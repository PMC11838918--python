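"""Developmentally dynamic half-lives: z-scoring, regression detection, clustering.

Half-lives measured at several developmental stages are z-score normalized per
sample (stage x replicate) across genes, so stages with different global
scalings become directly comparable. A per-gene polynomial regression of the
z-scored half-life on stage pseudo-time (default: embryonic day) is tested
against the intercept-only model with an F-test; Benjamini-Hochberg controls
the FDR, and a model-R² floor removes poorly explained profiles. Significant
genes are grouped by Ward (D2 criterion) hierarchical clustering of their
per-stage mean z-profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_STAGE_TIMES",
    "filter_shared_genes",
    "zscore_normalize",
    "detect_temporal_changes",
    "cluster_profiles",
]

# embryonic-day pseudo-time for the three cortical stages
DEFAULT_STAGE_TIMES: dict[str, float] = {"E11.5": 11.5, "E14.5": 14.5, "E16.5": 16.5}


def filter_shared_genes(genes_per_stage: dict[str, set[str]]) -> set[str]:
    """Intersection of gene sets across stages; errors if empty."""
    if len(genes_per_stage) < 2:
        raise ValueError("need at least 2 stages")
    sets = [set(g) for g in genes_per_stage.values()]
    shared = set.intersection(*sets)
    if not shared:
        raise ValueError("no genes shared across all stages")
    return shared


def zscore_normalize(half_lives: pd.DataFrame) -> pd.DataFrame:
    """Standardize half-lives across genes within each (stage, replicate) sample.

    Input columns: gene, stage, replicate, half_life_h. Adds a ``z`` column
    with (h - mean)/sd per sample, using the sample standard deviation
    (ddof=1) so a sample's z-scores have mean 0 and sd 1. Idempotent.
    """
    required = {"gene", "stage", "replicate", "half_life_h"}
    if not required.issubset(half_lives.columns):
        raise ValueError(f"need columns {sorted(required)}")
    out = half_lives.copy()

    def _z(v: pd.Series) -> pd.Series:
        if len(v) < 2:
            raise ValueError("need >= 2 genes per sample to z-score")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance in a sample; z-score undefined")
        return (v - v.mean()) / sd

    out["z"] = out.groupby(["stage", "replicate"])["half_life_h"].transform(_z)
    return out


def _design(times: np.ndarray, degree: int) -> np.ndarray:
    # centered powers keep the design well conditioned for day-scale times
    tc = times - times.mean()
    return np.column_stack([tc ** d for d in range(degree + 1)])


def detect_temporal_changes(
    profiles: pd.DataFrame,
    alpha: float = 0.05,
    rsq_min: float = 0.6,
    degree: int = 2,
    stage_times: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Flag genes whose z-scored half-life changes across stages.

    Each gene's z values over all (stage, replicate) samples are regressed on
    a degree-``degree`` polynomial of stage pseudo-time; the full model is
    compared to the intercept-only model with an F-test, p-values are BH
    adjusted, and a gene is significant when adjusted p < alpha AND model
    R² > rsq_min. Genes with zero variance across samples get F = 0, p = 1.

    Input must carry columns gene, stage, replicate, z (see
    :func:`zscore_normalize`). Returns one row per gene with coefficients,
    F, p, p_adj, r2 and the significant flag.
    """
    if "z" not in profiles.columns:
        raise ValueError("profiles must be z-scored (run zscore_normalize)")
    stage_times = stage_times or DEFAULT_STAGE_TIMES
    stages = sorted(profiles["stage"].unique())
    unknown = [s for s in stages if s not in stage_times]
    if unknown:
        raise ValueError(f"no pseudo-time for stages {unknown}")
    if degree >= len(stages):
        raise ValueError("polynomial degree must be below the number of stages")

    wide = profiles.pivot_table(index="gene", columns=["stage", "replicate"],
                                values="z")
    if wide.isna().any().any():
        raise ValueError("all genes must be present at every stage and replicate")
    times = np.array([stage_times[s] for s, _ in wide.columns], dtype=float)
    X = _design(times, degree)
    Y = wide.to_numpy(dtype=float).T  # samples x genes

    n, p1 = X.shape
    df_num = p1 - 1
    df_den = n - p1
    if df_den <= 0:
        raise ValueError("not enough samples for the requested degree")

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sse = (resid ** 2).sum(axis=0)
    sst = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat = ((sst - sse) / df_num) / (sse / df_den)
        r2 = 1.0 - sse / sst
    flat = sst <= 1e-300
    f_stat[flat] = 0.0
    r2[flat] = 0.0
    pvals = stats.f.sf(f_stat, df_num, df_den)
    pvals[flat] = 1.0

    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    significant = (p_adj < alpha) & (r2 > rsq_min)

    result = pd.DataFrame(
        {
            "gene": wide.index,
            "F": f_stat,
            "p": pvals,
            "p_adj": p_adj,
            "r2": r2,
            "significant": significant,
        }
    )
    for d in range(p1):
        result[f"coef_{d}"] = beta[d]
    return result


def cluster_profiles(
    profiles: pd.DataFrame,
    genes: pd.Index | list[str],
    k: int = 7,
) -> tuple[pd.Series, pd.DataFrame]:
    """Ward-linkage hierarchical clustering of per-stage mean z-profiles.

    Uses the Ward.D2 criterion on Euclidean distances (scipy's ``ward``),
    cutting the tree at ``k`` clusters. Fully deterministic.

    Returns (labels indexed by gene, per-cluster mean profile over stages).
    """
    genes = pd.Index(genes)
    if k < 1 or k > len(genes):
        raise ValueError("k must be between 1 and the number of genes")
    sub = profiles[profiles["gene"].isin(genes)]
    mat = sub.pivot_table(index="gene", columns="stage", values="z", aggfunc="mean")
    mat = mat.loc[genes.intersection(mat.index)]
    if len(mat) < len(genes):
        raise ValueError("profiles missing for some requested genes")
    if k == 1 or len(mat) == 1:
        labels = pd.Series(1, index=mat.index, name="cluster")
    else:
        link = hierarchy.linkage(mat.to_numpy(), method="ward")
        labels = pd.Series(
            hierarchy.fcluster(link, t=k, criterion="maxclust"),
            index=mat.index, name="cluster",
        )
    means = mat.groupby(labels).mean()
    means.index.name = "cluster"
    return labels, means
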