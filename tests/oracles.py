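"""Independent oracles used by the test suite.

Each function recomputes a quantity by a route independent of the package's
implementation (dense grid search, exhaustive enumeration, direct
sum-of-squares) so tests can cross-check the production code path.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def grid_search_decay_k(times, scaled_rates, k_grid=None) -> float:
    """Dense grid search for k minimizing the SSE of exp(-k t) vs scaled rates."""
    if k_grid is None:
        k_grid = np.linspace(1e-4, 5.0, 500_001)
    t = np.asarray(times, dtype=float)
    y = np.asarray(scaled_rates, dtype=float)
    sse = ((np.exp(-np.outer(k_grid, t)) - y) ** 2).sum(axis=1)
    return float(k_grid[np.argmin(sse)])


def qc_rules(min_coverage: int, half_life: float, r_squared: float,
             cov_threshold: int = 500, max_halflife: float = 24.0,
             min_r2: float = 0.6) -> bool:
    """The three quality rules, evaluated directly (all strict comparisons)."""
    return (
        min_coverage > cov_threshold
        and 0.0 < half_life < max_halflife
        and r_squared > min_r2
    )


def pearson_direct(x, y) -> float:
    """Pearson correlation from raw definitional sums (no library call)."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def wilcoxon_exact_p(a, b) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of all C(n+m, n) labelings.

    Assumes no ties across the pooled sample. Feasible for n, m <= 8.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    w_obs = sum(ranks[v] for v in a)
    n = len(a)
    total = 0
    as_extreme = 0
    all_ranks = list(ranks.values())
    mean_w = n * (len(pooled) + 1) / 2
    for combo in itertools.combinations(all_ranks, n):
        w = sum(combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            as_extreme += 1
    return as_extreme / total


def anova_f_direct(groups) -> float:
    """One-way ANOVA F from explicit between/within sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_v = np.concatenate(groups)
    grand = all_v.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_v) - len(groups)
    return float((ss_between / df_b) / (ss_within / df_w))


def welch_t_direct(a, b) -> tuple[float, float]:
    """Welch t statistic and Welch-Satterthwaite df by hand computation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(t), float(df)


def loglinear_decay(times, abundances) -> tuple[float, float]:
    """(y0, k) from ordinary regression of log abundance on time."""
    t = np.asarray(times, dtype=float)
    y = np.log(np.asarray(abundances, dtype=float))
    slope, intercept = np.polyfit(t, y, 1)
    return float(np.exp(intercept)), float(-slope)
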