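"""Bench-assay calculators: dual-pulse cell-cycle estimation and shutoff decay.

Semi-cumulative labeling: a BrdU pulse followed by an EdU pulse ``interval``
hours later yields three counts — S (EdU+, in S-phase at collection),
L (BrdU+ EdU−, left S-phase during the interval) and P (Ki67+, all cycling
cells). S-phase and total cycle durations follow from

    Ts = (S / L) * interval        Tc = (P / S) * Ts

Transcriptional shutoff: after actinomycin D blocks transcription, transcript
abundance measured by RT-qPCR decays as y = y0 * exp(-k t); the half-life is
ln(2)/k. Conditions are compared with Welch's two-sample t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CycleEstimate",
    "estimate_cell_cycle",
    "relative_abundance_from_ct",
    "fit_shutoff_decay",
    "compare_conditions",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class CycleEstimate:
    ts_h: float
    tc_h: float
    ratio: float  # Ts / Tc


def estimate_cell_cycle(
    s_cells: int, l_cells: int, p_cells: int, interval_h: float = 1.5
) -> CycleEstimate:
    """Cell-cycle durations from an S/L/P labeled-cell panel.

    Scale-invariant in the counts (only ratios enter) and linear in the
    injection interval.
    """
    if min(s_cells, l_cells, p_cells) < 0:
        raise ValueError("counts must be non-negative")
    if l_cells == 0 or s_cells == 0:
        raise ValueError("S and L counts must be positive (division by zero)")
    if s_cells > p_cells or l_cells > p_cells:
        raise ValueError("S and L cannot exceed the proliferative total P")
    if interval_h <= 0:
        raise ValueError("interval must be positive")
    ts = (s_cells / l_cells) * interval_h
    tc = (p_cells / s_cells) * ts
    return CycleEstimate(ts_h=ts, tc_h=tc, ratio=ts / tc)


def relative_abundance_from_ct(
    ct_target: dict[float, float],
    ct_reference: dict[float, float],
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Relative abundances from qPCR Ct values by the ΔΔCt method.

    abundance(t) = efficiency ** -(ΔCt(t) - ΔCt(0)) with ΔCt = Ct_target -
    Ct_reference, so abundance(0) == 1 by construction.
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("amplification efficiency must be in (1, 2]")
    if 0.0 not in ct_target or 0.0 not in ct_reference:
        raise ValueError("a time-0 Ct pair is required")
    times = sorted(ct_target)
    if sorted(ct_reference) != times:
        raise ValueError("target and reference must share identical time points")
    dct0 = ct_target[0.0] - ct_reference[0.0]
    rows = []
    for t in times:
        ddct = (ct_target[t] - ct_reference[t]) - dct0
        rows.append({"time_h": t, "abundance": efficiency ** (-ddct)})
    return pd.DataFrame(rows)


def fit_shutoff_decay(
    times: np.ndarray, abundances: np.ndarray
) -> dict[str, float | bool]:
    """Fit y = y0 * exp(-k t) to a shutoff decay series.

    Both y0 and k are free parameters (initialized from a log-linear
    regression). k <= 0 is flagged: the decay has no finite half-life.

    Returns y0, k_per_h, half_life_h (inf when k <= 0), r_squared, converged.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(abundances, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(y <= 0):
        raise ValueError("abundances must be positive")

    slope, intercept = np.polyfit(t, np.log(y), 1)
    p0 = [float(np.exp(intercept)), max(-slope, 1e-6)]

    def residuals(params: np.ndarray) -> np.ndarray:
        y0, k = params
        return y0 * np.exp(-k * t) - y

    sol = optimize.least_squares(residuals, x0=p0, method="lm",
                                 xtol=1e-13, ftol=1e-13, gtol=1e-13)
    y0, k = (float(v) for v in sol.x)
    resid = residuals(sol.x)
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    return {
        "y0": y0,
        "k_per_h": k,
        "half_life_h": LN2 / k if k > 0 else float("inf"),
        "r_squared": r2,
        "converged": bool(sol.success),
    }


def compare_conditions(
    halflives_a: np.ndarray, halflives_b: np.ndarray
) -> dict[str, float]:
    """Welch's two-sample t test between replicate half-life sets."""
    a = np.asarray(halflives_a, dtype=float)
    b = np.asarray(halflives_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each condition needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p),
            "mean_a": float(a.mean()), "mean_b": float(b.mean())}
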