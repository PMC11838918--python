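"""Half-life estimation from SLAM-seq T>C conversion chase time courses.

For each gene and biological replicate, the T>C conversion rate (converted-T
over covered-T) is computed at every chase time point, scaled so the rate at
time 0 equals 1, and fitted to a one-parameter exponential decay

    y(t) = exp(-k * t)

by nonlinear least squares. The half-life is ln(2)/k. Fits are then filtered
by the quality rules: covered-T strictly above a coverage floor at every chase
time, half-life strictly between 0 and an upper bound, and fit R² strictly
above a floor; a gene is retained at a stage only if it passes in every
replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "QCThresholds",
    "compute_conversion_rates",
    "scale_to_t0",
    "fit_decay",
    "fit_halflives",
    "apply_qc",
    "intersect_replicates",
    "summarize_gene_halflife",
]

LN2 = float(np.log(2.0))

COUNT_COLUMNS = ["gene", "replicate", "stage", "time_h", "covered_T", "converted_T"]


@dataclass(frozen=True)
class QCThresholds:
    """Quality-control thresholds; all comparisons are strict.

    min_coverage: covered-T must exceed this at every chase time (default 500).
    max_halflife: fitted half-life must be below this, in hours (default 24).
    min_r2: fit R² must exceed this (default 0.6).
    """

    min_coverage: int = 500
    max_halflife: float = 24.0
    min_r2: float = 0.6


def _validate_counts(counts: pd.DataFrame) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    bad = counts["converted_T"] > counts["covered_T"]
    if bad.any():
        rows = counts.index[bad][:5].tolist()
        raise ValueError(f"converted_T exceeds covered_T at rows {rows}")
    if (counts["time_h"] < 0).any():
        raise ValueError("negative chase times")


def compute_conversion_rates(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-record conversion rate = converted_T / covered_T.

    Records with covered_T == 0 get a missing rate; any profile containing one
    is excluded from fitting downstream. Output adds a ``rate`` column.
    """
    _validate_counts(counts)
    out = counts.copy()
    covered = out["covered_T"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = out["converted_T"].to_numpy(dtype=float) / covered
    rate[covered == 0] = np.nan
    out["rate"] = rate
    return out


def scale_to_t0(rates: pd.DataFrame) -> pd.DataFrame:
    """Scale each (gene, replicate, stage) profile so rate(0) == 1.

    Adds a ``scaled_rate`` column. Profiles whose time-0 rate is zero or
    missing are left with missing scaled rates (flagged unfittable downstream).
    """
    if "rate" not in rates.columns:
        raise ValueError("run compute_conversion_rates first")
    out = rates.copy()
    keys = ["gene", "replicate", "stage"]
    t0 = (
        out.loc[out["time_h"] == 0]
        .set_index(keys)["rate"]
        .rename("_rate0")
    )
    if t0.index.has_duplicates:
        raise ValueError("multiple time-0 records for one (gene, replicate, stage)")
    out = out.join(t0, on=keys)
    # profiles lacking a time-0 record surface as missing scaled rates
    rate0 = out.pop("_rate0").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = out["rate"].to_numpy() / rate0
    scaled[(rate0 == 0) | np.isnan(rate0)] = np.nan
    out["scaled_rate"] = scaled
    return out


def fit_decay(times: np.ndarray, scaled_rates: np.ndarray) -> dict[str, float | bool]:
    """Fit y = exp(-k t) to one scaled profile by nonlinear least squares.

    The amplitude is fixed at 1 (the scaling pins y(0)); k is initialized from
    the slope of an ordinary regression of log(scaled rate) on time, clamped
    to at least 1e-6, and refined by Levenberg-Marquardt. Negative k is
    allowed (it simply fails the half-life > 0 rule later). R² is computed as
    1 - SSE/SST about the mean of the scaled rates.

    Returns a dict with k_per_h, half_life_h (inf for k <= 0), r_squared and
    converged.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(scaled_rates, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 3:
        raise ValueError("need at least 3 usable time points")

    pos = y > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = 1e-6

    def residuals(k: np.ndarray) -> np.ndarray:
        return np.exp(-k[0] * t) - y

    try:
        sol = optimize.least_squares(residuals, x0=[k0], method="lm", xtol=1e-12,
                                     ftol=1e-12, gtol=1e-12)
        k = float(sol.x[0])
        converged = bool(sol.success)
    except Exception:
        k, converged = float("nan"), False

    if np.isfinite(k):
        resid = np.exp(-k * t) - y
        sse = float(resid @ resid)
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
        half_life = LN2 / k if k > 0 else float("inf")
    else:
        r2, half_life = float("nan"), float("nan")
    return {"k_per_h": k, "half_life_h": half_life, "r_squared": r2,
            "converged": converged}


def fit_halflives(counts: pd.DataFrame) -> pd.DataFrame:
    """Fit every (gene, replicate, stage) profile in a chase count table.

    Convenience wrapper chaining rate computation, t0 scaling and per-profile
    decay fitting. Profiles with a zero or undefined time-0 rate, or with
    fewer than 3 finite points, are reported unconverged with missing k.

    Returns one row per profile: gene, replicate, stage, k_per_h, half_life_h,
    r_squared, min_coverage, converged.
    """
    scaled = scale_to_t0(compute_conversion_rates(counts))
    rows = []
    for (gene, rep, stage), grp in scaled.groupby(["gene", "replicate", "stage"], sort=True):
        grp = grp.sort_values("time_h")
        min_cov = int(grp["covered_T"].min())
        y = grp["scaled_rate"].to_numpy()
        t = grp["time_h"].to_numpy()
        if np.isfinite(y).sum() < 3:
            fit = {"k_per_h": np.nan, "half_life_h": np.nan,
                   "r_squared": np.nan, "converged": False}
        else:
            fit = fit_decay(t, y)
        rows.append({"gene": gene, "replicate": rep, "stage": stage,
                     "min_coverage": min_cov, **fit})
    return pd.DataFrame(rows)


def apply_qc(fits: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Annotate fits with the QC verdict and the reasons for failure.

    Rules (all strict): min_coverage > min_coverage threshold at every chase
    time; 0 < half-life < max_halflife; R² > min_r2. QC never raises — it
    annotates. Adds qc_pass (bool) and fail_reasons (';'-joined string).
    """
    out = fits.copy()
    cov_ok = out["min_coverage"] > thresholds.min_coverage
    hl = out["half_life_h"]
    hl_ok = (hl > 0) & (hl < thresholds.max_halflife) & hl.notna()
    r2_ok = (out["r_squared"] > thresholds.min_r2).fillna(False)
    fit_ok = out["converged"].astype(bool)

    reasons = []
    for c, h, r, f in zip(cov_ok, hl_ok, r2_ok, fit_ok):
        why = []
        if not c:
            why.append("low_coverage")
        if not h:
            why.append("halflife_out_of_range")
        if not r:
            why.append("low_r_squared")
        if not f:
            why.append("fit_not_converged")
        reasons.append(";".join(why))
    out["qc_pass"] = cov_ok & hl_ok & r2_ok & fit_ok
    out["fail_reasons"] = reasons
    return out


def intersect_replicates(fits: pd.DataFrame, required_replicates: int | None = None) -> dict[str, set[str]]:
    """Genes whose fit passes QC in every replicate, per stage.

    ``required_replicates`` defaults to the number of replicates present at
    the stage; it may not exceed that number.
    """
    if "qc_pass" not in fits.columns:
        raise ValueError("run apply_qc first")
    retained: dict[str, set[str]] = {}
    for stage, grp in fits.groupby("stage"):
        n_reps = grp["replicate"].nunique()
        need = n_reps if required_replicates is None else required_replicates
        if need > n_reps:
            raise ValueError(f"required_replicates={need} exceeds available {n_reps}")
        passes = grp.groupby("gene")["qc_pass"].sum()
        retained[stage] = set(passes.index[passes >= need])
    return retained


def summarize_gene_halflife(
    fits: pd.DataFrame,
    retained: dict[str, set[str]] | None = None,
    aggregator: str = "mean",
) -> pd.DataFrame:
    """Aggregate replicate half-lives to one value per gene and stage.

    Only QC-passing replicate fits of retained genes contribute. The
    aggregator is the arithmetic mean by default (median available); the
    choice never alters QC verdicts, which are applied upstream.

    Returns a DataFrame with columns gene, stage, half_life_h, n_replicates.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError("aggregator must be 'mean' or 'median'")
    if retained is None:
        retained = intersect_replicates(fits)
    passing = fits[fits["qc_pass"]]
    rows = []
    for stage, genes in retained.items():
        grp = passing[(passing["stage"] == stage) & (passing["gene"].isin(genes))]
        if grp.empty:
            continue
        agg = grp.groupby("gene")["half_life_h"].agg(aggregator)
        n = grp.groupby("gene")["half_life_h"].size()
        rows.append(pd.DataFrame({"gene": agg.index, "stage": stage,
                                  "half_life_h": agg.values,
                                  "n_replicates": n.values}))
    if not rows:
        raise ValueError("no passing replicates to summarize")
    return pd.concat(rows, ignore_index=True)
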