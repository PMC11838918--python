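"""Synthetic-data generators with known ground truth.

Every input consumed by the analysis stages can be generated here: SLAM-seq
chase count tables (covered/converted T per gene, replicate and time point),
coding sequences with codon usage coupled to half-life, dual-pulse labeled-cell
panels for cell-cycle estimation, transcription-shutoff decay series, and
stage-wise expression count matrices.

The generative model for the chase inverts the downstream estimator: the
T>C conversion rate of a transcript decays as

    rate(t) = background + (t0 - background) * exp(-k * t),    k = ln2 / t_half

and observed converted-T counts are binomial draws at that rate out of a
Poisson-distributed covered-T total. Ground truth (half-life, decay constant,
planted codon classes, planted expression changes) is returned alongside every
simulated data set so that parameter-recovery tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS, STOP_CODONS

__all__ = [
    "SlamSimParams",
    "simulate_slamseq",
    "simulate_cds",
    "simulate_cycle_panel",
    "simulate_shutoff",
    "simulate_expression",
]


@dataclass(frozen=True)
class SlamSimParams:
    """Parameters of the SLAM-seq chase simulator.

    Attributes
    ----------
    n_genes : int
        Number of transcripts to simulate.
    times : tuple of float
        Chase collection times in hours; must include 0.
    n_replicates : int
        Biological replicates per stage.
    coverage_per_timepoint : float
        Expected covered-T count per gene and time point (Poisson mean).
    halflife_log_median : float
        Median of the lognormal half-life distribution, hours.
    halflife_log_sd : float
        Standard deviation of log half-life (dimensionless).
    t0_conversion : float
        Conversion rate of the fully labeled pool at chase start, in (0, 1].
    background_conversion : float
        Unlabeled conversion-error floor, in [0, 1); default 0.
    stage : str
        Stage label attached to every record.
    seed : int
        Seed for the generator; identical seeds give identical output.
    """

    n_genes: int
    times: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 12.0)
    n_replicates: int = 3
    coverage_per_timepoint: float = 1000.0
    halflife_log_median: float = 4.0
    halflife_log_sd: float = 0.6
    t0_conversion: float = 0.05
    background_conversion: float = 0.0
    stage: str = "E11.5"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if 0.0 not in self.times:
            raise ValueError("chase times must include 0")
        if self.coverage_per_timepoint <= 0:
            raise ValueError("coverage_per_timepoint must be positive")
        if not (0.0 < self.t0_conversion <= 1.0):
            raise ValueError("t0_conversion must be in (0, 1]")
        if not (0.0 <= self.background_conversion < 1.0):
            raise ValueError("background_conversion must be in [0, 1)")
        if self.t0_conversion <= self.background_conversion:
            raise ValueError("t0_conversion must exceed background_conversion")


def simulate_slamseq(
    params: SlamSimParams,
    half_lives: np.ndarray | pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a SLAM-seq chase count table with known half-lives.

    Parameters
    ----------
    params : SlamSimParams
    half_lives : array-like, optional
        Per-gene true half-lives in hours, overriding the lognormal draw.
        Lets several stages share one stability landscape (with any planted
        stage-specific changes applied by the caller).

    Returns
    -------
    counts : DataFrame
        Columns gene, replicate, stage, time_h, covered_T, converted_T.
    truth : DataFrame
        Columns gene, true_half_life_h, true_k_per_h, true_t0_conversion,
        codon_class (``none`` until a CDS simulation plants codons).
    """
    rng = np.random.default_rng(params.seed)
    genes = np.array([f"g{i:05d}" for i in range(params.n_genes)])
    if half_lives is None:
        half_lives = params.halflife_log_median * np.exp(
            rng.normal(0.0, params.halflife_log_sd, size=params.n_genes)
        )
    else:
        half_lives = np.asarray(half_lives, dtype=float)
        if half_lives.size != params.n_genes:
            raise ValueError("half_lives length must equal n_genes")
        if np.any(half_lives <= 0):
            raise ValueError("half-lives must be positive")
    k = np.log(2.0) / half_lives

    times = np.asarray(params.times, dtype=float)
    bg = params.background_conversion
    # rate[g, t]: conversion rate of gene g at chase time t
    rate = bg + (params.t0_conversion - bg) * np.exp(-np.outer(k, times))

    records = []
    for rep in range(1, params.n_replicates + 1):
        covered = rng.poisson(
            params.coverage_per_timepoint, size=(params.n_genes, times.size)
        )
        converted = rng.binomial(covered, rate)
        for j, t in enumerate(times):
            records.append(
                pd.DataFrame(
                    {
                        "gene": genes,
                        "replicate": rep,
                        "stage": params.stage,
                        "time_h": t,
                        "covered_T": covered[:, j],
                        "converted_T": converted[:, j],
                    }
                )
            )
    counts = pd.concat(records, ignore_index=True)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "true_half_life_h": half_lives,
            "true_k_per_h": k,
            "true_t0_conversion": params.t0_conversion,
            "codon_class": "none",
        }
    )
    return counts, truth


def _rank_unit(values: np.ndarray) -> np.ndarray:
    """Ranks mapped to [0, 1]; ties broken by position (stable argsort)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=float)
    ranks[order] = np.arange(values.size)
    if values.size == 1:
        return np.zeros(1)
    return ranks / (values.size - 1)


def simulate_cds(
    half_lives: pd.Series,
    n_planted_stab: int = 3,
    n_planted_destab: int = 3,
    n_planted_neutral: int = 3,
    cds_length_codons: int = 300,
    coupling_strength: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate one coding sequence per gene with codon usage coupled to half-life.

    Interior codons are drawn from a mixture ``(1-c)*baseline + c*weighted``
    where the weighted distribution gives planted stabilizing codons mass
    proportional to the gene's half-life rank (destabilizing codons the
    complement, neutral codons a constant), so at coupling 1 the frequency of
    a stabilizing codon increases monotonically with half-life.

    Parameters
    ----------
    half_lives : Series
        Gene id -> half-life in hours (all positive).
    n_planted_stab, n_planted_destab : int
        Number of codons planted as stabilizing / destabilizing.
    n_planted_neutral : int
        Number of codons designated as neutral controls. Their sampling
        weight is constant like every unplanted codon; the designation marks
        which codons neutrality claims are evaluated on (a sample correlation
        across n genes scatters with sd ~ 1/sqrt(n) under the null, so a
        tight bound cannot hold simultaneously for all ~55 unplanted codons).
    cds_length_codons : int
        Total codons per CDS including start and stop; >= 3.
    coupling_strength : float
        Mixture weight in [0, 1]; 0 decouples codon usage from half-life.
    seed : int

    Returns
    -------
    sequences : dict
        Gene id -> CDS string (starts ATG, ends with a stop, length % 3 == 0).
    codon_truth : DataFrame
        One row per sense codon: columns codon, codon_class in
        {stabilizing, destabilizing, neutral, none}.
    """
    if cds_length_codons < 3:
        raise ValueError("cds_length_codons must be at least 3")
    if not (0.0 <= coupling_strength <= 1.0):
        raise ValueError("coupling_strength must be in [0, 1]")
    n_planted = n_planted_stab + n_planted_destab + n_planted_neutral
    if n_planted > len(SENSE_CODONS):
        raise ValueError("cannot plant more codons than there are sense codons")
    hl = np.asarray(half_lives, dtype=float)
    if np.any(hl <= 0):
        raise ValueError("half-lives must be positive")

    rng = np.random.default_rng(seed)
    # plantable pool excludes ATG so the forced start codon does not dilute
    # the planted signal
    pool = [c for c in SENSE_CODONS if c != "ATG"]
    picked = rng.choice(len(pool), size=n_planted, replace=False)
    stab = [pool[i] for i in picked[:n_planted_stab]]
    destab = [pool[i] for i in picked[n_planted_stab:n_planted_stab + n_planted_destab]]
    neutral = [pool[i] for i in picked[n_planted_stab + n_planted_destab:]]

    interior = [c for c in SENSE_CODONS]  # no stops inside the ORF
    idx = {c: i for i, c in enumerate(interior)}
    baseline = np.full(len(interior), 1.0 / len(interior))

    u = _rank_unit(hl)
    n_interior = cds_length_codons - 2
    stops = list(STOP_CODONS)

    sequences: dict[str, str] = {}
    for g, gene in enumerate(half_lives.index):
        weighted = np.full(len(interior), 0.5)
        for c in stab:
            weighted[idx[c]] = u[g]
        for c in destab:
            weighted[idx[c]] = 1.0 - u[g]
        weighted /= weighted.sum()
        p = (1.0 - coupling_strength) * baseline + coupling_strength * weighted
        draws = rng.choice(len(interior), size=n_interior, p=p)
        body = "".join(interior[i] for i in draws)
        stop = stops[rng.integers(len(stops))]
        sequences[str(gene)] = "ATG" + body + stop

    classes = {c: "none" for c in SENSE_CODONS}
    classes.update({c: "stabilizing" for c in stab})
    classes.update({c: "destabilizing" for c in destab})
    classes.update({c: "neutral" for c in neutral})
    codon_truth = pd.DataFrame(
        {"codon": list(SENSE_CODONS),
         "codon_class": [classes[c] for c in SENSE_CODONS]}
    )
    return sequences, codon_truth


def simulate_cycle_panel(
    true_tc: float,
    true_ts: float,
    interval: float = 1.5,
    n_cells: int = 10_000,
    seed: int = 0,
) -> dict[str, float | int]:
    """Simulate an S/L/P labeled-cell panel from an asynchronous cycling population.

    Each cycling cell sits at a uniform-random phase position in [0, Tc); the
    S-phase window occupies [0, Ts). At collection, S cells are those inside
    the window; L cells are those that exited S during the inter-injection
    interval (position in [Ts, Ts + interval)); P counts every cycling cell.
    Hence E[S]/P = Ts/Tc and E[L]/P = interval/Tc.

    Raises
    ------
    ValueError
        If the estimator's assumption 0 < interval < Ts < Tc is violated.
    """
    if not (0 < interval < true_ts < true_tc):
        raise ValueError("require 0 < interval < Ts < Tc")
    if true_ts + interval > true_tc:
        raise ValueError("interval must not push the exit window past Tc")
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, true_tc, size=n_cells)
    s = int(np.count_nonzero(phase < true_ts))
    l = int(np.count_nonzero((phase >= true_ts) & (phase < true_ts + interval)))
    return {"S": s, "L": l, "P": n_cells, "interval_h": interval}


def simulate_shutoff(
    true_halflives: dict[str, float],
    times: tuple[float, ...] = (0.0, 2.0, 8.0),
    noise_sd_log: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate relative-abundance decay series after transcriptional shutoff.

    Abundance follows ``exp(-k t)`` with multiplicative lognormal noise
    (noiseless when ``noise_sd_log`` is 0). Infinite half-lives give constant
    abundance 1.

    Returns a DataFrame with columns transcript, replicate, time_h, abundance.
    """
    if 0.0 not in times:
        raise ValueError("times must include 0")
    if noise_sd_log < 0:
        raise ValueError("noise_sd_log must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    rows = []
    for name, hl in true_halflives.items():
        if hl <= 0:
            raise ValueError(f"half-life for {name} must be positive")
        k = 0.0 if np.isinf(hl) else np.log(2.0) / hl
        for rep in range(1, n_replicates + 1):
            y = np.exp(-k * t)
            if noise_sd_log > 0:
                y = y * np.exp(rng.normal(0.0, noise_sd_log, size=t.size))
            rows.append(
                pd.DataFrame(
                    {"transcript": name, "replicate": rep, "time_h": t, "abundance": y}
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_expression(
    n_genes: int,
    n_stages: int = 2,
    n_replicates: int = 3,
    frac_up: float = 0.05,
    frac_down: float = 0.05,
    fold: float = 4.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate stage-wise negative-binomial count matrices with planted changes.

    Planted "up" genes increase their mean by ``fold`` between consecutive
    stages; "down" genes decrease by the same factor. Counts are drawn from a
    negative binomial with mean m and variance ``m + dispersion * m**2``.

    Returns
    -------
    counts : DataFrame
        Gene x sample integer counts; sample columns named ``s{stage}_r{rep}``.
    samples : DataFrame
        Columns sample, stage, replicate.
    truth : DataFrame
        Columns gene, direction in {up, down, none}, baseline_mean.
    """
    if frac_up < 0 or frac_down < 0 or frac_up + frac_down > 1:
        raise ValueError("planted fractions must be non-negative and sum to <= 1")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    base = np.exp(rng.normal(np.log(200.0), 1.0, size=n_genes))

    n_up = int(round(frac_up * n_genes))
    n_down = int(round(frac_down * n_genes))
    direction = np.array(["none"] * n_genes, dtype=object)
    chosen = rng.choice(n_genes, size=n_up + n_down, replace=False)
    direction[chosen[:n_up]] = "up"
    direction[chosen[n_up:]] = "down"

    mult = np.where(direction == "up", fold, np.where(direction == "down", 1.0 / fold, 1.0))

    data = {}
    samples = []
    for stage in range(n_stages):
        mean = base * mult ** stage
        for rep in range(1, n_replicates + 1):
            name = f"s{stage}_r{rep}"
            if dispersion > 0:
                r = 1.0 / dispersion
                p = r / (r + mean)
                data[name] = rng.negative_binomial(r, p)
            else:
                data[name] = rng.poisson(mean)
            samples.append({"sample": name, "stage": f"s{stage}", "replicate": rep})

    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    truth = pd.DataFrame({"gene": genes, "direction": direction, "baseline_mean": base})
    return counts, pd.DataFrame(samples), truth
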