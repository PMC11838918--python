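"""Codon usage, the codon stabilization coefficient (CSC), and UTR features.

The CSC of a codon is the Pearson correlation, across transcripts, between the
codon's frequency in the coding sequence and the transcript's half-life.
Codons with CSC > 0 are called optimal; a transcript's percent-optimal score
is the share of its sense codons that are optimal. Transcripts are compared in
rank-based quartiles of that score.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "ALL_CODONS",
    "STOP_CODONS",
    "SENSE_CODONS",
    "select_longest_isoform",
    "codon_frequencies",
    "codon_frequency_matrix",
    "compute_csc",
    "percent_optimal",
    "quartile_bins",
    "extreme_stability_sets",
    "utr_features",
]

ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
)
STOP_CODONS: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

_CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}


def select_longest_isoform(isoforms: pd.DataFrame) -> pd.DataFrame:
    """Pick one CDS per gene: the longest isoform.

    Parameters
    ----------
    isoforms : DataFrame
        Columns gene, isoform, sequence (one row per isoform).

    Returns
    -------
    DataFrame with one row per gene (columns gene, isoform, sequence). Length
    ties are broken by the lexicographically smallest isoform label, so the
    choice is deterministic.
    """
    required = {"gene", "isoform", "sequence"}
    if not required.issubset(isoforms.columns):
        raise ValueError(f"isoform table must have columns {sorted(required)}")
    if isoforms.empty:
        raise ValueError("empty isoform table")
    df = isoforms.assign(_len=isoforms["sequence"].str.len())
    df = df.sort_values(["gene", "_len", "isoform"], ascending=[True, False, True])
    out = df.groupby("gene", sort=True).head(1).drop(columns="_len")
    return out.reset_index(drop=True)


def codon_frequencies(sequence: str) -> np.ndarray:
    """Proportions of the 64 codons over non-overlapping triplets of a CDS.

    The full CDS is windowed in-frame (width 3, step 3), so the stop codon is
    included in the denominator. Frequencies sum to 1.

    Raises
    ------
    ValueError
        For an empty sequence, a length not divisible by 3 (no silent
        trimming), or characters outside A/C/G/T.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    counts = np.zeros(len(ALL_CODONS), dtype=float)
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        j = _CODON_INDEX.get(codon)
        if j is None:
            raise ValueError(f"invalid codon {codon!r} at position {i}")
        counts[j] += 1
    return counts / counts.sum()


def codon_frequency_matrix(sequences: dict[str, str]) -> pd.DataFrame:
    """Gene x codon frequency matrix (64 columns, rows sum to 1)."""
    if not sequences:
        raise ValueError("no sequences")
    mat = np.vstack([codon_frequencies(s) for s in sequences.values()])
    return pd.DataFrame(mat, index=pd.Index(sequences.keys(), name="gene"),
                        columns=list(ALL_CODONS))


def _amino_acid(codon: str) -> str:
    return str(Seq(codon).translate())


def compute_csc(frequencies: pd.DataFrame, half_lives: pd.Series) -> pd.DataFrame:
    """Codon stabilization coefficients over the 61 sense codons.

    For each sense codon, CSC is the Pearson correlation between the codon's
    frequency and the transcript half-life across the genes shared by both
    inputs. Codons whose frequency has zero variance across genes get a
    missing (NaN) CSC, not zero.

    Returns a DataFrame with columns codon, amino_acid, csc, optimal
    (optimal == csc > 0; False where csc is missing).
    """
    shared = frequencies.index.intersection(half_lives.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 genes shared between frequencies and half-lives")
    hl = half_lives.loc[shared].to_numpy(dtype=float)
    if np.ptp(hl) == 0:
        raise ValueError("half-life vector is constant; CSC undefined")
    freq = frequencies.loc[shared, list(SENSE_CODONS)].to_numpy(dtype=float)

    hl_c = hl - hl.mean()
    f_c = freq - freq.mean(axis=0)
    denom_f = np.sqrt((f_c ** 2).sum(axis=0))
    denom_h = np.sqrt((hl_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        csc = (f_c * hl_c[:, None]).sum(axis=0) / (denom_f * denom_h)
    csc[denom_f == 0] = np.nan

    return pd.DataFrame(
        {
            "codon": list(SENSE_CODONS),
            "amino_acid": [_amino_acid(c) for c in SENSE_CODONS],
            "csc": csc,
            "optimal": np.where(np.isnan(csc), False, csc > 0),
        }
    )


def percent_optimal(sequence: str, csc_table: pd.DataFrame) -> float:
    """Percentage of a CDS's sense codons that are optimal (CSC > 0).

    Stop codons and codons with a missing CSC are excluded from both the
    numerator and the denominator.
    """
    seq = sequence.upper()
    if len(seq) % 3 != 0 or not seq:
        raise ValueError("sequence must be a non-empty in-frame CDS")
    table = csc_table.set_index("codon")
    known = table.index[table["csc"].notna()]
    optimal = set(table.index[(table["csc"] > 0).fillna(False)])
    total = 0
    n_opt = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS or codon not in set(known):
            continue
        total += 1
        if codon in optimal:
            n_opt += 1
    if total == 0:
        raise ValueError("CDS contains no scorable sense codons")
    return 100.0 * n_opt / total


def quartile_bins(values: pd.Series, n_bins: int = 4) -> pd.Series:
    """Rank-based bins 1..n_bins (1 = lowest values), near-equal occupancy.

    Ties are broken by stable gene-id order so the assignment is
    deterministic; bin sizes differ by at most 1.
    """
    if len(values) < n_bins:
        raise ValueError(f"need at least {n_bins} genes for {n_bins} bins")
    ordered = values.sort_index().sort_values(kind="stable")
    labels = np.empty(len(ordered), dtype=int)
    start = 0
    n = len(ordered)
    for b in range(n_bins):
        size = n // n_bins + (1 if b < n % n_bins else 0)
        labels[start : start + size] = b + 1
        start += size
    return pd.Series(labels, index=ordered.index, name="quartile").reindex(values.index)


def extreme_stability_sets(
    half_lives: pd.Series, fraction: float = 0.1
) -> tuple[set[str], set[str]]:
    """Top and bottom ``fraction`` of genes by half-life (most/least stable).

    Ties are broken by gene id so the sets are deterministic; the two sets are
    disjoint for any fraction <= 0.5.
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    if half_lives.empty:
        raise ValueError("empty half-life table")
    n = max(1, int(round(fraction * len(half_lives))))
    ordered = half_lives.sort_index().sort_values(kind="stable")
    least = set(ordered.index[:n])
    most = set(ordered.index[-n:])
    return most, least


def utr_features(sequence: str) -> tuple[int, float]:
    """(length in nucleotides, GC percent) of a UTR sequence.

    N bases count toward the length but are excluded from the GC denominator.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGTN"):
        raise ValueError("UTR sequence must contain only A/C/G/T/N")
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence has no unambiguous bases")
    gc = seq.count("G") + seq.count("C")
    return len(seq), 100.0 * gc / acgt
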