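"""Readers and writers for the pipeline's tabular (TSV) and FASTA formats.

TSV (tab-separated, header row, UTF-8, '.' decimal) is the canonical tabular
dialect. All writers round-trip losslessly through their readers.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .halflife import COUNT_COLUMNS

__all__ = [
    "read_chase_counts",
    "write_chase_counts",
    "read_fasta_sequences",
    "read_gene_sets",
    "write_tsv",
]


def read_chase_counts(path: str | Path) -> pd.DataFrame:
    """Read a chase count TSV, summing exon-level rows to gene level.

    Required columns: gene, replicate, stage, time_h, covered_T, converted_T;
    an optional ``exon`` column marks exon-level rows, whose covered and
    converted counts are summed per (gene, replicate, stage, time_h). Rows
    where converted exceeds covered are reported with their line numbers.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad = df.index[df["converted_T"] > df["covered_T"]]
    if len(bad):
        lines = [i + 2 for i in bad[:10]]  # 1-based, after header
        raise ValueError(f"{path}: converted_T > covered_T at line(s) {lines}")
    if "exon" in df.columns:
        df = (
            df.groupby(["gene", "replicate", "stage", "time_h"], as_index=False)[
                ["covered_T", "converted_T"]
            ].sum()
        )
    return df[COUNT_COLUMNS]


def write_chase_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_fasta_sequences(
    path: str | Path,
    id_pattern: str = r"^(?P<gene>[^|\s]+)(?:\|(?P<isoform>\S+))?",
) -> pd.DataFrame:
    """Read FASTA records into a (gene, isoform, sequence) table.

    ``id_pattern`` is a regex with a named ``gene`` group and an optional
    ``isoform`` group applied to each record id; the isoform label defaults to
    the full record id. Duplicate (gene, isoform) pairs are rejected and
    sequences are uppercased.
    """
    pattern = re.compile(id_pattern)
    rows = []
    for record in SeqIO.parse(str(path), "fasta"):
        m = pattern.match(record.id)
        if not m:
            raise ValueError(f"{path}: header {record.id!r} does not match id pattern")
        gene = m.group("gene")
        isoform = m.groupdict().get("isoform") or record.id
        rows.append({"gene": gene, "isoform": isoform,
                     "sequence": str(record.seq).upper()})
    if not rows:
        raise ValueError(f"{path}: no FASTA records")
    df = pd.DataFrame(rows)
    dup = df.duplicated(subset=["gene", "isoform"])
    if dup.any():
        raise ValueError(f"{path}: duplicate record id(s) {df.loc[dup, 'isoform'].tolist()}")
    return df


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a gene-set TSV (columns label, gene) into label -> id set."""
    df = pd.read_csv(path, sep="\t")
    if not {"label", "gene"}.issubset(df.columns):
        raise ValueError(f"{path}: gene-set table needs columns label, gene")
    return {label: set(grp["gene"]) for label, grp in df.groupby("label")}


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
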