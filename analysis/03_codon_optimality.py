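"""Codon stabilization coefficients and optimality quartiles on the CDS set.

Reads the simulated CDS FASTA and the fitted stage-1 half-lives, computes the
CSC per sense codon, checks planted codon classes, scores percent-optimal
codons per gene, and verifies the quartile half-life trend. Also extracts the
extreme-stability gene sets per stage and their cross-stage overlap.
"""

from pathlib import Path

import pandas as pd

from slamkinetics.codons import (
    codon_frequency_matrix,
    compute_csc,
    extreme_stability_sets,
    percent_optimal,
    quartile_bins,
    select_longest_isoform,
)
from slamkinetics.io import read_fasta_sequences, write_tsv

DATA = Path("results/data")
HALFLIFE = Path("results/halflife")
OUT = Path("results/codons")


def main() -> None:
    isoforms = read_fasta_sequences(DATA / "cds.fa")
    cds = select_longest_isoform(isoforms)
    sequences = dict(zip(cds["gene"], cds["sequence"]))
    codon_truth = pd.read_csv(DATA / "codon_truth.tsv", sep="\t")

    summary = pd.read_csv(HALFLIFE / "halflife_summary.tsv", sep="\t")
    stage0 = sorted(summary["stage"].unique())[0]
    hl = summary[summary["stage"] == stage0].set_index("gene")["half_life_h"]

    freq = codon_frequency_matrix(sequences)
    csc = compute_csc(freq, hl)
    write_tsv(csc, OUT / "csc.tsv")

    merged = csc.merge(codon_truth, on="codon")
    for cls in ("stabilizing", "destabilizing", "neutral"):
        vals = merged.loc[merged["codon_class"] == cls, "csc"]
        print(f"[03] planted {cls}: CSC range [{vals.min():+.3f}, {vals.max():+.3f}]")

    pct = pd.Series({g: percent_optimal(s, csc) for g, s in sequences.items()})
    shared = pct.index.intersection(hl.index)
    bins = quartile_bins(pct.loc[shared])
    write_tsv(pd.DataFrame({"gene": pct.index, "percent_optimal": pct.values,
                            "quartile": bins.reindex(pct.index).values}),
              OUT / "optimality.tsv")
    medians = [hl.loc[bins.index[bins == b]].median() for b in (1, 2, 3, 4)]
    print("[03] median half-life by optimality quartile (1=least optimal): "
          + ", ".join(f"Q{b}={m:.2f} h" for b, m in enumerate(medians, start=1)))

    per_stage = {s: summary[summary["stage"] == s].set_index("gene")["half_life_h"]
                 for s in summary["stage"].unique()}
    most = {s: extreme_stability_sets(h, 0.1)[0] for s, h in per_stage.items()}
    overlap = set.intersection(*most.values())
    print(f"[03] top-10% most stable: {', '.join(str(len(v)) for v in most.values())} "
          f"genes per stage; {len(overlap)} shared across all stages")


if __name__ == "__main__":
    main()
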