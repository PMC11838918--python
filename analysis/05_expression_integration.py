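"""Differential expression and its integration with stability and optimality.

Runs the simplified DE on the simulated two-condition experiment, checks
planted-gene recovery, compares half-lives of up/down/unchanged genes with
rank-sum tests, and measures the fold-change trend across codon-optimality
quartiles.
"""

from pathlib import Path

import pandas as pd

from slamkinetics.integrate import (
    compare_halflife_groups,
    foldchange_by_optimality_quartile,
    prefilter_counts,
    simplified_de,
)
from slamkinetics.io import write_tsv

DATA = Path("results/data")
HALFLIFE = Path("results/halflife")
CODONS = Path("results/codons")
OUT = Path("results/integration")


def main() -> None:
    counts = pd.read_csv(DATA / "expression_counts.tsv", sep="\t").set_index("gene")
    samples = pd.read_csv(DATA / "expression_samples.tsv", sep="\t")
    truth = pd.read_csv(DATA / "expression_truth.tsv", sep="\t")

    filtered = prefilter_counts(counts, 10)
    de = simplified_de(filtered, samples, "s0", "s1")
    write_tsv(de, OUT / "de.tsv")

    m = de.merge(truth, on="gene")
    planted = m[m["direction_y"] != "none"]
    recovery = (planted["direction_x"] == planted["direction_y"]).mean()
    print(f"[05] DE: {int((de['direction'] != 'ns').sum())} calls; "
          f"planted recovery {100 * recovery:.1f}% ({len(planted)} planted genes)")

    # stability of DE classes (stage-1 half-lives; universes simulated
    # independently here, so the comparison illustrates the machinery)
    summary = pd.read_csv(HALFLIFE / "halflife_summary.tsv", sep="\t")
    stage0 = sorted(summary["stage"].unique())[0]
    hl = summary[summary["stage"] == stage0].set_index("gene")["half_life_h"]
    groups = {d: hl.reindex(de.loc[de["direction"] == d, "gene"]).dropna()
              for d in ("up", "down", "ns")}
    if min(len(g) for g in groups.values()) > 0:
        res = compare_halflife_groups(groups["up"], groups["down"])
        print(f"[05] half-life up vs down: medians "
              f"{res['median_a']:.2f} vs {res['median_b']:.2f} h, "
              f"rank-sum p = {res['p']:.3g}")

    optimality = pd.read_csv(CODONS / "optimality.tsv", sep="\t")
    quart = optimality.dropna(subset=["quartile"]).set_index("gene")["quartile"]
    trend = foldchange_by_optimality_quartile(de, quart.astype(int))
    meds = ", ".join(f"Q{b}={m:+.3f}" for b, m in sorted(trend["medians"].items()))
    print(f"[05] median log2FC by optimality quartile: {meds} "
          f"(trend rho = {trend['trend_rho']:+.2f})")


if __name__ == "__main__":
    main()
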