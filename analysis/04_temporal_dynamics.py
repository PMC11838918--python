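"""Detect developmentally dynamic half-lives and cluster their profiles.

Restricts to genes passing QC at every stage, z-scores half-lives per
(stage, replicate) sample, runs the polynomial regression screen, and Ward-
clusters the significant genes' mean z-profiles.
"""

from pathlib import Path

import pandas as pd

from slamkinetics.io import write_tsv
from slamkinetics.temporal import (
    cluster_profiles,
    detect_temporal_changes,
    filter_shared_genes,
    zscore_normalize,
)

HALFLIFE = Path("results/halflife")
OUT = Path("results/temporal")
N_CLUSTERS = 7


def main() -> None:
    fits = pd.read_csv(HALFLIFE / "halflife_fits.tsv", sep="\t")
    passing = fits[fits["qc_pass"]]
    shared = filter_shared_genes(
        {s: set(g["gene"]) for s, g in passing.groupby("stage")})
    print(f"[04] {len(shared)} genes measured at all stages")

    profiles = zscore_normalize(passing[passing["gene"].isin(shared)])
    n = profiles.groupby("gene").size()
    profiles = profiles[profiles["gene"].isin(n[n == n.max()].index)]

    result = detect_temporal_changes(profiles, alpha=0.05, rsq_min=0.6)
    n_sig = int(result["significant"].sum())
    print(f"[04] {n_sig}/{len(result)} genes "
          f"({100 * n_sig / len(result):.1f}%) change stability across stages")

    truth = pd.read_csv(Path("results/data/halflife_truth.tsv"), sep="\t")
    planted = set(truth.loc[truth["dynamic"], "gene"])
    merged = result.assign(planted=result["gene"].isin(planted))
    power = merged.loc[merged["planted"], "significant"].mean()
    fp = merged.loc[~merged["planted"], "significant"].mean()
    print(f"[04] planted-drift detection: power {100 * power:.0f}%, "
          f"false-positive rate {100 * fp:.1f}%")

    if n_sig >= N_CLUSTERS:
        sig = result.loc[result["significant"], "gene"]
        labels, means = cluster_profiles(profiles, sig, k=N_CLUSTERS)
        result = result.merge(labels.rename("cluster"), left_on="gene",
                              right_index=True, how="left")
        write_tsv(means.reset_index(), OUT / "cluster_means.tsv")
        occupancy = labels.value_counts().sort_index()
        print("[04] cluster occupancy: "
              + ", ".join(f"c{c}={n}" for c, n in occupancy.items()))
    write_tsv(result, OUT / "temporal.tsv")


if __name__ == "__main__":
    main()
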