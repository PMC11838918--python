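"""Generate every synthetic input for the downstream analyses.

Writes, under results/data/: SLAM-seq chase counts for three developmental
stages (shared gene universe, per-stage half-life truth), a CDS FASTA with
codon usage coupled to stage-1 half-lives, a two-condition expression
experiment with planted fold changes, dual-pulse cell-count panels for
several simulated embryos per genotype, and transcription-shutoff decay
series for control and decay-impaired conditions.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from slamkinetics.io import write_chase_counts, write_tsv
from slamkinetics.synthetic import (
    SlamSimParams,
    simulate_cds,
    simulate_cycle_panel,
    simulate_expression,
    simulate_shutoff,
    simulate_slamseq,
)

SEED = 20260
N_GENES = 400
STAGES = ("E11.5", "E14.5", "E16.5")
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # one stability landscape shared by all stages, with a small planted
    # dynamic subset whose half-life drifts monotonically across stages
    rng = np.random.default_rng(SEED)
    base = 4.0 * np.exp(rng.normal(0.0, 0.6, N_GENES))
    n_dynamic = N_GENES // 20
    dynamic_idx = rng.choice(N_GENES, size=n_dynamic, replace=False)
    drift = rng.choice([0.5, 2.0], size=n_dynamic)  # halving or doubling per step

    counts_frames, truth_frames = [], []
    for i, stage in enumerate(STAGES):
        hl = base.copy()
        hl[dynamic_idx] = base[dynamic_idx] * drift ** i
        params = SlamSimParams(n_genes=N_GENES, coverage_per_timepoint=2000.0,
                               stage=stage, seed=SEED + i)
        counts, truth = simulate_slamseq(params, half_lives=hl)
        counts_frames.append(counts)
        truth_frames.append(truth.assign(stage=stage))
    counts = pd.concat(counts_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    gene_ids = truth_frames[0]["gene"].to_numpy()
    truth["dynamic"] = truth["gene"].isin(gene_ids[dynamic_idx])
    write_chase_counts(counts, OUT / "chase_counts.tsv")
    write_tsv(truth, OUT / "halflife_truth.tsv")
    print(f"[01] chase counts: {len(counts)} rows, {N_GENES} genes x "
          f"{len(STAGES)} stages x 3 replicates x 5 time points; "
          f"{n_dynamic} genes with planted stability drift")

    # CDS set coupled to the first stage's true half-lives
    hl0 = truth[truth["stage"] == STAGES[0]].set_index("gene")["true_half_life_h"]
    sequences, codon_truth = simulate_cds(hl0, seed=SEED + 10)
    with open(OUT / "cds.fa", "w") as fh:
        for gene, seq in sequences.items():
            fh.write(f">{gene}|cds1\n{seq}\n")
    write_tsv(codon_truth, OUT / "codon_truth.tsv")
    planted = codon_truth[codon_truth["codon_class"] != "none"]
    print(f"[01] CDS FASTA: {len(sequences)} sequences; planted codons: "
          + ", ".join(f"{r.codon}({r.codon_class})" for r in planted.itertuples()))

    # expression experiment with planted 4-fold changes
    expr_counts, samples, expr_truth = simulate_expression(
        N_GENES, frac_up=0.05, frac_down=0.05, fold=4.0, dispersion=0.05,
        seed=SEED + 20)
    write_tsv(expr_counts.reset_index(), OUT / "expression_counts.tsv")
    write_tsv(samples, OUT / "expression_samples.tsv")
    write_tsv(expr_truth, OUT / "expression_truth.tsv")
    n_planted = (expr_truth["direction"] != "none").sum()
    print(f"[01] expression: {N_GENES} genes, {n_planted} planted 4-fold changes")

    # cell-cycle panels: control ~ (Tc 10 h, Ts 5 h); mutant ~ (Tc 14 h, Ts 6.5 h)
    rows = []
    for genotype, tc, ts in (("control", 10.0, 5.0), ("mutant", 14.0, 6.5)):
        for embryo in range(1, 7):
            panel = simulate_cycle_panel(tc, ts, 1.5, 10_000,
                                         seed=SEED + 30 + embryo +
                                         (100 if genotype == "mutant" else 0))
            rows.append({"embryo": f"{genotype}_{embryo}", "genotype": genotype,
                         "S": panel["S"], "L": panel["L"], "P": panel["P"],
                         "interval_h": panel["interval_h"]})
    write_tsv(pd.DataFrame(rows), OUT / "cycle_panels.tsv")
    print(f"[01] cell-cycle panels: {len(rows)} embryos, 2 genotypes")

    # shutoff series: the same transcripts decay slower in the mutant
    half_lives = {"control": {"tx1": 2.0, "tx2": 1.5, "tx3": 3.0},
                  "mutant": {"tx1": 6.0, "tx2": 4.0, "tx3": 7.0}}
    frames = []
    for genotype, hls in half_lives.items():
        series = simulate_shutoff(hls, noise_sd_log=0.1, n_replicates=4,
                                  seed=SEED + 40 + (1 if genotype == "mutant" else 0))
        frames.append(series.assign(genotype=genotype))
    write_tsv(pd.concat(frames, ignore_index=True), OUT / "shutoff_series.tsv")
    print("[01] shutoff series: 3 transcripts x 2 genotypes x 4 replicates")


if __name__ == "__main__":
    main()
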