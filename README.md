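# slamkinetics

RNA stability analysis for SLAM-seq chase experiments, built around the
developing mouse cortex use case: estimate per-gene mRNA half-lives from
T>C conversion time courses, relate stability to codon optimality and to
developmental expression changes, detect transcripts whose stability changes
across stages, and compute the two bench-assay kinetics used alongside
sequencing — dual-pulse cell-cycle durations and actinomycin-D shutoff
half-lives. A synthetic-data module generates every input with known ground
truth, so the whole pipeline is testable without any external data.

## The model

After 4sU labeling and a uridine chase, the per-gene T>C conversion rate
(converted T / covered T) tracks the surviving labeled pool. Scaling each
profile to its time-0 rate and fitting

    y(t) = exp(-k t),        t½ = ln(2) / k

by nonlinear least squares gives the decay constant and half-life per gene
and replicate. Estimates are kept when coverage on T exceeds 500 at every
chase time, 0 < t½ < 24 h and R² > 0.6, in all replicates of a stage.

Downstream, the codon stabilization coefficient CSC(c) = Pearson r between
codon frequency and half-life across transcripts defines optimal (CSC > 0)
codons; z-scored half-lives regressed on stage pseudo-time flag
developmentally dynamic transcripts (BH-adjusted p < 0.05, R² > 0.6), which
are Ward-clustered; and the cell-cycle estimator uses
Ts = (S/L)·interval, Tc = (P/S)·Ts from S/L/P labeled-cell counts.

## Worked example

The `analysis/` scripts run a complete synthetic study (400 genes, 3 stages,
3 replicates, chase at 0/2/4/8/12 h) end to end:

```
python analysis/01_simulate_data.py
python analysis/02_fit_halflives.py
python analysis/03_codon_optimality.py
python analysis/04_temporal_dynamics.py
python analysis/05_expression_integration.py
python analysis/06_bench_kinetics.py
```

Output of the half-life and codon stages:

```
[02] E11.5: 385/400 genes pass QC in all 3 replicates
[02] E14.5: 389/400 genes pass QC in all 3 replicates
[02] E16.5: 381/400 genes pass QC in all 3 replicates
[02] recovery over 1155 gene-stage estimates: Spearman r = 0.985, median relative error = 6.8%
[03] planted stabilizing: CSC range [+0.674, +0.704]
[03] planted destabilizing: CSC range [-0.694, -0.682]
[03] median half-life by optimality quartile (1=least optimal): Q1=2.46 h, Q2=3.46 h, Q3=4.83 h, Q4=7.56 h
[04] 10/371 genes (2.7%) change stability across stages
[06] control: Tc = 9.9 h, Ts = 4.9 h, Ts/Tc = 0.50 (n=6 embryos)
[06] mutant: Tc = 13.8 h, Ts = 6.4 h, Ts/Tc = 0.46 (n=6 embryos)
```

Reading the numbers: nearly all simulated genes clear the coverage/fit QC;
estimated half-lives track the generator's truth closely (rank correlation
0.985); codons planted to co-vary with stability come out with strongly
positive/negative CSC while half-life rises monotonically across
optimality quartiles; only the small planted subset of transcripts is called
developmentally dynamic; and the cell-cycle estimator recovers the control
(~10 h cycle, ~5 h S-phase) and slowed mutant kinetics with an unchanged-to-
slightly-lower Ts/Tc ratio.

The same stages are available as a library (`slamkinetics.halflife`,
`.codons`, `.temporal`, `.integrate`, `.kinetics`, `.synthetic`) and through
the `slamkinetics` command-line tool (`simulate`, `halflife`, `codons`,
`temporal`, `cellcycle`, `shutoff`, `run --simulate`).

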