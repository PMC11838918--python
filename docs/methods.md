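# Methods

## Half-life estimation from conversion time courses

During metabolic labeling with 4-thiouridine, labeled transcripts read out as
T>C conversions. After the label is chased with excess uridine, the per-gene
conversion rate — converted-T over covered-T, summed over a gene's exons —
decays with the degradation of the labeled pool. For each gene, replicate and
stage the pipeline:

1. computes the conversion rate at every chase time (default times 0, 2, 4,
   8, 12 h);
2. scales the profile so the rate at time 0 equals 1 (any labeling
   efficiency, background or library scaling common to the profile cancels
   here, which is why the model needs no amplitude parameter);
3. fits `y(t) = exp(-k t)` by Levenberg–Marquardt nonlinear least squares,
   with k initialized from the slope of an ordinary regression of
   log(scaled rate) on time, clamped to ≥ 1e-6;
4. reports half-life `t½ = ln(2)/k`, and R² computed as `1 − SSE/SST` about
   the mean of the scaled rates (the conventional pseudo-R² for nonlinear
   fits; scaled rather than raw rates are assumed).

The time-0 point (scaled value 1) is included in the fit; it constrains
nothing but keeps SST conventional. Negative fitted k is allowed — it simply
fails the half-life range filter rather than being clipped, preserving the
filter semantics.

Quality control per replicate, all comparisons strict: covered-T > 500 at
every chase time, 0 < t½ < 24 h, R² > 0.6. A gene is retained at a stage only
when it passes in every replicate. Replicate half-lives are aggregated by
arithmetic mean (median available); the aggregation choice cannot alter QC
verdicts because filtering precedes it.

## Codon optimality

The codon stabilization coefficient (CSC) of a codon is the Pearson
correlation, across transcripts, between the codon's frequency in the CDS and
the transcript's half-life. Frequencies are computed over non-overlapping
in-frame triplets of the full CDS (the stop codon is part of the
denominator), but CSC is reported for the 61 sense codons only; a codon with
zero frequency variance is reported missing, not zero. Codons with CSC > 0
are optimal. A transcript's percent-optimal score counts optimal sense codons
over scorable sense codons (stops and missing-CSC codons excluded from both
counts; the denominator choice is configurable). Transcripts are compared in
rank-based quartiles of near-equal occupancy, ties broken by gene id. For
genes with several isoforms the longest is used, ties broken by the
lexicographically smallest isoform label.

## Temporal dynamics

Half-lives measured at the three cortical stages (E11.5, E14.5, E16.5) are
z-scored per (stage × replicate) sample across genes (sample sd, ddof 1), so
per-sample scalings cancel and the transform is idempotent. Each gene's z
values are regressed on a degree-2 polynomial of stage pseudo-time, encoded
as embryonic day {11.5, 14.5, 16.5} (configurable to {0, 1, 2}); the full
model is compared to the intercept-only model with an F-test, p-values are
Benjamini–Hochberg adjusted, and a gene is called dynamic when adjusted
p < 0.05 and model R² > 0.6. With three stages and degree 2 the polynomial
model is saturated in the stage means, so a two-step stepwise selection of
polynomial terms would be nearly vacuous; the single F-test + FDR + R² filter
is a deliberate, documented simplification of that family of time-course
screens, not a reimplementation of any of them. Significant genes are grouped
by agglomerative hierarchical clustering with the Ward.D2 criterion on
Euclidean distances between per-stage mean z-profiles, cutting the tree at
k = 7 by default; the procedure is fully deterministic, and cluster labels
are compared to any ground truth only up to permutation (adjusted Rand
index).

## Expression integration

Differential expression between two conditions uses median-of-ratios size
factors, log2 fold changes of normalized condition means with a pseudocount
of 0.5, and an unequal-variance t-test on log2(normalized + 0.5) replicate
values with BH adjustment; calls require |fold change| > 2 and adjusted
p < 0.05. With 2–3 replicates per condition a per-gene variance estimate is
too unstable to test against, so by default each group's variance is shrunk
toward the across-gene mean variance with 20 pseudo-observations
(empirical-Bayes moderation in the spirit of limma); the unmoderated Welch
test is available via `moderate_variance=False`. This DE is deliberately
simple — it exists so synthetic pipelines are self-contained — and externally
computed DE tables (gene, log2fc, padj) import as a drop-in replacement.

Group comparisons of half-lives use the two-sided Wilcoxon rank-sum test
(exact null distribution when both groups have n ≤ 20 and no ties, otherwise
the normal approximation with continuity and tie corrections) or one-way
ANOVA with Tukey HSD post-hoc tests for three or more groups. Sets
responding in two contrasts are intersected by direction and characterized by
baseline log10 expression (normalized mean counts + pseudocount) and
percent-optimal distributions; fold-change trends across optimality quartiles
are summarized by the Spearman correlation of quartile index with median
log2 fold change (defined as 0 when the medians are flat).

## Bench kinetics

Dual-pulse cell-cycle estimation: with counts S (EdU+, in S-phase at
collection), L (BrdU+EdU−, exited S-phase during the inter-injection
interval) and P (Ki67+, all cycling cells),

    Ts = (S / L) · interval,    Tc = (P / S) · Ts,

with the interval defaulting to 1.5 h. The estimator assumes an asynchronous
population (uniform phase), interval < Ts < Tc, and that every counted cell
cycles. Estimates are scale-invariant in counts; per-embryo estimates feed
group statistics rather than averaging count ratios across embryos.

Transcriptional shutoff: after actinomycin D stops transcription, relative
abundance (from qPCR Ct values via ΔΔCt with a reference transcript,
amplification efficiency defaulting to 2 since no efficiency correction is
assumed) is fitted to `y = y0 · exp(-k t)` with both y0 and k free, and
t½ = ln(2)/k; k ≤ 0 is flagged as having no finite half-life. Conditions are
compared by Welch's two-sample t-test on replicate half-lives.

## Synthetic data: what it emulates and what it does not

The generators invert each estimator's model so every stage is testable with
known ground truth:

- **Chase counts** — conversion rate
  `background + (t0 − background) · exp(−k t)`; covered-T is Poisson around
  the target coverage (so the coverage filter is exercised stochastically)
  and converted-T is binomial at the model rate. Half-lives are lognormal
  with median 4 h and log-sd 0.6, spanning the 0–24 h QC window; the
  conversion rate at chase start defaults to 0.05 and the background error
  floor to 0 (the t0 scaling makes the pipeline background-agnostic; nonzero
  background is an option for stress-testing misfit). Full steady-state
  labeling at t = 0 is assumed — any saturation shortfall is absorbed by the
  t0 scaling. Several stages can share one half-life landscape with a planted
  dynamic subset.
- **Coding sequences** — interior codons drawn from a mixture
  `(1−c)·uniform + c·weighted`, where planted stabilizing codons get weight
  proportional to the gene's half-life rank, destabilizing codons the
  complement and all other codons a constant; at coupling 1 planted codon
  frequency is monotone in half-life. Three codons are additionally
  *designated neutral*: their weight is constant like every unplanted codon,
  and neutrality claims are evaluated on them — a sample correlation over n
  genes scatters with sd ≈ 1/√n under the null (≈ 0.022 at n = 2,000), so a
  tight bound cannot hold simultaneously for all ~55 unplanted codons and is
  not asserted for them.
- **Cycle panels** — cells at uniform phase in [0, Tc), S-phase window of
  length Ts, so E[S]/P = Ts/Tc and E[L]/P = interval/Tc. A single
  10,000-cell panel gives Tc with sampling sd ≈ 2.4% (L is a binomial count
  with mean 1,500), so recovery checks average the estimator over six
  simulated embryos, matching how the assay is used in practice.
- **Shutoff series** — exponential decay with multiplicative lognormal
  noise; at log-sd 0.1 and 4 replicates the mean of per-replicate half-life
  estimates has sd ≈ 7.5% (the linear-space fit weights the early, large
  abundances most).
- **Expression counts** — negative binomial with variance m + φm², planted
  genes changing by a fixed fold between consecutive stages.

None of the generators model alignment artifacts, SNP masking, multimapping,
exon-level heterogeneity, batch effects, or library-composition biases; a
passing recovery test shows the estimators invert their own generative
models, not that real libraries are free of those artifacts.

## Problem sizes and numerical choices

Recovery benchmarks use 2,000 genes at coverage 1,000 per time point (chase),
2,000 genes × 300 codons (CSC), 2,000 null + 200 planted genes (temporal
screen), and 10,000 cells × 6 embryos (cell cycle); the bundled analysis
scripts run a 400-gene end-to-end study. Optimizer tolerances are 1e-12/1e-13
(xtol/ftol/gtol) so noiseless fits recover generating parameters to ~1e-9.
Degenerate inputs are annotated rather than raised wherever the QC layer owns
the decision (zero time-0 rate, non-convergence, zero profile variance);
corrupt inputs (converted > covered, out-of-frame CDS) raise immediately.

## Known limitations

- The simplified DE is not a negative-binomial GLM and should not be used on
  real count data when a dedicated DE package is available; the importer is
  the intended route for real data.
- The temporal screen assumes all genes present at every stage × replicate
  sample after QC intersection; unbalanced designs are not supported.
- The cell-cycle formulas ignore growth fraction and cell-cycle exit during
  the pulse interval.
- CSC treats transcripts as independent observations; phylogenetic or
  expression-level confounding between codon usage and stability is not
  modeled.
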