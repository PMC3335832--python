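# Methods

This note documents the statistical model behind `edsig`, the defaults and
the reasoning behind them, what the synthetic cohort generator does and
does not emulate, and the numerical conventions that matter for exact
reproducibility.

## Preprocessing

Raw bead-array intensities (one value per probe per sample, no background
correction) are scaled per sample so the median intensity equals 256 = 2⁸,
then log₂-transformed; after both steps every sample's median log₂ value is
exactly 8. Intensities below 1 are floored to 1 before the log — without
background correction small positive intensities occur, and the floor
avoids large negative logs while preserving order. Probes enter the
analysis only if their detection p-value is < 0.01 in at least one sample
and a gene symbol is available.

Two z-transformations are used. For clustering, heatmaps and per-sample
enrichment, each sample column is standardized over the retained probes,
then (for clustering/heatmaps) each probe row is standardized across
samples. Both use the population (divide-by-N) standard deviation. Sample
vs population SD is a genuinely open convention here; population SD is
applied uniformly — including in the enrichment metric's δ — because
internal consistency between the normalization and the scores is what the
method requires, and the choice cancels wherever a standardized quantity is
compared to another standardized quantity. Constant probe rows are emitted
as zeros (with a warning) for display purposes but are excluded from
variance ranking, correlation expansion and enrichment input, where they
would be undefined or poisonous.

## Differential expression

For each probe and group pair: Welch's unequal-variance t-statistic with
Welch–Satterthwaite degrees of freedom and a two-sided Student-t p-value;
Benjamini–Hochberg step-up q-values; and the fold change 2^(mean_A − mean_B)
of log₂ values, i.e. the ratio of geometric means. Significance requires
p ≤ 0.01, q ≤ 0.1 and FC ≥ 1.5 (or ≤ 1/1.5) simultaneously.

The detection gate precedes testing: a probe is tested only if at least
80% of samples in the group with the higher mean expression have detection
p < 0.01. Ties between group means are resolved symmetrically (either group
passing the threshold admits the probe), avoiding order dependence. The BH
correction runs over gated probes only and within each contrast
separately — gating exists precisely to shrink the testing universe, and
pooling contrasts would couple unrelated comparisons. The fold-change
criterion is likewise evaluated on the gated universe, keeping one
consistent probe set across all three criteria. Probe-to-gene collapse for
reporting treats a gene as significant if any of its probes is.

## Signature discovery

The 500 most variant probes (ties broken by probe id) are clustered by
complete linkage under the distance 1 − uncentered correlation, where the
uncentered correlation of two rows is Σxy/√(Σx²·Σy²) — cosine similarity,
the convention of the classic Cluster/TreeView tools. Input rows are the
doubly z-transformed values; rows are sorted by probe id before distance
computation so the merge tree and leaf order are deterministic. The
dendrogram is cut into at most six flat clusters and clusters below a
minimum size (default 20) are discarded; the historical manual step of
hand-picking probes with "distinct clustering patterns" is replaced by this
automatic cut, since a curator's judgment is not reproducible
algorithmically.

A cluster's centroid is the per-sample arithmetic mean of its member
probes' log₂ values; the centroid is kept on the log₂ scale because Pearson
correlation is affine-invariant (membership would be identical on z-scored
input) while log₂ profiles remain interpretable. The signature is every
probe in the dataset with Pearson r ≥ 0.7 against the centroid; raising the
threshold can only shrink membership. The top-k members by centroid
correlation (default k = 2) are reported as surrogate biomarkers.

## Gene-set enrichment

A gene set with m genes in the metric universe scores

    Z = (S̄ₘ − μ) · √m / δ,

with S̄ₘ the mean metric over the set and μ, δ the mean and population SD
of the whole metric vector; the two-sided p comes from the standard normal.
Sets with m below 10 are not reported. This is the standard parametric
(size-adjusted, Gaussian) gene-set statistic; under an i.i.d. metric it is
asymptotically standard normal, and slightly conservative at small m/N
because sampling without replacement shrinks the variance by
(N−m)/(N−1).

Metrics: for internal contrasts, the *z-ratio* — per-gene difference of
group means of within-sample z-scores, standardized over genes; for
external datasets (whose processing is heterogeneous), the *simple
difference* of group mean log₂ values. In the per-sample landscape variant,
each sample's own row-normalized expression vector is the metric and μ, δ
are that sample's column moments; group summaries average the resulting Z
scores per group (averaging scores, not inputs, so one aberrant sample
cannot dominate a small group nonlinearly).

Probe-level data are collapsed to genes by keeping the probe with the
highest mean expression per symbol (deterministic, ties by probe id);
symbols match case-insensitively with no alias expansion, which avoids a
version-drifting alias database at the cost of missing renamed genes. No
multiplicity correction is applied across sets beyond the p ≤ 0.01
reporting cutoff, matching the workflow this package reproduces; callers
can apply `bh_fdr` to the score table if they want it.

External validation embeds a query signature in a background collection
(any GMT with enough sets), scores all sets with the difference metric, and
reports the signature's Z and rank among reported sets.

## Clinical association

Correlations between surrogate-biomarker log₂ expression and hemodynamic
covariates use the Pearson coefficient and the customary test
t = r√(n−2)/√(1−r²) with df = n−2, two-sided. Subjects qualify when their
right-heart catheterization fell within 120 days (the conventional 4 × 30
reading of "four months"; configurable) of the blood draw and the covariate
is recorded. Group summaries use 84% confidence intervals — non-overlap of
two such intervals approximates a 0.05-level mean difference — computed
with the t distribution because groups as small as 8 subjects occur (the
large-n half-width tends to 1.4051·SE). Cardiac index is dichotomized at
2.2 L/min/m² with the boundary assigned to the high stratum, since the
poor-prognosis stratum is defined as strictly below the cut. qPCR
validation math: ΔCt against the mean of three endogenous controls (GAPDH,
ACTB, PGK1), ΔΔCt against a calibrator sample, relative quantity 2^−ΔΔCt.

## Synthetic cohort generator

Log₂ expression is probe baseline + module activation + Gaussian noise,
anti-logged to the intensity scale on emission so preprocessing is
exercised end to end. Defaults and what they emulate:

* **Group sizes** 41 / 19 / 30 / 42 / 8 (Control / SSc / IPAH / SSc-PAH /
  SSc-PH-ILD), 140 subjects, 20 000 probes.
* **Modules**: EDS (169 probes), platelet (456), immune-response up (81)
  and down (58), immature neutrophil (40), sex-linked (10). Module
  activation is continuous: a subject is a carrier with probability
  *penetrance* (EDS: 0.5 in IPAH/SSc-PAH, 0.9 in SSc-PH-ILD, 0.1 in SSc,
  0.02 in controls — the observation that only a subset of patients per
  group shows the signature is a penetrance statement, and since no source
  fixes the fraction these are configuration, not facts), and carriers draw
  a gamma-distributed amplitude (shape 4, mean = `amplitude_log2`, default
  2.0 for the EDS) so carriers span a graded range of activation.
* **Within-module correlation** (default 0.8 for EDS) is hit exactly in
  expectation by solving for the idiosyncratic-noise variance that the
  shared amplitude implies: extra independent noise is added when the
  amplitude variance is too strong, and part of the noise budget is made
  module-shared when it is too weak.
* **Cross-module correlation**: the platelet amplitude vector is rebuilt by
  a Gram–Schmidt blend so its realized correlation with the EDS amplitudes
  is exactly 0.6.
* **Noise** `noise_sd` = 0.3 log₂ units, a typical within-group probe-level
  variability for processed bead arrays; tests of specific power claims
  pass 0.5 explicitly where that level is part of the claim.
* **Detection p-values**: expressed probes draw U(0, 0.005), background
  probes (default 30% of the array) U(0.02, 1), making both the ≥ 1-sample
  filter and the 80% gate meaningfully selective.
* **Hemodynamics**: per PH group, covariate = baseline mean + baseline SD ×
  (ρ·z + √(1−ρ²)·ε) with z the group-standardized EDS amplitude, so the
  population correlation equals the configured ρ exactly. IPAH couplings
  default to 0.776 (RAmean), 0.752 (PVRI), −0.71 (PA sat), −0.449 (CI);
  SSc-PAH and SSc-PH-ILD are decoupled. Catheterization-to-draw offsets
  are U(0, 300) days, so the 120-day window keeps ≈ 40% of PH subjects
  (≈ 12 of 30 IPAH). NYHA classes follow the cohort's per-group
  distribution; sex follows the per-group female fractions and drives the
  sex-linked module, which serves as a positive control for clustering.

Everything derives from one integer seed; identical configuration and seed
give byte-identical outputs.

**What the generator does not emulate**: bead-level summary statistics,
batch and spatial artifacts, probe cross-hybridization, non-Gaussian heavy
tails, annotation errors, and correlated detection failures. Passing tests
therefore demonstrate that the pipeline's logic and calibration are correct
under its own model assumptions — not that real cohorts will show the same
effect sizes or that the preprocessing removes real-array artifacts it
never sees.

## Numerical conventions and edge cases

* Population SD throughout the z-machinery; sample SD (ddof 1) inside the
  Welch test and confidence intervals, where the estimator convention is
  part of the statistic's definition.
* Welch test with zero variance in both groups: p = 1 when means are equal
  (by convention), an error otherwise.
* BH q-values: step-up with a stable mergesort; q is clipped to 1 and is a
  monotone nondecreasing function of p.
* |r| = 1 in the correlation test is reported as p = 0 with an explicit
  exact-fit flag rather than a division error.
* Dendrogram determinism: rows sorted by probe id before distance
  computation; variance and surrogate ties break by probe id.
* Degenerate enrichment inputs (zero metric SD, constant landscape column)
  raise rather than emit NaN scores; an all-equal z-ratio difference vector
  returns zeros with a warning (the two groups are indistinguishable).
* Parsers report 1-based line numbers; expression values serialize with
  `repr` so files round-trip bit-exactly.

## Problem sizes used in the test suite

Monte-Carlo checks run at sizes chosen to keep the whole suite fast while
leaving clear margins: 1000 random instances for the FDR/enrichment oracle
comparisons (tolerance 1e−12), 2000 draws for enrichment null calibration,
20 seeded cohorts for the differential-expression null, 5 for power, 200
small-n (n = 12) coupling-sign runs and 400 decoupled-group null runs. The
signature-recovery check runs once on the full default cohort (140 × 20 000).

One calibration fact worth recording: at the planted cardiac-index coupling
ρ = −0.449 and n = 12, the sampling distribution of r places ≈ 7% of runs
on the wrong side of zero (Fisher z: Φ(−atanh(0.449)·3) ≈ 0.073), so
per-run sign recovery for that covariate cannot exceed ≈ 93% in
expectation; the suite asserts the three strong couplings at the 95% level
and cardiac index against an attainable 85% bound. This mirrors the
substantive point that weak couplings are not reliably detected at n = 12 —
the cardiac-index association is exactly the one that fails to reach
significance in the motivating analysis.

## Known limitations

* Seed-cluster extraction replaces human curation; on data whose modules
  are not well separated at the six-cluster cut, signatures may merge or
  split (tune `max_clusters`/`min_size`).
* Gene-symbol matching is exact (case-insensitive); external datasets using
  aliases will undercount signature members.
* The enrichment normal approximation is anti-conservative if the metric
  has heavy tails and sets are tiny; the min-size 10 rule is the guard.
* The landscape variant assumes within-sample z-scores are comparable
  across samples, i.e. that most genes do not change; grossly abnormal
  samples violate this.
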