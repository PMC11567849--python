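# Methods

This note documents the statistical model behind each stage of `txconn`,
the assumptions of the synthetic-data generators, the numerical choices, and
the known limitations.

## Seed-based connectivity

Each scan is a 4D array on a voxel grid with an affine to millimetre (MNI)
space.  The seed is a sphere in millimetre space (default: left angular
gyrus, MNI −45, −67, 38, radius 6 mm); a voxel belongs to the seed iff its
centre lies within the radius.  On a 3 mm grid with the centre on a voxel
centre this yields exactly 33 voxels (integer offsets with squared norm
≤ 4).

Nuisance regression projects each voxel series onto the orthogonal
complement of an intercept plus the confound columns (six motion parameters
and the mean white-matter and CSF series in the intended use).  Collinear
confound columns are dropped via pivoted QR with a warning rather than
erroring, since motion parameters from short scans are occasionally
degenerate.  Residuals are orthogonal to every retained column to machine
precision.

The connectivity map is the Pearson correlation of the mean residual seed
series with every voxel's residual series, transformed to *z* = atanh(*r*).
*r* is clipped to ±(1 − 10⁻⁷) before the transform, keeping *z* finite
(|z| ≤ ~8.4) with bias far below sampling noise.  Zero-variance voxels
(out-of-brain padding) get *z* = 0 and a flag instead of an error so that
all subjects share one grid.  Inputs are assumed already preprocessed
(slice timing, realignment, normalization, band-pass filtering are out of
scope); the generator produces band-limited series directly.

We correlate against the mean seed series itself; "signal change"
phrasings in the literature are ambiguous between the mean series and its
temporal derivative, and the mean series is the standard choice for
seed-based FC.

## Group × timepoint interaction

For the balanced 2×2 mixed design (group between, session within, subject
nested in group) the three F statistics have closed forms via the
difference-score identity:

* interaction: two-sample *t*² on per-subject differences *d* = *z*₂ − *z*₁,
  df = (1, n₁+n₂−2);
* group: two-sample *t*² on per-subject means;
* session: the unweighted mean of the group difference-means against the
  same pooled within-subject error.

These equal a general linear model with subject dummy coding (verified to
10⁻⁸ against an OLS oracle on random instances) and SPM's flexible
factorial for this design.  A dedicated formula is used instead of a
generic mixed-model fitter because it is exact, fast enough to run
voxelwise, and directly testable.  Subjects missing a session are excluded
with a warning.

**Smoothness estimation.**  Residual change maps (per-subject difference
minus its group mean) estimate the per-axis noise FWHM from the variance of
neighbour differences: for a Gaussian autocorrelation,
var(x₍ᵢ₊₁₎ − xᵢ) = 2σ²(1 − ρ) with ρ = exp(−Δ²/4s²), giving the kernel
scale *s* and FWHM = 2.355·s, floored at the voxel size (white noise).
Recovery is within 20% for known kernels on the simulated grids.

**Monte-Carlo cluster-extent threshold.**  Stationary Gaussian fields
(periodic-boundary smoothing, standardized within the mask) at the
estimated FWHM are thresholded two-sided at the voxel *p* (F tests are
thresholded at the equivalent F quantile), and the maximum cluster size per
iteration is recorded.  The returned extent is the smallest integer *k*
with empirical P(max ≥ *k*) ≤ α — the AlphaSim convention.  Because
cluster sizes are integers, the realized family-wise rate is the largest
attainable value below α (e.g. ≈ 0.04 rather than 0.05 on a 12³ grid),
never above it.  Cluster connectivity defaults to 18 (configurable 6/18/26);
the Monte-Carlo iteration count defaults to 1000 with the seed logged.

A cluster-size threshold such as "6165 mm³" is a dataset-specific *output*
of this procedure (it depends on the mask, smoothness, and α), not a
constant of the method.

**Known limitation.**  The single-field Gaussian Monte-Carlo null is the
classic AlphaSim model.  Against *t*/F statistic fields computed from
smooth per-subject maps it is anti-conservative (the spatially smooth
variance estimate in the denominator inflates cluster sizes), a documented
property of cluster-extent inference.  Calibration checks therefore use
cohorts with independent-voxel noise, where the supra-threshold pattern is
i.i.d. Bernoulli regardless of the statistic's marginal distribution and
the correction is exact up to integer-size granularity.

## Behavioral composites

The memory composite z-scores each of the four tests against the mean and
SD of *all* rows passed in (all subjects, both sessions pooled — keeping
pre and post on one scale) and sums the four z's; a zero-variance test is
an error naming the test.

The sleep index standardizes the five scale totals, takes PC1, and fixes
the sign so the ISI loading is negative: all five scales score sleep
*badness*, so higher PC1 = better sleep, making "below the median → low
sleep quality" semantically consistent.  Subjects strictly below the median
PC1 are labelled CI+LSQ, the rest CI+HSQ; at-median subjects go to the
high-quality group, and with an even number of distinct scores the split is
exactly half/half (23/23 at n = 46).  Constant scales are dropped with a
warning; fewer than two remaining is an error.

Adjusted correlations residualize both variables on an intercept plus the
covariates (age, education, sex coded 0/1, sleep-status group) and report
the Pearson correlation of the residuals — algebraically the partial
correlation — with p from *t* on df = n − k − 2.  This satisfies both a
"Pearson with covariates" and a "partial correlation" reading.

## Transcription–neuroimaging association

Samples are retained iff their coordinate falls in an interaction-mask
voxel or within 2 mm of a mask-voxel centre (tolerance for atlas samples
lying just off the grid).  Each retained sample receives the mean of the
cohort-level connectivity-change volume (mean over subjects of follow-up −
baseline *z*) over mask voxels within a 6 mm sphere — the same spatial
scale as the seed — with radius 0 meaning the containing voxel.  Gene-wise
association is the Pearson correlation across retained samples with
two-sided *t* p-values; zero-variance genes are excluded and flagged.
Selection uses Benjamini–Hochberg at *q* < 0.001, with significance taken
from the step-up decision itself (equivalently *q* ≤ threshold, so a gene
landing exactly on the boundary is selected).

**Spatially constrained permutation null.**  Gene-wise p-values assume
exchangeable samples, but both expression and connectivity maps are
spatially autocorrelated, which inflates the significant-gene count.  The
null therefore preserves spatial structure: a Gaussian variogram model
γ(h) = nugget + psill·(1 − exp(−h²/2ρ²)) is fitted to the empirical
semivariogram of the imaging vector (25 bins to the 70th distance
percentile, weighted by pair counts), surrogate vectors are drawn from the
implied Gaussian process at the sample coordinates (Cholesky factor with a
jitter ladder), and each draw is rank-remapped to the original value
multiset.  Surrogates thus share the original's marginal distribution
exactly and its variogram to within sampling noise (integrated absolute
deviation ~8–13% on the simulated geometries, at the level of independent
same-process realizations), while their alignment with expression is
random.  The permutation p is the add-one estimator
(k+1)/(n+1); with 500 surrogates its floor is 1/501 ≈ 0.002.  Plain
shuffling (`surrogate="shuffle"`) is retained for comparison and is
demonstrably anti-conservative on smooth data — the reason the constrained
null exists.  Degenerate geometry (coincident samples) falls back to plain
permutation with a warning.

Mask restriction acts on samples only; all genes in the dataset are tested
(no differential-stability pre-filter — upstream atlas processing is
consumed, not re-implemented).

## PPI analysis

Edge tables use the STRING dialect: columns node1/node2/combined_score,
scores on [0,1] or integers 0–999 (any value > 1 switches the whole table
to the integer reading, divided by 1000).  Self-loops are dropped and
symmetric duplicates merged keeping the maximum score.  The candidate
subnetwork is the induced subgraph on the significant genes with edges
re-filtered at ≥ 0.9 and isolated nodes removed; membership in the
"interconnected network" is degree ≥ 1 at that threshold.

Enrichment compares the observed induced-edge count with counts from
uniform random same-size node sets drawn from all graph nodes; the expected
count is the null mean and p = (k+1)/(n+1).  When C(N, k) is small
(≤ 10⁵) all subsets are enumerated instead of sampled.  This explicit,
reproducible null replaces database-server background models whose
internals are not specifiable; its expected counts and p-values are
therefore not comparable to server-reported ones.  Hub genes are the first
⌈0.10·N⌉ nodes by descending degree, ties broken lexicographically for
determinism.

## Synthetic generators: what they emulate, and what they don't

**BOLD cohort.**  Every in-mask voxel series is x(t) = w·s(t) + σ·ε(t):
a shared per-scan seed time course s (white noise, temporally smoothed with
a 0.75-volume Gaussian to emulate band-limited data, standardized) scaled
by a coupling weight w, plus Gaussian noise spatially smoothed to the
design FWHM (6 mm default; a setting at or below the voxel size means
independent voxels) and mildly contaminated by the confound series (which
nuisance regression removes).  The seed sphere itself has strong coupling
(w = 1.2σ), the rest of the mask weak baseline coupling (0.2σ).  Inside
planted clusters the coupling changes from baseline to follow-up by
+d·σ in group 1 (CI+LSQ) and −d·σ in group 2 — a pure interaction with
zero session main effect — with per-subject effect heterogeneity
(SD 0.25·d) that drives the behavioral coupling.  The FC ground truth is
analytic: r(w) = w/√(w²+σ²), z = atanh(r).  Planted clusters are validated
to lie inside the brain mask and to be disjoint from the seed sphere
(overlap would overwrite the seed coupling and corrupt the ground truth).
Not emulated: hemodynamic response shapes, physiological noise spectra,
motion artefacts beyond linear confound leakage, multi-echo acquisition —
so passing tests certify the statistics, not robustness to un-modelled
artefacts.

**Phenotype.**  A latent sleep-quality factor (group means ±1, SD 0.6)
loads negatively on all five scale totals, so PC1 of the scales recovers
the grouping (≥ 80% agreement at the default noise).  Memory tests have
plausible baseline distributions; their follow-up change is a common gain
plus a term proportional to the subject's *within-group standardized*
planted connectivity change at correlation 0.5, plus noise.  Defining the
coupling on the within-group variation matters: downstream correlations
adjust for sleep-status group, which absorbs any between-group component.
Measured recovery: r > 0 with p < 0.05 in 9/10 seeded runs at 23 subjects
per group.

**Expression.**  Samples sit at random mask-voxel centres with sub-voxel
jitter; donors (6 by default) contribute random intercept offsets
(SD 0.3).  Noise genes are spatially autocorrelated via Gaussian-kernel
mixing over inter-sample distance, with kernel width L/√2 so the *field*
autocorrelation length equals the stated parameter L (kernel
self-convolution).  L defaults to 5 mm — short relative to AHBA's ~8 mm
mean sample spacing, consistent with expression similarity decaying over a
few millimetres at this sampling density.  Planted genes are constructed
as r·t̂ + √(1−r²)·n̂⊥ with the noise component orthogonalized against the
standardized target values, so their cross-sample correlation is exactly
the target before donor offsets (attenuation ≈ 4% after).  Default scale
(2000 genes, 300 samples, 50 planted at r = 0.8) is a reduced-scale
emulation of a 15,633-gene × 3121-sample atlas matrix.  Calibration and
recovery studies place the samples in a brain-scale 40³-voxel (120 mm)
volume, mirroring atlas sampling of the whole brain; at this geometry the
aggregate empirical FDR of BH selection is ~1% (measured over 40 seeds)
and planted-gene recovery is complete.  Not emulated: probe-level noise,
donor-specific expression structure, hemispheric asymmetries.

**PPI background.**  Erdős–Rényi G(n, p) with an optional planted module
(extra within-subset edge probability) and uniform scores on [0.4, 1]
written in the integer dialect.  Node names follow the synthetic gene
naming so the table composes with the expression generator.

## Problem sizes used in the validation suite

Simulations are scaled so the full suite runs in minutes on one CPU while
keeping every check at a meaningful Monte-Carlo resolution: 12³–16³ voxel
grids at 3 mm, 60–120 time points, 6–23 subjects per group; the null
calibration of the cluster threshold uses 2000 (tests) or 500 (acceptance
script) replicate null cohorts of 6 + 6 subjects, and the planted
transcriptomics studies use 2000 genes × 300 samples with 500 surrogates.
Tolerances follow the Monte-Carlo standard error at those sizes (e.g.
voxelwise rate within 3·SE; family-wise rate within ±0.02).

## Degenerate inputs and tie-breaks

Zero-variance voxels → flagged z = 0; rank-deficient confounds → collinear
columns dropped with a warning; constant sleep scales → dropped, error if
fewer than two remain; zero-variance memory test → error naming the test;
at-median PC1 scores → high-quality group; constant genes → excluded and
flagged; samples with no mask voxel in the sphere → dropped with a warning;
coincident sample coordinates → unconstrained permutation with a warning;
hub-degree ties → lexicographic; empty candidate subnetwork → warning and
empty graph, not an error.
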