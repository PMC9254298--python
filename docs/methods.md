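# Methods notes

## Model and assumptions

The pipeline treats a serum small-RNA sequencing experiment as a
feature × sample matrix of non-negative integer counts over four
clinical groups (control, T1D, T2D, LADA), with three structural
assumptions:

* **isomiRs are the primitive unit.** A mature miRNA's count is defined
  as the exact per-sample sum of its isomiRs' counts. The synthetic
  generator builds matrices this way, and the validators enforce the
  parent relationship.
* **Counts are negative binomial** with the edgeR-style common
  dispersion parameterisation, variance = μ + φμ². This is the
  mean–variance behaviour the precision-weighting step is designed
  for: on the log₂ scale the variance of a count is approximately
  (1/μ + φ)/ln²2, monotonically decreasing in abundance, which is what
  the lowess trend captures.
* **Spike-in calibrators measure technical yield.** The per-sample
  technical factor (library-preparation efficiency for biological RNA)
  multiplies every biological feature's expectation but not the
  calibrators', whose expectations track only the input amount and
  sequencing depth. This is the identifying assumption that makes
  calibrator normalization work, and the generator encodes it
  explicitly so the tests can verify recovery.

## Normalization

TMM on the calibrator submatrix with the conventional constants
(M-trim 0.30 per side, A-trim 0.05 per side, inverse-delta-method
precision weights, reference column chosen by the 75th-percentile rule).
Two open choices were resolved as follows:

* **Denominator of the calibrator proportions.** Proportions are taken
  relative to the *biological* library size (column sums excluding
  calibrators). Under this convention a sample with poor technical
  yield has inflated calibrator proportions and receives a factor < 1,
  so effective library sizes estimate input RNA amount — the stated
  purpose of the spike-ins. Taking proportions relative to total reads
  including calibrators would shrink but not remove this signal; the
  calibrator-exclusive convention is also what keeps downstream cpm
  values on a per-biological-read scale.
* **Library sizes elsewhere.** Biological library sizes exclude
  calibrator counts throughout (filtering, cpm, voom). The calibrator
  fraction of a library is small (≈ 2 % in the generator), so the
  alternative inclusive convention would change results marginally;
  the exclusive one is self-consistent with the factor definition.

The implementation agrees with edgeR's `calcNormFactors(calib,
lib.size=bio_lib, method="TMM")` to machine precision (cross-checked in
the test suite via Rscript).

## Differential expression

The log₂-cpm transform uses prior count 0.5 and denominator
(effective library size + 1); the trend is a lowess fit (span 0.5,
3 robustifying iterations, R-style delta = 1 % of the x-range) of
√(residual SD) on mean log₂ count; weights are the interpolated trend
value at each observation's predicted log₂ count raised to the −4
power, extrapolated flat outside the trend support. Variance
moderation estimates (d₀, s₀²) by matching the mean and variance of
log s² to a scaled-F model, inverting the trigamma function by Newton
iteration (tolerance 1e-8); d₀ is capped at 1e7 to represent infinity,
in which case the prior variance is the arithmetic mean of the sample
variances and the total degrees of freedom are capped at the pooled
residual df. The whole chain reproduces limma's `voom` + `lmFit` +
`eBayes` + `topTable` to 1e-10 on shared inputs (cross-checked in the
test suite).

Design matrices use treatment coding with the first-named group of a
comparison as reference, so reported log₂ fold changes are
second-vs-first. Sex is coded female = 0 / male = 1 (the contrast is
invariant to this choice). Continuous covariates enter unscaled.
Missing mandatory covariates (age, sex, BMI) are a hard error rather
than being imputed, because every model adjusts for them; optional
covariates (diabetes duration, the 30–33 nt fragment-length abundance)
are requested explicitly and error when absent. The fragment-length
covariate is log₂(1 + total counts in the closed 30–33 nt range); the
log scale keeps it commensurate with the response scale of the linear
model.

Expression filters are inclusive at the 1-cpm boundary ("at least
1 cpm"), use calibrator-normalized effective library sizes, and are
applied after factor computation but before the weighted fit — the
standard ordering. Each feature class is filtered and tested
separately (mature miRNAs: all samples; isomiRs and other sRNAs: ≥ 50 %
of samples), sharing global library sizes and factors. The engine
refits the trend per pairwise comparison rather than once across all
four groups; this matches building the design from "the groups being
compared" and keeps each contrast's variance model local to its data.

## Signatures and cross-validation

The prediction rule for a held-out sample is the direction-aligned
standardised mean over the signature's features,
score = mean(direction × (x − m)/s) with (m, s) from the training
samples. This rule was chosen because it is parameter-free: there is
nothing to tune inside a leave-one-out training fold of ~100 samples,
it is monotone in every selected feature, and its null distribution is
symmetric around 0. It is a deliberate, documented choice — different
predictors will give numerically different AUCs on the same data.

Nesting: the expression filter, the weighted fit, the BH adjustment,
the signature selection and the standardisation constants are all
recomputed on every fold's training set. Normalization factors are the
single exception: they are per-sample technical quantities derived
from spike-ins without access to group labels, so computing them once
globally cannot leak label information into the scores. Empty
signatures (no feature significant in a fold) score 0 — the
class-ambiguous value — and are counted and reported, preserving
exactly one out-of-fold score per sample. A non-nested mode (selection
once on all samples) exists solely to demonstrate the optimistic bias
that nesting avoids; the tests require its null AUC to exceed the
nested mode's.

AUC is the Mann–Whitney estimator with mid-rank tie handling; the 95 %
confidence interval is the DeLong structural-components Wald interval
truncated to [0, 1] (degenerate (a, a) under perfect separation); the
p-value against AUC = 0.5 is the one-sided normal approximation to U
with tie-corrected variance. Orientation is fixed: higher scores
predict the second-named group, and AUCs below 0.5 are reported as-is.
DeLong intervals agree with pROC's `ci.auc` (cross-checked).

## Synthetic data generator

Defaults describe one cohort of the study design: 4 × 50 samples,
~600 features (98 mature miRNAs × 2 isomiRs each, 296 other sRNAs of
which half are tRNA fragments with lengths 28–36 nt, 10 calibrators),
mean biological depth 2 × 10⁶ reads (the order of small-RNA-aligned
reads per library in serum sRNA-seq), depth CV 0.3, dispersion
φ = 0.1 (a typical biological dispersion for bulk RNA-seq),
technical-yield SD 0.3 log₂ units, calibrators at 2 % of the library
spanning a 32-fold concentration ladder. Calibrators use a separate
dispersion of 0.005 because spike-ins carry only technical (near-
Poisson) noise, not biological variability. Group effects default to
|log₂ FC| = log₂ 1.5 — the minimum fold change in the study's power
statement — applied to a designated group (default T2D) for a
`frac_de` fraction of units, where a unit is a mature miRNA (with all
its isomiRs moved together, so the parent sum shifts by exactly the
same fold change) or a single other sRNA. Clinical covariates are
drawn per group from normal distributions matching the published
cohort descriptives (e.g. controls ~53 ± 16 y vs LADA ~68 ± 9 y), so
age–group confounding is present whenever age expression effects are
switched on.

What the generator does **not** emulate: sequence content and mapping
artefacts, zero inflation beyond the NB, correlated features,
batch/run structure, and the study's actual (undeposited) count
distributions. Passing tests therefore demonstrate statistical
correctness of the machinery under the model it assumes, not numerical
agreement with the original cohort's feature lists or AUCs.

## Problem sizes in the verification suite

The statistical guarantees are checked at sizes chosen to balance
Monte-Carlo resolution against desk-scale runtimes: FDR control on 100
null cohorts of 4 × 20 samples and ~500 features; nested-vs-non-nested
cross-validation on 50 null cohorts of 4 × 20 samples and ~200
features (the null behaviour of LOOCV does not depend on cohort size);
signal recovery at the full study design size (4 × 50, 600 features);
DeLong coverage and p-value uniformity on 1000 replicates of 40 and 20
samples per class respectively; power at 50 per group over 10
replicates with common random seeds across grid cells.

## Known limitations

* The moderated-t chain assumes the design is identical across
  features; per-feature missingness is not supported.
* `anova_screen` tests each clinical variable marginally (the
  per-response F-tests a MANOVA summary would report) and applies
  Bonferroni across variables; it is a descriptive screen, not a joint
  model.
* The power module estimates power for this pipeline on generator
  conditions; it deliberately does not reproduce analytic
  NB sample-size calculations, and its numbers are not comparable to
  power figures computed from a different cohort's dispersion and
  depth estimates.
* Missing clinical values in optional covariates exclude the variable
  from the design (hard error if requested) rather than imputing or
  dropping samples silently.
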