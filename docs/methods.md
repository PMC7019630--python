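# Methods

## Scope and model

The package implements the complete validation workflow for two-class
PLS-DA on a targeted metabolite panel: cohort simulation, model fitting,
repeated double cross-validation (DCV), permutation-based significance,
VIP variable selection, and descriptive cohort statistics. The class
label is coded case = 1 / control = 0 everywhere.

PLS-DA is fitted by NIPALS with a single centred dummy response. For a
univariate response the weight update is closed-form (w ∝ Xᵀy, unit
norm), so each component costs two matrix–vector products plus a rank-one
deflation of X and y. Training scores are mutually orthogonal and, when
the component count equals the rank of the scaled predictor matrix, the
fitted values coincide with ordinary least squares — both properties are
enforced by the test suite, alongside a prediction-level cross-check
against an independent PLS implementation.

## Preprocessing and decision rule

Predictors are autoscaled (mean-centred, divided by the column sample SD,
n−1 denominator). The panel spans three orders of magnitude (≈ 0.25 to
≈ 570 µmol/L), so unit-variance scaling is the only way every analyte can
contribute to the covariance criterion; it is the standard choice for
concentration panels. Scaling parameters are always computed on training
folds only and frozen before any held-out sample is touched — the suite
contains a planted-outlier test proving that perturbing a test-fold
sample cannot move the predictions of its fold mates.

Class assignment thresholds the predicted response at 0.5, the midpoint
of the label coding; a score exactly at the threshold goes to class 0,
deterministically. The threshold is a parameter (`DCVConfig.threshold`,
`pls_fit(threshold=...)`) for users who prefer a prior-adjusted cut.

## Double cross-validation

Defaults: 5 outer folds × 5 inner folds, 20 repetitions, complexity
scanned over 1..10 latent variables. Five-fold splitting keeps six
controls in every outer fold at the default 30-control arm; ten
components is ample for a panel whose information concentrates in the
first two LVs. The inner loop selects the LV count minimising the pooled
inner-CV misclassification count, ties broken toward the simpler model;
the selected complexity is refitted on the full outer-training set and
scored once per sample in the outer loop. Rates are reported on a 0–100%
scale as mean ± SD across repetitions, overall and per class, separately
for the calibration (outer-training), inner-CV and outer-test stages.

Randomness follows a single master seed: per-repetition child generators
are spawned from a `SeedSequence`, and the permutation loop draws from a
disjoint branch of the same tree, so every result is bit-reproducible
and the permutation null is independent of the observed splits.

## Permutation test

Each of the B permutations (default 1000) shuffles the labels uniformly
and re-runs the *same* repeated-DCV pipeline, with the per-permutation
repetition count reduced to 5 to bound cost — the null statistic must be
produced by the same estimator as the observed one, and 5 repetitions
keep its Monte-Carlo error well below the null spread. The comparison
statistic is the across-repetition mean of the pooled outer figure.
P-values use the add-one estimator (b + 1)/(B + 1) — counting null NMC ≤
observed, and null AUROC/DQ2 ≥ observed — whose floor is 1/(B + 1).

DQ2 zeroes residuals that overshoot their own label in the correct
direction (cases predicted above 1, controls below 0), so DQ2 ≥ plain Q²
on every input; this keeps the statistic from punishing confident
correct predictions.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes: 66
cases and 30 controls, 37 analytes of which 9 carry the published
class-conditional means ± SDs (taurine, glutamic acid, sarcosine,
alanine, arginine, ethanolamine, 3-methylhistidine with standardised
differences 0.7–1.8; tryptophan and ornithine with ≈ 0.2) and 28 carry
no class effect. The non-discriminant analyte identities were not
published, so the default background uses placeholder names at typical
fasting-serum magnitudes, identical in both arms; any panel can be
substituted via a template CSV.

Analytes are drawn independently per class — the templates specify only
marginal moments, and simulating exactly what is parameterised keeps the
generator honest about what it can and cannot claim (see Limitations).
Concentrations are non-negative by rejection-resampling from a normal
truncated at zero. Truncation shifts the mean of a naive truncated
normal upward (by ≈ +4 µmol/L for the glutamic-acid case arm, 2.6%
truncation mass), so the latent location is calibrated by a Brent
root-find such that the truncated draw has exactly the template mean;
SDs are left at their template values (the corresponding SD shrinkage is
second-order). Rejection rather than clamping preserves unimodality.

Clinical covariates (age, sex, BMI, SPPB, disease count) are drawn per
class from the published summary moments; SPPB is rounded and clamped to
its 0–12 range, sex is Bernoulli on the published female fraction, other
covariates stay continuous.

## Descriptive statistics

Continuous covariates are compared by a pooled-variance t-test when both
groups pass a Kolmogorov–Smirnov normality check at α = 0.05, and by
Mann–Whitney U otherwise; the KS test uses estimated parameters, so it
inherits the Lilliefors caveat (mildly anti-conservative gate). The
pooled (not Welch) t-test reproduces the published BMI comparison
(t = 2.65, df = 94, p = 0.0095 → 0.01) from the printed summaries,
whereas Welch gives ≈ 0.001 — evidence the original analysis pooled
variances. Sex uses the Yates-corrected 2×2 χ², which gives p = 0.827
against the published 0.82 (the uncorrected statistic gives 0.66). The
test chosen is always recorded in the output. A summary-statistic
variant (`pooled_t_from_summary`) re-tests printed "mean ± SD, n" rows
without raw data.

## What the simulations do and do not show

Passing tests demonstrate that the pipeline recovers planted structure
at realistic sizes, that its estimators agree with independent oracles,
and that its null behaviour is calibrated (label-shuffled and
no-effect cohorts are non-significant; effect-size ladders move p
monotonically). They do **not** show that real serum panels would yield
the published accuracy: the generator reproduces marginal moments only,
while real amino-acid panels are strongly correlated, and correlation
structure can add (or remove) linear separability. Quantitatively, under
independence the population-optimal linear classifier on the default
template reaches 95.5% accuracy (Bayes-optimal quadratic: 98.2%), and
cross-validated PLS-DA at n = 96, p = 37 attains ≈ 93% (case) / 92%
(overall) outer rates — a few points below the rates reported on the
real, correlated data. Likewise, weak discriminants with standardised
differences ≈ 0.2 (tryptophan, ornithine) have point-biserial
correlations (~0.09) statistically indistinguishable from null-analyte
sampling noise (SD ~0.10) at this sample size, so VIP selection
reliably recovers the seven strong effects but not those two.

## Numerical choices and degenerate inputs

- Zero-variance predictor columns raise an error naming the column (no
  silent drop); NIPALS raises if the deflated response becomes
  orthogonal to the predictors (weight norm < 1e-12).
- The component count is validated against min(n−1, p); the inner loop
  additionally caps it by the smallest inner-training-fold size.
- Stratified folds differ by at most one sample per class per fold and
  raise when a class is smaller than k.
- AUROC uses mid-rank tie handling; it equals the exhaustive
  case–control pair count on every input.
- CSV ingestion refuses missing cells, non-numeric cells, unknown class
  tokens and absent label columns with distinct error types; there is no
  imputation.
- Reports are JSON (schema-versioned, config echoed) with TSV side
  exports; null histograms are binned over the exact null support so
  counts sum to B and empty bins are preserved.

## Known limitations

- No covariance structure between analytes and no batch, drift or
  missing-data mechanisms; the generator is a statistical, not an
  analytical-chemistry, emulation.
- Binary classification only; no multiclass, orthogonal-PLS or sparse
  variants.
- The permutation test re-runs DCV with a reduced repetition count per
  permutation (default 5); single-repetition nulls are available via
  `permutation_repetitions=1`.
- VIP is computed on one final model fitted at the inner-CV-selected
  complexity on all samples; selection stability across resamples is
  left to the user.
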