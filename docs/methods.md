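# Methods

This note documents the models, numerical choices and defaults behind
`ba_diag`, and what the synthetic data do and do not establish.

## Intensity normalization

Ultrasound devices differ in gain and dynamic range, so each image is
mapped affinely to a common scale before any feature is computed:

```
out = (in − mean(in)) / IQR(in) · 40 + 55
```

with IQR = Q3 − Q1 computed by linear interpolation between order
statistics (the `quartile_method` is configurable; any numpy percentile
rule is accepted). Because the map is affine with positive slope, the
output mean is exactly 55 and the output IQR exactly 40, the operation is
idempotent, and any device-side transformation `aX + b` (a > 0) that does
not clip is removed entirely — features extracted downstream are invariant
to it. Values are kept as real numbers and may leave [0, 255]; clipping
and rounding to 8-bit happen only when an image is exported. An image with
zero IQR cannot be normalized and is reported as degenerate by source id.

## ROI delineation

Crop boxes are 0-based, row-major, half-open `[r0, c0, r1, c1]`. Inside a
crop the structure is segmented by a fixed morphological pipeline:
Gaussian smoothing (σ = 2 px) → global Otsu threshold → keep the dark side
for fluid-filled structures (gallbladder) or the bright side for echogenic
ones (triangular cord) → binary opening then closing with a disk of
radius 3 px → keep the largest 8-connected component → fill holes. All
knobs are exposed in `MorphologyConfig`; the defaults were chosen once on
phantom scenes and give intersection-over-union ≥ 0.8 against ground-truth
masks at high contrast. An empty result raises a delineation failure and
the view is treated as missing downstream — it is never silently imputed
at the segmentation stage.

## Features

Per view: quantiles at levels {0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95}
plus mean/median for the masked ROI and for the whole crop (gray-scale
features), absolute mask area in pixels and its ratio to the crop area
(size features), and the population standard deviation (ddof = 0) of ROI
and crop intensities (texture features) — 22 features per view, 66 per
patient over the three views (gallbladder, triangular cord at the
portal-vein branches, transverse right portal vein), plus a 0/1
availability indicator per view. A patient qualifies with at least one
delineated view; missing views are imputed with training-cohort medians
and flagged by the indicator. Patients with no usable view are excluded
with an explicit signal carrying the patient id.

## MMP-7 rule

Replicates (up to three) are averaged arithmetically; the 20-fold dilution
factor is applied only when readings are flagged as pre-dilution, since
reported concentrations are normally already back-calculated. Positivity
uses strict inequalities: > 18 ng/mL above 30 days of age, > 28.1 ng/mL at
or below 30 days. Age exactly 30 days falls in the younger stratum. The
boundary behaviour at exactly 28.1 ng/mL is taken as negative (strict
">"), which is the literal reading of the rule.

## Diagnostic models

Numeric features are min–max scaled to [0, 1] with bounds learned on the
training cohort only; validation data reuse those bounds and are not
clipped, so out-of-range cases keep their leverage. Constant features are
dropped with a warning. Variable selection uses an L1-penalized logistic
path with the per-observation penalty convention (objective ∝ mean
log-loss + λ‖w‖₁), making selection invariant to duplicating the dataset
at fixed λ. λ is chosen on a 30-point log grid from the smallest
all-zero λ down three decades, by stratified 5-fold cross-validated
deviance with the one-standard-error rule — the largest λ within one
standard error of the minimum. The 1-SE rule is the package's parsimony
choice: it keeps planted informative features while admitting few noise
variables in recovery experiments, which matches the stated purpose of
selection (reducing model complexity). The selected features are then
refit without penalty by maximum likelihood; with perfect separation the
refit falls back to a light ridge (C = 10³ on scaled features) with a
warning. An empty selection yields an intercept-only model whose fitted
probability is the training prevalence.

MMP-7 enters the combined model continuously as log10(1 + concentration)
together with a ≤ 30-days age-stratum indicator; the binary clinical rule
remains available separately. The decision threshold defaults to the
Youden-index maximum over all cut-points of the training ROC, with ties
broken toward higher sensitivity (missing a BA case delays surgery, which
is the costlier error); a fixed threshold is supported. Models serialize
to JSON (scaling bounds, selected features, coefficients, threshold,
imputation medians, training metadata) and round-trip losslessly.

## Accuracy statistics

AUC is the tie-corrected rank statistic (concordant pairs plus half-ties
over all case–control pairs), computed from DeLong structural components;
its variance is S₁₀/m + S₀₁/n and the 95% CI uses the normal
approximation truncated to [0, 1]. The paired DeLong test uses the
2×2 covariance of the components; two identical score vectors have zero
variance of the difference and are assigned p = 1 by convention.
Proportions (sensitivity, specificity, accuracy) get exact Clopper–Pearson
intervals; percentages are printed to one decimal with
round-half-away-from-zero. Calibration curves use equal-frequency decile
bins of the predicted probability (duplicated edges merged). Cohort
comparison tables use Pearson's chi-squared without continuity correction
for categorical variables and the two-sided Wilcoxon rank-sum test for
continuous ones; p-values are unadjusted.

## Synthetic data

The generator emulates the study conditions, not ultrasound physics.
Cohorts: labels are independent Bernoulli draws at the configured
prevalence (training default 187 patients at 0.299; validation 161 at
0.621); MMP-7 is log-normal per class with medians 8 ng/mL (non-BA) and
60 ng/mL (BA) and σ = 0.7 on the natural-log scale, so that the two
medians straddle the 18 ng/mL threshold and stratum positivity rates land
in the mid-90s% for BA and low-teens% for non-BA — the regime a strong
biomarker shows; ages are uniform integers on [20, 120] days so both age
strata occur; biochemistry (TB, DB, GGT, ALT, AST, TBA) is log-normal
with BA shifted upward in GGT and conjugated bilirubin. One RNG stream
per (seed, patient) makes any subset reproducible.

Images are 128×128 by default (a realistic cropped-field size; tests use
64–96 px where scale is irrelevant): a flat background of mean 90 with
Gaussian noise (σ = 12) lightly blurred (σ = 0.8 px) to mimic speckle
correlation, plus one embedded structure — a dark ellipse for the
gallbladder (contrast −45) or a bright triangle/band for the triangular
cord (+35) — with small random jitter in position, size and rotation.
Class effects multiply contrast and size: in BA the gallbladder is
smaller (×0.55) and fainter (×0.45) and the triangular cord more
prominent (×1.6 contrast, ×1.2 size); in non-BA the cord is faint
(×0.35). The ground-truth mask is exactly the rasterized geometry and is
re-renderable from the stored parameters. Crop boxes are the mask
bounding box padded by 12 px, standing in for a manual crop.

What passing tests show: the pipeline recovers planted geometric and
intensity differences, selection finds the informative features, the
combined model dominates either modality alone, and the statistics match
independent oracles. What they do not show: performance on real
sonograms — speckle statistics, shadowing, operator variability and the
true overlap between BA and non-BA anatomy are all absent, and the
synthetic effect sizes are free parameters, not estimates from patient
data.

## Problem sizes and determinism

Recovery experiments use 500 patients (lasso) and twenty independent
study replicates at the default cohort sizes (187/161); segmentation
checks use 128×128 phantoms; calibration self-consistency uses 10,000
patients with a model trained on 500. All randomness flows from explicit
integer seeds (numpy `SeedSequence`); reruns of any generator, training
or CLI command with the same seed reproduce outputs byte-for-byte
(dataset manifests deliberately contain no timestamps).

## Known limitations

- No automatic ROI localization: crop boxes are inputs, as in manual
  clinical workflow.
- The delineation pipeline assumes one dominant structure per crop; two
  similar-sized structures would be resolved arbitrarily by the
  largest-component rule.
- DeLong CIs are asymptotic; at very small n or AUC near 1 they reach the
  truncation bounds.
- The decision threshold is learned on the training cohort; recalibration
  for cohorts with very different prevalence is out of scope.
- DICOM support reads pixel data only and ignores modality LUTs.
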