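# Methods

This note documents the models and procedures `deltarad` implements, the
choices made where the methodology is genuinely open, and what the
synthetic data can and cannot show.

## Filtration-histogram texture analysis

**Filtration.**  Each 2D CT slice is convolved with a rotationally
symmetric Laplacian-of-Gaussian kernel.  The spatial scale filter (SSF, in
mm) is tied to the Gaussian width by `σ = SSF / (2√2)`, so that the LoG
zero-crossing diameter `2√2·σ` equals the SSF: discs of roughly that
diameter produce the strongest centre response (verified by a disc-sweep
test).  The kernel is sampled at pixel centres in physical coordinates
(anisotropic spacing supported), truncated at a radius of `4σ`, and then
mean-subtracted so its coefficients sum to exactly zero — a constant image
yields zero response, and adding a constant to any image leaves the
response unchanged.  Commercial implementations of this technique do not
publish their exact kernel normalisation or σ↔SSF mapping, so absolute
filtered values here follow this documented construction rather than any
proprietary one.  Kernels whose σ falls below 0.3 px are refused
(undersampled by the grid).  The whole slice is filtered before the ROI
mask is applied, so the convolution sees real surrounding context instead
of a masked edge; SSF = 0 returns the raw HU map.  Mirror padding handles
image borders; phantom grids are required to span at least twice the
lesion diameter so padding never touches the ROI.

**Statistics.**  In-mask values are rounded to the nearest integer (ties to
even, matching CT integer storage) and the empirical distribution over the
distinct integer values gives the histogram — "integer binning", no bin
width pooling.  The six statistics are population-moment based (divide by
n): mean; SD; entropy `−Σ pᵢ log₂ pᵢ` in bits (the log base is
configurable; published work does not state one); MPP, the mean of
strictly positive values (undefined if none); skewness `m₃/sd³`; kurtosis
`m₄/sd⁴ − 3`, i.e. *excess* kurtosis so a Gaussian scores 0 (a Pearson
`+3` convention is available).  Skewness and kurtosis are undefined at
sd = 0, and undefined entries propagate as missing — never as 0, which
would bias downstream standardization.  By default all six statistics are
computed on the binned values; a switch computes the five moment
statistics on the raw filter responses instead (entropy always needs the
integer histogram), since published descriptions do not fix this detail.

## ROI handling and lesion rules

Polygons are rasterized by the pixel-centre even–odd rule with boundary
centres included; coordinates are 0-based with `x` along columns and the
centre of pixel `(row, col)` at `(col+0.5, row+0.5)`.  The largest lesion
diameter is the maximum pairwise distance between in-mask pixel centres in
mm — a deliberately simple, translation- and rotation-invariant measure;
the 5 mm eligibility rule it feeds is a coarse gate, so sub-pixel
refinements would not change decisions.  Per patient and timepoint,
lesions under 5 mm are excluded, the remainder are sorted by diameter
(ties by lesion id) and at most five are kept; a patient with no eligible
lesion is excluded and counted.  An optional HU window (default
[−100, 300]) automates the manual exclusion of air, streak artifact and
dense calcification pixels from the ROI; it is off by default because
manual curation is the reference practice.

## Aggregation and delta features

Lesion features are averaged per patient with an unweighted mean
(outcomes exist per patient, and weighting lesions by size or site has no
established rationale).  Delta features are computed per lesion as
`perc-Var = 100·(var_pre − var_post)/var_pre` on lesions present at both
timepoints (matched by id; vanished or new lesions are excluded and
reported), then averaged per patient.  A zero baseline value makes the
percentage undefined (flagged, never ±∞).

**Sign convention.**  The printed formula above makes an *increase* in a
feature yield a *negative* percentage, while the accompanying clinical
narrative treats "an increase in delta-entropy" as the adverse direction
and reports better survival *above* a positive cutoff.  These cannot all
hold under one convention, and the source material does not resolve it.
The package therefore implements the formula exactly as printed
(`as-printed`, the default) and exposes the exact negation
(`increase-positive`) as a config switch; every output records which
convention produced it.  Nothing in the downstream statistics depends on
the choice except the sign of reported delta coefficients.

## Survival analysis

**Selection.**  LASSO-Cox (L1-penalised Cox partial likelihood) is run
separately over the baseline feature family and the delta family, per
endpoint.  Features are standardized internally; rows with missing values
are dropped and counted; zero-variance features are dropped with a
warning.  The penalty grid is the glmnet-style log-spaced path of the full
data fit; 10-fold cross-validation — folds stratified by event status and
seeded for reproducibility — scores each penalty by out-of-fold Breslow
partial-likelihood deviance, and the minimum-deviance penalty (lambda-min,
not 1-SE) is chosen.  Lambda-min matches the evidently permissive
selection behaviour this workflow is meant to reproduce (several
correlated scales retained).  The "best" marker is the selected feature
with the largest |standardized coefficient|.  The path solver is
scikit-survival's Coxnet; the CV deviance uses this package's own Breslow
partial likelihood, which is also unit-tested against a naive double-loop
implementation.

**Multivariate Cox.**  Each marker is refit unpenalised (statsmodels PHReg,
Breslow ties — month-resolution times tie often and a fixed tie rule keeps
results deterministic) in its clinical template: baseline markers with
`{ldh_high, sites_high}`, delta markers with `{sites_high,
perc_ldh_high}`.  Texture markers enter continuously (per-unit hazard
ratios), clinical covariates as binary flags.  Wald 95 % intervals are
`exp(β ± 1.96·SE)`.  Non-convergence, perfect separation or a singular
information matrix are flagged on the result, never silent; constant
covariates are dropped with a note inside the pipeline (an error when
fitting directly).  Clinical cutoffs: LDH strictly above 1.5 × ULN, LDH
percentage change strictly above 20, and ≥ 3 metastatic sites; values
exactly at a continuous cutoff fall in the low group.  The ULN default is
450 U/L — LDH assays differ, so set your laboratory's value.  No multiple-
testing correction is applied beyond two-sided p < 0.05 per test, matching
the workflow being reproduced; reports include the number of tests run.

**Kaplan–Meier.**  Groups are `value > cutoff` versus `value ≤ cutoff`
(median by default, fixed cutoffs configurable — defaults 1.11 for
kurtosis at SSF 2, 1.20 at SSF 3, and 5 for delta-entropy at SSF 4 and 6).
Group medians are the first times the product-limit estimate reaches 0.5
(reported as not-reached when the curve never crosses); groups are
compared by a two-sided log-rank test.  A one-sided split is an error that
suggests the fixed-cutoff mode.

## Synthetic data

**What it emulates.**  Lesion phantoms are circular ROIs on a uniform
40 HU background containing `object_count` hard discs of
`object_diameter_mm` at a uniform `object_contrast_hu` offset — the three
classic heterogeneity levers (object size, density, number) — plus i.i.d.
Gaussian noise, rounded to integer HU.  Overlapping discs add the contrast
once (union, not sum), keeping HU bounded.  Post-therapy twins reuse the
lesion geometry and redraw objects and noise from a derived seed; a
requested relative entropy shift is realised by scaling the noise SD
(`σ_post = σ·2^{H₀·shift}` for entropy in bits), a monotone lever on
histogram entropy; unreachable requests are flagged on the output.
Cohorts draw per-patient lesion counts (default 1–3), diameters
(10–22 mm), object parameters (0–12 objects, 2–6 mm, 30–90 HU), noise
(6–14 HU) and an entropy shift (default ±15 %), all on the 0.98 mm pixel
grid of the reference scanner protocol.  LDH is log-normal around
389 U/L with an 18 % SD relative pre→post shift, and metastatic-site
counts are `1 + Poisson(0.7)` (≈ 16 % of patients at ≥ 3) — magnitudes
chosen to resemble a metastatic melanoma cohort's clinical table.
Survival times are exponential proportional hazards on *standardized*
extracted features, `h(t) = λ₀·exp(βᵀx_std)`, with independent exponential
censoring; defaults `λ₀ = ln2/30` per month for OS (PFS uses twice the
hazard), censoring `ln2/60`, and planted effects `β = −0.6` on kurtosis
(SSF 2) and `+0.6` on delta-entropy (SSF 4) per SD.  Every generator is a
pure function of spec + seed; per-stage seeds are fanned out from the
master seed through `SeedSequence` so stages never collide.

**What it does not emulate.**  3D anatomy, scanner reconstruction,
contrast kinetics, registration error, reader variability in segmentation,
lesion-specific biology, or any correlation between clinical covariates
and imaging (clinical flags are null effects by construction).  Passing
tests therefore demonstrate that the *pipeline* recovers what is planted
under its own assumptions — proportional hazards, exponential censoring,
feature-linked risk — not that the biomarkers generalise to patients.

## Problem sizes and numerical choices

The test and acceptance workloads use cohorts of 150 patients (the scale
at which the planted β = 0.6/SD effects give essentially deterministic
sign recovery with ~100 events), 50-replicate selection/estimation
simulations, 200-replicate CI coverage and 1,000-replicate log-rank
calibration — sizes at which the Monte-Carlo error is well inside the
asserted bands while a full run stays in the minutes range on one core.
Other fixed numerical choices: kernel truncation at 4σ; convolution in
float64 with mirror padding; ties-to-even integer rounding; population
moments throughout; entropy clamped at −0.0; Coxnet path of 50 alphas
with `alpha_min_ratio = 0.01`; KM medians by the first-crossing rule.

## Known limitations

* 2D only, one slice per lesion, as in the reference workflow.
* Absolute texture values are implementation-specific (kernel
  normalisation differs between implementations); only the documented
  construction and its invariants are guaranteed.
* The LASSO CV deviance uses the basic out-of-fold partial likelihood,
  not the glmnet "V&VH" decomposition; at these sample sizes the chosen
  penalty is insensitive to the difference.
* The delta sign ambiguity described above is surfaced, not resolved.
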