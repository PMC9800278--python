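# Methods

This note records the models the package implements, the defaults it ships,
the numerical choices behind them, and what the synthetic data do and do not
establish.

## Uptake model

SUV is activity concentration divided by injected activity per gram of body
weight (density 1 g/mL), so it is dimensionless and equals 1 under uniform
distribution. Lesion SUVmax is analyzed on the natural-log scale throughout:
uptake distributions are right-skewed, and log-scale linear models
back-transform to geometric means and percent differences
(`100·(exp(b) − 1)`). Normal-tissue SUVmean is analyzed untransformed.

The core model is a Gaussian linear mixed model with random intercepts for
patient and — when the same lesion is scanned more than once — lesion nested
within patient. One patient's covariance is
`σ²_patient·J + σ²_lesion·L + σ²_resid·I` (J all-ones, L marking same-lesion
pairs). Fitting profiles both the fixed effects and the residual scale, and
optimizes the two log variance ratios; because the structured covariance has a
closed-form inverse (Sherman–Morrison per lesion block, a rank-1 Woodbury
update per patient), one criterion evaluation is a handful of vectorized
reductions and a full fit takes ~0.1–0.2 s at trial scale (≈270 lesions,
38 patients).

Numerical choices:

* Nelder–Mead from a small grid of starts locates the optimum; Newton steps
  on finite-difference derivatives polish it. On balanced one-way data the
  REML components then agree with the closed-form ANOVA method-of-moments
  estimators to ~1e-10.
* Variance ratios are optimized on the log scale (nonnegativity for free);
  a ratio below 1e-10 is reported as a boundary (zero) estimate.
* Residual sums of squares are floored at 1e-10 relative to `y'W⁻¹y`. This is
  above the cancellation noise of the quadratic-form subtraction, so exact
  zero-residual fits (degenerate test data) produce equal, comparable
  log-likelihoods instead of noise-ranked ones.
* Wald intervals use Satterthwaite degrees of freedom computed by the delta
  method: the gradient of `c'(X'V⁻¹X)⁻¹c` in the variance components against
  the inverse numerical Hessian of the REML log-likelihood. At boundary
  estimates the quadratic expansion is untrustworthy and the code falls back
  to the normal approximation with a warning.
* Likelihood-ratio tests and AIC-based curve selection require ML fits; REML
  fits are rejected there since REML likelihoods are not comparable across
  fixed-effect structures.
* ICC is reported as `σ²_patient / (σ²_patient + σ²_lesion + σ²_resid)`. With
  one scan per lesion the lesion and residual components are inseparable and
  the baseline model folds them into the residual.

Time–uptake curves over the first post-injection week are selected by ML-AIC
among linear, log-linear and quadratic time, each with a patient intercept and
protein dose as a main effect; near-ties (within 1e-6) resolve toward fewer
parameters, and predictions are projected at the 10 mg dose. The log-linear
form uses log(hours since injection) with the 1-hour scan entered as 1 h.
Serum half-life is the standard noncompartmental terminal log-linear fit:
among the last k ≥ 3 post-peak samples the window maximizing adjusted R² wins,
`t½ = ln 2 / λ_z`.

## Partial-volume adjustment

Lesion volume comes from two orthogonal CT diameters as an oblate spheroid
`V = (π/6)·L²·S` (the two equal axes take the long measurement; the
`(π/6)·L·S²` alternative is a config option). Volume at PET time is linearly
interpolated between the baseline and first response CT, clamped after the
follow-up (volumes must stay nonnegative; queries before baseline are
errors).

The adjustment regresses pretreatment log SUVmax on a restricted cubic spline
(Harrell basis, linear tails) of log volume with 5 knots at the 0.05/0.275/
0.5/0.725/0.95 quantiles. Log volume is the predictor because lesion volumes
span three orders of magnitude; a raw-volume predictor and an optional
95th-percentile volume trim are provided. When patient identifiers are
available the spline coefficients are fixed effects of a patient
random-intercept LMM — lesions cluster within patients, and the clustered fit
is both more efficient and consistent with every other model in the package;
otherwise OLS is used. Adjusted uptake is, on the log scale,

`log SUV_adj = log SUV − Ê(V_at_PET) + Ê(5 cm³)`

interpreted as the uptake difference from treatment-naive lesions of identical
volume, projected to a 5 cm³ lesion (a volume inside the flat region of the
curve). The "absolute difference" is taken on the log scale, keeping the
analysis geometric end to end; a linear-scale mode exists behind a flag.

Because Ê is estimated, treating it as known understates uncertainty in the
second stage. The adjusted response is linear in the spline coefficients
(`y_adj = y + U·θ̂` with `U = B(5 cm³) − B(V)` rows), so for any contrast the
first-stage variance contribution is `(a'U)·Cov(θ̂)·(U'a)` with `a` the GLS
influence vector of that contrast; `treatment_change_model` adds this
delta-method term to every reported interval and p value when handed the
spline. At trial scale the omission is material — simulations show ~1.3× SE
underestimation and ~85 % coverage of nominally 95 % intervals without the
term, restored to ~95 % with it. The (small, slightly conservative)
covariance between the first-stage errors and the baseline noise of the same
lesions is ignored.

Treatment effects are expressed per week of therapy (days/7, exact; the
pretreatment scan is coded day 0), overall and split PD vs non-PD with a
week×group interaction, and summarized at 30 days by compounding
`(1 + rate)^(30/7) − 1`.

## Survival

Patient exposure is the geometric mean baseline SUVmax over nonirradiated
lesions. The median split is predefined, with ties assigned to the lower
group; the continuous analysis standardizes by the population SD with a
"per SD decrease" direction flag. Kaplan–Meier estimation and the log-rank
test come from lifelines (Greenwood variance; the log-rank statistic is
cross-checked in tests against the Cox score test, which it equals at untied
event times). The Cox model is Firth-penalized, `ℓ*(β) = ℓ(β) + ½ log I(β)`
with Breslow tie handling, maximized by a bounded scalar search to 1e-10;
confidence limits are profile penalized-likelihood roots at the χ²(1) cutoff
(tolerance 1e-6) and the p value is the penalized likelihood-ratio test —
Wald inference degrades exactly in the separated configurations the penalty
exists to handle. RECIST categorization (PR ≥30 % below baseline; PD ≥20 %
and ≥5 mm above nadir, or new lesions; CR at zero) feeds best-overall-response
groupings.

## Autoradiography–IHC coregistration

The affine map from IHC-frame to ARG-frame coordinates is the least-squares
solution over ≥3 non-collinear landmark pairs; resampling pulls the ARG into
the IHC frame (bilinear for intensities, nearest for masks; out-of-bounds
pixels are marked invalid and excluded from every mean). Pixels are 0-based
(row, col), origin top-left; tiles are half-open squares. Tile grids use a
stride of half the tile size (the ladder defaults to 100/400/1000/2000/4000/
8000 px on full-size slides; the synthetic tests use smaller sizes matched to
their 256–512 px images). Tiles need ≥25 % tumor-ROI overlap; per tile, IHC
positivity is percent positive pixels and ARG intensity is the
decay-corrected mean (⁸⁹Zr t½ = 78.4 h, reference time = injection) minus the
decay-corrected slide background (mean over a non-tissue mask). Negative
background-subtracted intensities are kept — clamping would bias rank
correlations. Kendall's τ_b handles ties; p values use exact permutation
enumeration for n ≤ 8 and the normal approximation otherwise. Within-slide
correlations are only reported for slides with ≥6 tiles (rank correlations on
fewer are too unstable), but such slides still contribute to pooled
correlations; slide-level global values use all ROI pixels, not only kept
tiles.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analyses assume, with
ground truth retained:

* **Uptake hierarchy.** Baseline `log SUVmax = μ + u_patient + v_lesion + ε`
  with μ = ln 5.6 and total log-variance `ln(1 + 0.72²) = 0.418` (geometric
  CV 0.72), split σ²_patient = 0.46·total = 0.192 (ICC 0.46 at one scan per
  lesion), σ²_resid = 0.01, σ²_lesion the remainder (0.216). 38 patients,
  zero-truncated Poisson(7) lesions per patient (≈266 lesions), organ sites
  and dMMR/phenotype frequencies at the trial's observed mix.
* **Response and treatment.** Best overall response is drawn per patient at
  (PD, SD, PR, CR) = (19, 4, 8, 4)/35. On-treatment log uptake adds a per-BOR
  weekly slope (defaults −0.02/−0.05/−0.09/−0.12 for PD/SD/PR/CR, averaging
  near −4.6 %/week) plus lesion-level slope noise (SD 0.01/week — the
  interlesional slope heterogeneity is a free parameter, not an observed
  value). Half the patients get a repeat scan at a uniform 28–36 days.
* **Volume course.** Each lesion's volume changes linearly in time as a
  per-week fraction of its baseline volume (defaults +0.05/0/−0.10/−0.14 per
  week by BOR, floored at 1 % of baseline), with the response CT at ~6 weeks.
  The linear-in-time course matches what sparse RECIST assessments can
  resolve and what the analysis's linear volume interpolation assumes; lesion
  diameters at each CT are back-computed from the volume with the lesion's
  fixed axis ratio.
* **Partial-volume attenuation.** Measured SUV is the true noisy SUV times
  `min(1, (V/2 cm³)^γ)` with γ = 0.3 — the simplest monotone curve that is
  flat above the 2 cm³ knee. The analysis must rediscover the knee through
  the spline; nothing downstream reads γ. Setting γ = 0 disables the effect.
* **Survival.** Exponential event times whose log-hazard is `hr_per_sd`
  (default −ln 1.6) times the standardized patient-level mean log uptake;
  PFS baseline hazards additionally depend on BOR (medians 1.5/4/8/12 months
  for PD/SD/PR/CR); random exponential censoring plus an 18-month
  administrative horizon.
* **PK.** Monoexponential serum decay, t½ = 1.19 days, sampled at the
  first-week schedule (pre-injection through day 7), multiplicative Gaussian
  noise.
* **Slides.** A smoothed random blob field scaled per immune phenotype
  (desert ≈ zero density inside tumor; stromal concentrated in a rim via a
  distance transform; inflamed diffuse) generates per-pixel Bernoulli IHC
  positivity; the ARG is the PSF-blurred (σ = 3 px) density, decayed by
  `2^(−delay/78.4 h)`, pulled through a known affine misalignment, plus
  background and Gaussian noise. Landmarks are exact; IHC positivity is
  generated directly as a binary mask (stain color deconvolution is out of
  scope).

Not emulated: voxel-level PET physics (SUV statistics are lesion-level), scan
protocol irregularities, informative censoring, pseudo-progression, nonrigid
tissue deformation between ARG and IHC sections, and pathologist scoring
noise. Passing recovery tests on these cohorts therefore demonstrates the
statistical machinery is correct and unbiased under the assumed structure,
not that the assumptions hold in any particular clinical dataset.

## Problem sizes used in tests

Simulation-based checks run at the trial's own scale (38 patients, ≈266
lesions) with 100–200 replicates; registration and tile oracles use 256–512 px
images. These sizes keep the full suite and the acceptance script to a few
minutes on one CPU while leaving Monte-Carlo error well inside the asserted
margins.

## Known limitations

* Satterthwaite df rely on numerical derivatives; at variance boundaries the
  code deliberately degrades to normal approximations rather than reporting
  fragile df.
* The Firth–Cox implementation is single-covariate (the analyses here need
  nothing more); multivariable penalized Cox is out of scope.
* The spline-uncertainty propagation covers the adjustment's coefficient
  covariance but not knot-placement variability (knots are data quantiles)
  or the first-stage/second-stage error correlation; both are second-order
  at these sample sizes.
* `estimate_affine` assumes landmark errors are isotropic; anisotropic
  section distortion would call for weighted or nonrigid registration.
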