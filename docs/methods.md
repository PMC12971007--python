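# Methods

This note documents the models, the defaults and the numerical choices
behind `hemopattern`, and what the synthetic-data generator does and does
not emulate.

## OEF quantification

The TRUST decay model is `S(eTE) = S0·exp(−eTE/T2)` at the four effective
echo times 0.44, 40, 80 and 160 ms. Fitting is least squares: a log-linear
regression of `log S` on eTE provides starting values, refined by
Levenberg–Marquardt (`xtol = ftol = 1e−12`). Series that do not decay
(non-negative log-space slope, or a refined T2 above 10 000 ms) raise a fit
error rather than returning a meaningless time constant; series containing
non-positive signals (heavy noise) skip the log initializer, start from a
heuristic (median eTE, max signal) and are flagged on the result.

T2 converts to venous saturation through the quadratic relaxivity law
`1/T2 [s⁻¹] = a + b·(1−Y) + c·(1−Y)²` at fixed haematocrit. The
haematocrit dependence of (a, b, c) is parametrized in
`data/blood_t2_calibration.json` — `a` quadratic in hct, `b` linear,
`c ∝ hct(1−hct)` — with representative in-vitro 3 T values (CPMG spacing
10 ms). The file is deliberately swappable: different sites calibrate
against different blood preparations, and the package's contracts
(strict monotonicity of T2 in Y over the valid range, exact inverse
consistency, range errors that name the admissible T2 interval) hold for
any coefficients satisfying the validity checks. At hct 0.42 the defaults
give blood T2 ≈ 35–161 ms over Yv 0.30–0.98, and T2 = 70 ms ↦ Yv ≈ 59 % —
consistent with a cohort-mean OEF near 40 % at Ya = 98 %. Inversion solves
the quadratic in closed form (positive root); values mapping outside the
calibrated saturation range are rejected, not extrapolated.

Haematocrit defaults are 0.42 (men) and 0.40 (women); arterial saturation
Ya defaults to 98 %. `OEF = (Ya − Yv)/Ya × 100 %` is pure arithmetic and is
invariant to rescaling the TRUST amplitudes, since S0 cancels in the fit.

## CBF quantification

Flow through a vessel ROI is the signed sum of through-plane velocity
(cm/s) × pixel area (cm²) over the ROI, × 60 for ml/min. Negative-phase
pixels contribute with their sign; an optional static-tissue correction
subtracts the median velocity over a caller-supplied background mask before
summation (manual vendor-specific corrections are not reproducible, so the
package exposes this single documented rule). Global CBF divides the summed
arterial inflow by brain mass, taking brain density 1.06 g/ml to convert
the (input) brain volume to mass: `CBF = flow/(volume × 1.06) × 100` in
ml/100 g/min. A negative total flow is returned with a warning rather than
rejected, so signed phase artefacts remain visible downstream.

## Derived cohort variables

* **Cognitive composites.** Raw test scores are Z-scored against the whole
  sample (sample SD, n−1), timed colour-trails tests are negated first so
  higher Z is always better. Domain scores are the mean of their tests' Z,
  re-standardized; the global composite is the re-standardized mean of the
  domain Z-scores, hence exactly 0 ± 1 in the analysis sample. The
  transformer retains the fitted constants, so external samples can be
  scored against a reference cohort. Complete test batteries are required —
  no partial-battery averaging, no imputation.
* **WMH.** Natural log of (volume + 0.01 cm³); the floor handles
  lesion-free subjects. All WMH models run on the infarct-free subset,
  since infarcts inflate automated lesion volumes.
* **Vascular risk score.** Count of hypertension, diabetes,
  hyperlipidaemia, ever smoking, obesity (BMI strictly > 28), range 0–5;
  stratified low (≤2) vs high (≥3). Missing components are an error.
* **Quadrants.** Median splits of OEF and CBF; "high" is strictly above
  the median, ties go to "low" — deterministic and order-independent.
  Labels are invariant under any strictly monotone transform of either
  axis.

## Association models

All models are ordinary least squares (identity-link Gaussian GLM). The
quadrant factor is dummy-coded with Q2 (high OEF + low CBF) as reference;
sex enters as a 0/1 male indicator and education as a single ordinal 0–4
covariate. Confidence intervals are Wald, estimate ± 1.96 SE, with
classical (homoskedastic) standard errors. The battery runs log-WMH
(age + sex; infarct-free) and the global + six domain composites
(age + sex + education), each with and without the vascular risk score —
48 contrast rows. Stratified analyses repeat the continuous OEF/CBF slope
models within vascular-risk or APOE strata with the same covariates minus
the stratifier itself (the risk score is nearly constant within its own
strata); underpowered strata are skipped with a warning, not silently
dropped.

The MANCOVA builds, for each exposure term, the hypothesis cross-product
matrix `H = (Lb)'[L(X'X)⁻¹L']⁻¹(Lb)` and the residual cross-product matrix
E explicitly, reporting Pillai's trace `V = tr[H(H+E)⁻¹]` with the standard
F approximation and per-outcome follow-up ANCOVA F tests. With a single
outcome the statistic reduces exactly to the univariate F; the test suite
cross-checks the general case against an independent hat-matrix oracle and
against `statsmodels.multivariate.MANOVA`.

## Response-surface analysis

X and Y are centred at their sample means (the centring is stored with the
fit); the design is `(1, X, Y, X², XY, Y², covariates)`. Covariates are
included **inside** the polynomial regression by default. Because the
literature also describes fitting surfaces to covariate-*residualized*
outcomes — and the two differ whenever covariates correlate with the
predictors — a `covariate_mode="residualize"` sensitivity variant is
provided, and every fit records which mode produced it.

Axis statistics are linear combinations of the coefficients
(balance slope `b1+b2`, balance curvature `b3+b4+b5`, bias slope `b1−b2`,
bias curvature `b3−b4+b5`), parametrized per unit of X along the axis line
(not per unit arc length — the directional derivative along the unit
balance direction is `(b1+b2)/√2`). SEs are delta-method `√(c'Σc)` from the
stored coefficient covariance; a zero covariance (e.g. when feeding printed
coefficient tables) collapses the intervals to the point estimates.
Surface grids are 50 × 50 over the observed centred ranges, clipped to
±2.5 SD so the polynomial is never extrapolated far outside the data;
explicit wider ranges are rejected.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the cohort
conditions the analysis targets:

| quantity | default | note |
|---|---|---|
| n subjects | 296 | analytic sample size |
| age | N(67.8, 8.76²) yr | |
| male fraction | 0.311 | |
| education | ordinal 0–4, probs (.162, .348, .220, .149, .121) | category mix |
| OEF | N(39.7, 4.45²) % | bivariate normal with CBF |
| CBF | N(58.2, 8.95²) ml/100g/min | correlation a knob, default 0 |
| WMH volume | log-normal, log-mean 0.486, log-SD 1.210 | matches mean 3.38, SD 6.16 cm³; floored at 0.01 |
| risk prevalences | HT .453, DM .203, HL .348, smoking .206, obesity .118 | obesity implied by N(24.2, 3.21²) BMI above 28 |
| genotyped / APOE4 / infarct | 140/296, 24/140, 42/296 | |
| cognition surface | (0, −0.49, −0.03, 0.01, 0, 0) | published global-cognition surface, applied per domain |
| cognitive noise | SD 1 Z-unit | |
| TRUST | eTEs (0.44, 40, 80, 160) ms, S0 1000, noise 1 % of S0 | |
| velocity maps | 64×64, 0.0025 cm² pixels, venc 40 cm/s, noise 0.5 cm/s | four disc ROIs |
| brain volume | N(1100, 100²) ml | typical older-adult parenchyma |

BMI is drawn from truncated normals conditional on the obesity indicator,
so the configured obesity prevalence and the strict BMI > 28 rule agree
exactly. The marginal WMH ↔ haemodynamics linkage defaults to **zero**: the
published WMH surface coefficients are far too large relative to the
cohort's log-WMH dispersion to serve as a generating mechanism (a 1-SD CBF
shift would move log-WMH by ~13 log-units), so they are used only as
inputs to the axis arithmetic, while the generator preserves the observed
WMH marginal; the linkage remains a config knob for power studies.
Covariate effects on cognition default to −0.02 Z/yr of (centred) age and
+0.10 Z per education level.

Signal truth is internally consistent: each subject's TRUST T2 follows
from their OEF through the sex-specific calibration, and each velocity
scene integrates (noiselessly) to the inflow implied by their CBF and
brain volume — so quantifying noiseless signals reproduces the cohort
columns to machine precision, which the tests exploit as a stage-
equivalence check. Seeding uses one master seed with fixed named child
streams per component, so adding a component never changes another's
draws, and identical configs are byte-identical.

What the generator does **not** emulate: spatial lesion geometry or FLAIR
contrast, k-space/MR physics beyond mono-exponential decay, cardiac
pulsatility or partial-volume effects in the velocity maps, missing data
other than the optional APOE subset, and any selection effects of
recruitment. Passing tests therefore demonstrate the correctness and
calibration of the estimators and models under the assumed data-generating
laws — not robustness to real-world acquisition artefacts.

## Monte-Carlo test sizes and numerical choices

The calibration checks in the test suite use problem sizes chosen to keep
the whole suite fast while leaving Monte-Carlo error well below the bands
being checked: 1000 replicates for the T2-bias bound (<1 ms at 1 % noise),
500 cohorts of n = 296 for surface-coefficient recovery (joint chi-square
of the standardized mean deviations at the 99 % quantile, the
multiplicity-correct version of a per-coefficient 2·SE check), 1000
simulations for the 95 % ± 2 % coverage of the balance-slope interval, and
2000 replicates for the 5 % ± 1.5 % type-I error of the Q4-vs-Q2 contrast.
Degenerate inputs fail loudly everywhere: non-decaying TRUST series,
out-of-range T2, empty ROIs, velocities that would alias past venc,
zero-variance tests, all-equal median splits and rank-deficient designs
(reported with the offending column names) all raise typed errors.

## Known limitations

* The calibration coefficients are representative, not site-specific;
  absolute OEF levels shift with the chosen calibration file (the
  analysis-level conclusions operate on within-cohort variation).
* Classical SEs throughout; no robust/bootstrap variants.
* The MANCOVA F approximation is exact only for single-df hypotheses
  (the case used here); multi-df terms would inherit the standard
  approximation error.
* No multiple-testing correction across the battery, mirroring the
  analysis design this package operationalizes.
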