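# hemopattern

Cerebral haemodynamic pattern analysis for community ageing cohorts:
quantification of the global **oxygen extraction fraction (OEF)** and
**cerebral blood flow (CBF)**, classification of joint OEF × CBF
("misery perfusion") phenotypes, and statistical modelling of their
association with white-matter hyperintensity (WMH) burden and
neurocognitive performance.

It is written for imaging/epidemiology analysts who have, per subject,
(a) a TRUST-MRI decay series, (b) a phase-contrast velocity map with vessel
ROIs, and (c) a cohort table of demographics, vascular risk factors, WMH
volume and raw neuropsychological scores — or who want to develop and test
such an analysis against a fully synthetic stand-in cohort, which the
package generates.

## The science in brief

**OEF.** TRUST difference signals in the superior sagittal sinus decay
mono-exponentially in the effective echo time, `S(eTE) = S0·exp(−eTE/T2)`.
The fitted venous-blood T2 converts to venous oxygen saturation Yv through
a haematocrit-dependent quadratic relaxivity calibration
(`1/T2 = a + b(1−Y) + c(1−Y)²`; hct 0.42 for men, 0.40 for women), and
Fick's principle gives `OEF = (Ya − Yv)/Ya × 100 %` with Ya = 98 %.

**CBF.** Through-plane velocities (cm/s) are integrated over the four
feeding-artery ROIs to volumetric inflow (ml/min), then normalised by brain
mass: `CBF = total flow / (brain volume × 1.06) × 100` in ml/100 g/min.

**Patterns.** Subjects are split at the sample medians of OEF and CBF into
quadrants Q1 (high/high), Q2 (high OEF + low CBF — misery perfusion),
Q3 (low/low) and Q4 (low OEF + high CBF). Covariate-adjusted linear models
contrast each quadrant against Q2.

**Response surface.** The continuous interplay is modelled as

```
Z = b0 + b1·X + b2·Y + b3·X² + b4·X·Y + b5·Y² + covariates
```

with X, Y the mean-centred OEF and CBF and Z the outcome (log-WMH or a
cognitive composite). Inference follows two lines in the (X, Y) plane: the
**balance axis** (CBF = OEF; slope `b1+b2`, curvature `b3+b4+b5`) for
coordinated supply/demand states, and the **bias (mismatch) axis**
(CBF = −OEF + 2μ; slope `b1−b2`, curvature `b3−b4+b5`). Standard errors of
these combinations come from the delta method; intervals are Wald ±1.96 SE.
A Pillai-trace MANCOVA with per-domain follow-up ANCOVAs serves as the
multivariate sensitivity analysis.

## Worked example

```python
>>> import hemopattern as hp

# --- signal-level quantification -------------------------------------
>>> series = hp.generate_trust_series(t2_true=70.0, s0=1000.0, noise_sd=0.01, rng=3)
>>> fit = hp.fit_blood_t2(series)
>>> model = hp.calibration_for_hct(hp.hct_default("female"))
>>> yv = model.t2_to_yv(fit.t2) * 100
>>> print(f"T2 = {fit.t2:.1f} ms, Yv = {yv:.1f} %, OEF = {hp.compute_oef(98.0, yv):.1f} %")
T2 = 67.0 ms, Yv = 56.6 %, OEF = 42.3 %

>>> res = hp.compute_cbf({"LICA": 250.0, "RICA": 245.0, "LVA": 90.0, "RVA": 85.0},
...                      brain_volume=1100.0)
>>> print(f"total flow = {res.total_flow:.0f} ml/min, CBF = {res.cbf:.1f} ml/100g/min")
total flow = 670 ml/min, CBF = 57.5 ml/100g/min

# --- cohort-level analysis on a synthetic cohort ---------------------
>>> cohort = hp.generate_cohort(hp.SimulationConfig(n_subjects=296, seed=42))
>>> derived = hp.derive_variables(cohort)
>>> derived["quadrant"].value_counts().sort_index()
Q1    79
Q2    69
Q3    79
Q4    69

>>> fit = hp.fit_rsa(derived["oef"], derived["cbf"], derived["global_cognition"],
...                  covariates=derived[["age", "male", "education"]])
>>> hp.axis_tests(fit).as_frame().round(3)
             term  estimate    se     lo     hi
    balance_slope    -0.223 0.003 -0.228 -0.218
balance_curvature     0.004 0.000  0.003  0.005
       bias_slope    -0.195 0.003 -0.200 -0.189
   bias_curvature     0.005 0.000  0.004  0.006
```

The first block turns one subject's TRUST decay into blood T2 (67 ms),
venous saturation (56.6 %) and OEF (42.3 %), and four arterial flows into a
global CBF of 57.5 ml/100 g/min — both in the range expected for older
adults. The second block builds derived variables for a simulated cohort
(quadrant counts partition the 296 subjects at the medians) and fits the
cognition response surface: the negative balance-axis slope says that
moving up the "both high → both low" diagonal towards jointly elevated
OEF+CBF lowers the expected composite, and the negative bias-axis slope
says the high-OEF/low-CBF (misery-perfusion) end of the mismatch axis fares
worse than the low-OEF/high-CBF end. (The magnitudes are smaller than the
generating surface because the composite is re-standardized to unit
variance.)

The same pipeline runs from the shell:

```bash
hemopattern all --out runs/demo --seed 1          # simulate → … → rsa
hemopattern rsa --out runs/demo                   # re-run a single stage
```

Each run writes CSV/JSON outputs plus a `manifest.json` recording the seed
and every analysis convention in effect.

## Layout

```
src/hemopattern/
  synthetic.py   cohort / TRUST / velocity-map generator (SimulationConfig)
  mri.py         T2 fitting, T2↔Yv calibration, Fick OEF, flow → CBF
  cohort.py      Z-composites, log-WMH, vascular risk score, quadrants
  models.py      OLS batteries, stratified models, Pillai-trace MANCOVA
  rsa.py         ResponseSurfaceRegressor, axis tests, surface grids
  pipeline.py    stage orchestration with manifest
  cli.py         `hemopattern` command
docs/methods.md  modelling assumptions, parameter choices, limitations
```
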