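"""Synthetic cohort, TRUST-signal and velocity-map generator.

Emulates the statistical structure the downstream analysis assumes for a
community ageing cohort: OEF/CBF drawn from a bivariate normal
(39.7 +/- 4.45 % and 58.2 +/- 8.95 ml/100g/min by default), log-normal WMH
volumes, Bernoulli risk factors at cohort prevalences, an ordinal 0-4
education mix, and six-domain cognitive latents tied to mean-centred
(OEF, CBF) through a configurable second-order surface plus Gaussian noise.

Signal-level inputs are generated to match the cohort truth: each subject's
TRUST decay series uses the blood T2 implied by their OEF through the
haematocrit calibration, and each velocity scene integrates (noiselessly) to
the arterial inflow implied by their CBF and brain volume, so quantifying the
noiseless signals reproduces the cohort columns.

Seeding: one master seed spawns fixed, named child streams per component, so
adding a component never perturbs the draws of the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import mri
from .cohort import COGNITIVE_DOMAINS, TIMED_TESTS

__all__ = [
    "SimulationConfig",
    "SyntheticBundle",
    "generate_cohort",
    "generate_trust_series",
    "generate_velocity_scene",
    "generate_artery_scene",
    "generate_bundle",
    "TEST_SCALES",
    "DEFAULT_SURFACES",
]

#: Raw-score location/scale per neuropsychological test (battery-typical).
TEST_SCALES: dict[str, tuple[float, float]] = {
    "colour_trails_a": (65.0, 25.0),
    "colour_trails_b": (140.0, 45.0),
    "digit_span_forward": (8.0, 2.0),
    "digit_span_backward": (5.0, 2.0),
    "boston_naming": (12.0, 2.0),
    "symbol_digit": (35.0, 10.0),
    "rcft_copy": (32.0, 4.0),
    "rcft_immediate": (15.0, 6.0),
    "rcft_delayed": (14.0, 6.0),
    "rcft_recognition": (20.0, 2.5),
    "hvlt_immediate": (22.0, 5.0),
    "hvlt_delayed": (8.0, 2.5),
    "hvlt_recognition": (10.5, 1.5),
}

#: Default generating surfaces (b0..b5 on 1, X, Y, X^2, XY, Y^2). The
#: cognition surface is the published global-cognition response surface; the
#: WMH linkage defaults to zero because the published WMH surface is not
#: scale-compatible with the cohort's WMH marginal distribution (see the
#: methods note) — it remains a config knob.
DEFAULT_SURFACES: dict[str, tuple[float, ...]] = {
    "cognition": (0.0, -0.49, -0.03, 0.01, 0.0, 0.0),
    "log_wmh": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
}

_STREAMS = {
    "demographics": 0,
    "risk": 1,
    "hemodynamics": 2,
    "wmh": 3,
    "cognition": 4,
    "apoe": 5,
    "infarct": 6,
    "brain_volume": 7,
    "trust": 8,
    "velocity": 9,
    "tests": 10,
}


def _child_rng(seed: int, name: str) -> np.random.Generator:
    ss = np.random.SeedSequence(seed)
    return np.random.Generator(np.random.PCG64(ss.spawn(len(_STREAMS))[_STREAMS[name]]))


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of the synthetic cohort.

    Defaults reproduce the target cohort's marginal moments and prevalences;
    every field is a knob. ``surface_coeffs`` maps outcome names ("cognition"
    applies to every domain unless a domain-specific key is given;
    "log_wmh" links WMH to the haemodynamics) to the six coefficients
    (b0..b5) of the generating second-order surface in sample-centred
    (OEF, CBF).
    """

    n_subjects: int = 296
    seed: int = 0
    # demographics
    age_mean: float = 67.8
    age_sd: float = 8.76
    male_fraction: float = 0.311
    education_probs: tuple[float, ...] = (0.162, 0.348, 0.220, 0.149, 0.121)
    # haemodynamics
    oef_mean: float = 39.7
    oef_sd: float = 4.45
    cbf_mean: float = 58.2
    cbf_sd: float = 8.95
    oef_cbf_corr: float = 0.0
    # white matter hyperintensities (log-normal volume, cm^3)
    wmh_logmean: float = 0.486
    wmh_logsd: float = 1.210
    wmh_floor: float = 0.01
    # vascular risk
    risk_prevalences: Mapping[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.453,
            "diabetes": 0.203,
            "hyperlipidaemia": 0.348,
            "smoking_ever": 0.206,
            "obesity": 0.118,
        }
    )
    bmi_mean: float = 24.2
    bmi_sd: float = 3.21
    # genetics / infarcts
    apoe_fraction_genotyped: float = 140 / 296
    apoe4_prevalence: float = 24 / 140
    infarct_fraction: float = 42 / 296
    # cognition
    surface_coeffs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SURFACES)
    )
    cognitive_noise_sd: float = 1.0
    test_scatter_sd: float = 0.5
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": -0.02, "education": 0.10, "male": 0.0}
    )
    # anatomy / signals
    brain_volume_mean: float = 1100.0
    brain_volume_sd: float = 100.0
    trust_etes: tuple[float, ...] = mri.DEFAULT_ETES_MS
    trust_s0: float = 1000.0
    trust_noise_sd: float = 0.01  # fraction of S0
    velocity_noise_sd: float = 0.5  # cm/s
    scene_shape: tuple[int, int] = (64, 64)
    pixel_area: float = 0.0025  # cm^2 (0.5 x 0.5 mm pixels)
    venc: float = 40.0
    roi_radius_px: int = 6
    artery_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"LICA": 0.38, "RICA": 0.38, "LVA": 0.12, "RVA": 0.12}
    )
    ya_pct: float = mri.DEFAULT_YA_PCT

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be at least 4")
        for name in ("age_sd", "oef_sd", "cbf_sd", "wmh_logsd", "bmi_sd",
                     "brain_volume_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1.0 <= self.oef_cbf_corr <= 1.0:
            raise ValueError(
                "oef_cbf_corr outside [-1, 1]: implied covariance is not "
                "positive semi-definite"
            )
        probs = [self.male_fraction, self.apoe_fraction_genotyped,
                 self.apoe4_prevalence, self.infarct_fraction,
                 *self.risk_prevalences.values(), *self.education_probs]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for key, b in self.surface_coeffs.items():
            if len(tuple(b)) != 6:
                raise ValueError(f"surface_coeffs[{key!r}] must have six entries b0..b5")

    def surface_for(self, outcome: str) -> np.ndarray:
        coeffs = self.surface_coeffs.get(outcome)
        if coeffs is None and outcome in COGNITIVE_DOMAINS:
            coeffs = self.surface_coeffs.get("cognition")
        if coeffs is None:
            coeffs = (0.0,) * 6
        return np.asarray(coeffs, dtype=float)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["risk_prevalences"] = dict(self.risk_prevalences)
        d["surface_coeffs"] = {k: list(v) for k, v in self.surface_coeffs.items()}
        d["covariate_effects"] = dict(self.covariate_effects)
        d["artery_fractions"] = dict(self.artery_fractions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("education_probs", "trust_etes", "scene_shape"):
            if key in d:
                d[key] = tuple(d[key])
        if "surface_coeffs" in d:
            d["surface_coeffs"] = {k: tuple(v) for k, v in d["surface_coeffs"].items()}
        return cls(**d)


@dataclass
class SyntheticBundle:
    """Everything one simulated study produces, plus the generating truth."""

    cohort: pd.DataFrame
    trust_series: dict[str, mri.TrustSeries]
    velocity_scenes: dict[str, mri.VelocityScene]
    truth: dict

    def __post_init__(self) -> None:
        ids = list(self.cohort["subject_id"])
        if len(set(ids)) != len(ids):
            raise ValueError("subject identifiers must be unique")
        for component in (self.trust_series, self.velocity_scenes):
            if set(component) != set(ids):
                raise ValueError("component subject identifiers are inconsistent")


def _surface_value(b: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return b[0] + b[1] * x + b[2] * y + b[3] * x * x + b[4] * x * y + b[5] * y * y


def _truncated_normal(rng, mean, sd, lower, upper, size):
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """One synthetic cohort table, deterministic in ``config.seed``.

    Includes simulation-truth latent columns ``sim_latent_<domain>`` (the
    noisy domain latents before conversion to raw test scores) which the
    preparation stage drops.
    """
    n = config.n_subjects
    ids = [f"S{i:04d}" for i in range(1, n + 1)]

    rng = _child_rng(config.seed, "demographics")
    age = rng.normal(config.age_mean, config.age_sd, n)
    male = (rng.random(n) < config.male_fraction).astype(int)
    probs = np.asarray(config.education_probs, dtype=float)
    probs = probs / probs.sum()
    education = rng.choice(len(probs), size=n, p=probs)

    rng = _child_rng(config.seed, "risk")
    risk = {
        k: (rng.random(n) < p).astype(int)
        for k, p in config.risk_prevalences.items()
        if k != "obesity"
    }
    obese = (rng.random(n) < config.risk_prevalences.get("obesity", 0.0)).astype(int)
    # BMI drawn conditionally on obesity so the strict BMI > 28 rule matches
    # the configured obesity prevalence exactly.
    bmi = np.where(
        obese == 1,
        _truncated_normal(rng, config.bmi_mean, config.bmi_sd, 28.0 + 1e-9, 60.0, n),
        _truncated_normal(rng, config.bmi_mean, config.bmi_sd, 12.0, 28.0, n),
    )

    rng = _child_rng(config.seed, "hemodynamics")
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    r = config.oef_cbf_corr
    oef = config.oef_mean + config.oef_sd * z1
    cbf = config.cbf_mean + config.cbf_sd * (r * z1 + np.sqrt(1.0 - r * r) * z2)

    rng = _child_rng(config.seed, "wmh")
    b_wmh = config.surface_for("log_wmh")
    xc = oef - oef.mean()
    yc = cbf - cbf.mean()
    log_wmh = (
        config.wmh_logmean
        + _surface_value(b_wmh, xc, yc)
        + config.wmh_logsd * rng.standard_normal(n)
    )
    wmh = np.maximum(np.exp(log_wmh), config.wmh_floor)

    rng = _child_rng(config.seed, "infarct")
    infarct = (rng.random(n) < config.infarct_fraction).astype(int)

    rng = _child_rng(config.seed, "apoe")
    genotyped = rng.random(n) < config.apoe_fraction_genotyped
    apoe4 = np.where(genotyped, (rng.random(n) < config.apoe4_prevalence), np.nan)
    apoe4 = np.where(genotyped, apoe4.astype(float), np.nan)

    rng = _child_rng(config.seed, "brain_volume")
    brain_volume = np.clip(
        rng.normal(config.brain_volume_mean, config.brain_volume_sd, n), 700.0, None
    )

    eff = dict(config.covariate_effects)
    cov_term = (
        eff.get("age", 0.0) * (age - age.mean())
        + eff.get("education", 0.0) * education
        + eff.get("male", 0.0) * male
    )

    rng = _child_rng(config.seed, "cognition")
    latents = {}
    for domain in COGNITIVE_DOMAINS:
        b = config.surface_for(domain)
        latents[domain] = (
            _surface_value(b, xc, yc)
            + cov_term
            + config.cognitive_noise_sd * rng.standard_normal(n)
        )

    rng = _child_rng(config.seed, "tests")
    tests = {}
    for domain, test_names in COGNITIVE_DOMAINS.items():
        for t in test_names:
            m, s = TEST_SCALES[t]
            sign = -1.0 if t in TIMED_TESTS else 1.0
            scatter = config.test_scatter_sd * rng.standard_normal(n)
            tests[t] = m + s * sign * (latents[domain] + scatter)

    df = pd.DataFrame(
        {
            "subject_id": ids,
            "age": age,
            "sex": np.where(male == 1, "male", "female"),
            "education": education,
            "bmi": bmi,
            **risk,
            "apoe4": apoe4,
            "oef": oef,
            "cbf": cbf,
            "wmh_volume": wmh,
            "infarct": infarct,
            "brain_volume": brain_volume,
            **tests,
        }
    )
    for domain in COGNITIVE_DOMAINS:
        df[f"sim_latent_{domain}"] = latents[domain]
    return df


def generate_trust_series(
    t2_true: float,
    s0: float,
    etes=mri.DEFAULT_ETES_MS,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "",
) -> mri.TrustSeries:
    """A TRUST decay series ``s0*exp(-eTE/t2)`` with Gaussian noise.

    ``noise_sd`` is a fraction of ``s0`` (so 0.01 means 1% of the eTE=0
    amplitude at every echo time).
    """
    if t2_true <= 0:
        raise ValueError("t2_true must be positive")
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    etes = tuple(float(t) for t in etes)
    if len(etes) < 3:
        raise ValueError("need at least 3 effective echo times")
    signal = s0 * np.exp(-np.asarray(etes) / t2_true)
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        signal = signal + rng.normal(0.0, noise_sd * s0, len(etes))
    return mri.TrustSeries(etes=etes, signals=tuple(signal), subject_id=subject_id)


def _disc_mask(shape, center, radius) -> np.ndarray:
    if radius < 0:
        return np.zeros(shape, dtype=bool)
    ii, jj = np.ogrid[: shape[0], : shape[1]]
    return (ii - center[0]) ** 2 + (jj - center[1]) ** 2 <= radius**2


def generate_velocity_scene(
    true_flow: float,
    roi_shape: tuple[int, int] = (64, 64),
    pixel_area: float = 0.0025,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    venc: float = 40.0,
    roi_radius_px: int = 6,
    subject_id: str = "",
) -> mri.VelocityScene:
    """A single-vessel velocity scene whose noiseless ROI integral is ``true_flow``.

    The vessel is a centred disc of uniform velocity; Gaussian noise of SD
    ``noise_sd`` (cm/s) is added to every pixel and the map is clipped to the
    venc limit.
    """
    if true_flow < 0:
        raise ValueError("true_flow must be non-negative")
    if pixel_area <= 0:
        raise ValueError("pixel_area must be positive")
    center = (roi_shape[0] // 2, roi_shape[1] // 2)
    mask = _disc_mask(roi_shape, center, roi_radius_px)
    if not mask.any():
        raise ValueError("empty ROI: increase roi_radius_px or the grid size")
    vmap = np.zeros(roi_shape)
    v = true_flow / (60.0 * mask.sum() * pixel_area)
    if v > venc:
        raise ValueError(
            f"vessel velocity {v:.1f} cm/s exceeds venc {venc:g} (would alias); "
            "enlarge the ROI or the pixel area"
        )
    vmap[mask] = v
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        vmap = vmap + rng.normal(0.0, noise_sd, roi_shape)
    vmap = np.clip(vmap, -venc, venc)
    return mri.VelocityScene(
        velocity_map=vmap, roi_masks={"vessel": mask}, pixel_area=pixel_area,
        venc=venc, subject_id=subject_id,
    )


def generate_artery_scene(
    flows: Mapping[str, float],
    roi_shape: tuple[int, int] = (64, 64),
    pixel_area: float = 0.0025,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    venc: float = 40.0,
    roi_radius_px: int = 6,
    subject_id: str = "",
) -> mri.VelocityScene:
    """A four-artery scene: one disc ROI per named artery flow (ml/min)."""
    if not flows:
        raise ValueError("flows must name at least one artery")
    h, w = roi_shape
    centers = [(h // 4, w // 4), (h // 4, 3 * w // 4),
               (3 * h // 4, w // 4), (3 * h // 4, 3 * w // 4)]
    if len(flows) > len(centers):
        raise ValueError("at most four arteries are supported")
    vmap = np.zeros(roi_shape)
    masks = {}
    for (name, flow), center in zip(flows.items(), centers):
        if flow < 0:
            raise ValueError(f"flow for {name!r} must be non-negative")
        mask = _disc_mask(roi_shape, center, roi_radius_px)
        if not mask.any():
            raise ValueError(f"empty ROI for {name!r}")
        v = flow / (60.0 * mask.sum() * pixel_area)
        if v > venc:
            raise ValueError(
                f"vessel velocity {v:.1f} cm/s for {name!r} exceeds venc {venc:g} "
                "(would alias); enlarge the ROI or the pixel area"
            )
        vmap[mask] = v
        masks[name] = mask
    if noise_sd > 0:
        rng = np.random.default_rng(rng)
        vmap = vmap + rng.normal(0.0, noise_sd, roi_shape)
    vmap = np.clip(vmap, -venc, venc)
    return mri.VelocityScene(
        velocity_map=vmap, roi_masks=masks, pixel_area=pixel_area, venc=venc,
        subject_id=subject_id,
    )


def generate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Cohort table plus per-subject TRUST series and velocity scenes.

    Signal truth is tied to the cohort: blood T2 follows from each subject's
    OEF through the sex-specific haematocrit calibration, and arterial flows
    follow from CBF and brain volume (density 1.06 g/ml), split across the
    four feeding arteries at the configured fractions.
    """
    cohort = generate_cohort(config)
    calib = {sex: mri.calibration_for_hct(mri.hct_default(sex)) for sex in ("male", "female")}
    fractions = dict(config.artery_fractions)
    total_frac = sum(fractions.values())

    trust_rng = _child_rng(config.seed, "trust")
    vel_rng = _child_rng(config.seed, "velocity")

    trust_series: dict[str, mri.TrustSeries] = {}
    scenes: dict[str, mri.VelocityScene] = {}
    t2_true = {}
    flows_true = {}
    for row in cohort.itertuples(index=False):
        yv_frac = (config.ya_pct / 100.0) * (1.0 - row.oef / 100.0)
        t2 = calib[row.sex].yv_to_t2(yv_frac)
        t2_true[row.subject_id] = t2
        trust_series[row.subject_id] = generate_trust_series(
            t2, config.trust_s0, config.trust_etes, config.trust_noise_sd,
            rng=trust_rng, subject_id=row.subject_id,
        )
        total_flow = row.cbf * row.brain_volume * mri.BRAIN_DENSITY_G_PER_ML / 100.0
        flows = {k: total_flow * f / total_frac for k, f in fractions.items()}
        flows_true[row.subject_id] = flows
        scenes[row.subject_id] = generate_artery_scene(
            flows, config.scene_shape, config.pixel_area, config.velocity_noise_sd,
            rng=vel_rng, venc=config.venc, roi_radius_px=config.roi_radius_px,
            subject_id=row.subject_id,
        )

    truth = {
        "config": config,
        "t2_ms": pd.Series(t2_true, name="t2_ms"),
        "flows_ml_min": pd.DataFrame(flows_true).T,
        "latents": cohort[[f"sim_latent_{d}" for d in COGNITIVE_DOMAINS]].copy(),
    }
    return SyntheticBundle(
        cohort=cohort, trust_series=trust_series, velocity_scenes=scenes, truth=truth
    )
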