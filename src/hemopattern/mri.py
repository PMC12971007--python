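"""Quantification of cerebral oxygen extraction fraction and global blood flow.

OEF path
--------
TRUST (T2-relaxation-under-spin-tagging) difference signals in the superior
sagittal sinus decay mono-exponentially with the effective echo time (eTE):

    S(eTE) = S0 * exp(-eTE / T2)

The fitted venous-blood T2 maps to venous oxygen saturation Yv through a
haematocrit-dependent relaxivity calibration, and Fick's principle gives

    OEF = (Ya - Yv) / Ya * 100 %

with arterial saturation Ya assumed 98% in healthy adults breathing room air.

CBF path
--------
Through-plane velocity maps from phase-contrast MRI are integrated over
vessel cross-section ROIs (internal carotid and vertebral arteries) to give
volumetric inflow in ml/min, which is normalised by brain mass
(volume x density, density 1.06 g/ml) to ml/100g/min.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TrustSeries",
    "BloodT2Fit",
    "CalibrationModel",
    "OefResult",
    "VelocityScene",
    "CbfResult",
    "FitError",
    "CalibrationRangeError",
    "fit_blood_t2",
    "load_calibration_params",
    "calibration_for_hct",
    "t2_to_yv",
    "yv_to_t2",
    "compute_oef",
    "hct_default",
    "integrate_flow",
    "compute_cbf",
    "BRAIN_DENSITY_G_PER_ML",
    "DEFAULT_ETES_MS",
    "DEFAULT_YA_PCT",
]

#: Brain tissue density used to convert brain volume (ml) to mass (g).
BRAIN_DENSITY_G_PER_ML = 1.06

#: Effective echo times (ms) of the TRUST acquisition this analysis targets.
DEFAULT_ETES_MS = (0.44, 40.0, 80.0, 160.0)

#: Assumed arterial oxygen saturation (%).
DEFAULT_YA_PCT = 98.0

#: Fits with T2 above this are treated as non-decaying (ms).
_T2_CEILING_MS = 10_000.0


class FitError(RuntimeError):
    """Raised when a decay series cannot be fitted to a mono-exponential."""


class CalibrationRangeError(ValueError):
    """Raised when a T2 value maps outside the calibrated saturation range."""


@dataclass(frozen=True)
class TrustSeries:
    """One subject's TRUST signal versus effective echo time."""

    etes: tuple[float, ...]
    signals: tuple[float, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        etes = tuple(float(t) for t in self.etes)
        signals = tuple(float(s) for s in self.signals)
        if len(etes) != len(signals):
            raise ValueError("etes and signals must have the same length")
        if len(etes) < 3:
            raise ValueError("a TRUST series needs at least 3 echo times")
        if not all(np.isfinite(etes)) or not all(np.isfinite(signals)):
            raise ValueError("etes and signals must be finite")
        if any(b <= a for a, b in zip(etes, etes[1:])):
            raise ValueError("effective echo times must be strictly increasing")
        object.__setattr__(self, "etes", etes)
        object.__setattr__(self, "signals", signals)


@dataclass(frozen=True)
class BloodT2Fit:
    """Mono-exponential fit result for a TRUST decay series."""

    t2: float  # ms
    s0: float  # signal amplitude at eTE = 0
    rss: float  # residual sum of squares
    n_points: int
    used_fallback: bool = False  # heuristic start was used (non-positive signals)

    def __post_init__(self) -> None:
        if self.t2 <= 0 or self.s0 <= 0 or self.rss < 0:
            raise ValueError("invalid fit: require t2 > 0, s0 > 0, rss >= 0")


def _mono_exp(t: np.ndarray, s0: float, t2: float) -> np.ndarray:
    return s0 * np.exp(-t / t2)


def fit_blood_t2(series: TrustSeries) -> BloodT2Fit:
    """Fit ``S(eTE) = S0 exp(-eTE/T2)`` to a TRUST series.

    Initial values come from a log-linear regression of ``log S`` on eTE,
    refined by Levenberg–Marquardt nonlinear least squares. Series with
    non-positive signals fall back to a heuristic start and are flagged.

    Raises
    ------
    FitError
        If the series does not decay (non-negative log-space slope, or a
        fitted T2 beyond 10 000 ms).
    """
    t = np.asarray(series.etes, dtype=float)
    s = np.asarray(series.signals, dtype=float)

    used_fallback = False
    if np.all(s > 0):
        slope, intercept = np.polyfit(t, np.log(s), 1)
        if slope >= 0:
            raise FitError(
                "series does not decay: log-signal slope "
                f"{slope:.3g} >= 0 over the echo times"
            )
        t2_init = -1.0 / slope
        s0_init = float(np.exp(intercept))
    else:
        used_fallback = True
        t2_init = float(np.median(t[t > 0])) if np.any(t > 0) else 50.0
        s0_init = float(max(np.max(s), 1.0))

    try:
        popt, _ = curve_fit(
            _mono_exp,
            t,
            s,
            p0=[s0_init, t2_init],
            maxfev=20_000,
            xtol=1e-12,
            ftol=1e-12,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological series
        raise FitError(f"nonlinear refinement failed: {exc}") from exc

    s0_hat, t2_hat = float(popt[0]), float(popt[1])
    if not np.isfinite(t2_hat) or t2_hat <= 0 or t2_hat > _T2_CEILING_MS:
        raise FitError(f"fitted T2 = {t2_hat:.3g} ms is outside (0, {_T2_CEILING_MS:g}]")
    rss = float(np.sum((s - _mono_exp(t, s0_hat, t2_hat)) ** 2))
    return BloodT2Fit(t2=t2_hat, s0=s0_hat, rss=rss, n_points=len(t), used_fallback=used_fallback)


# ---------------------------------------------------------------------------
# T2 <-> Yv calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationModel:
    """Quadratic relaxivity law linking blood T2 and venous saturation.

    ``1/T2 [s^-1] = a + b*(1-Y) + c*(1-Y)^2`` at a fixed haematocrit. Over
    ``valid_y_range`` the law must be strictly monotone: T2 increases with Y.
    """

    hct: float
    coeffs: tuple[float, float, float]  # (a, b, c), 1/s
    valid_y_range: tuple[float, float] = (0.3, 0.98)

    def __post_init__(self) -> None:
        if not 0 < self.hct < 1:
            raise ValueError("haematocrit must be a fraction in (0, 1)")
        lo, hi = self.valid_y_range
        if not 0 <= lo < hi <= 1:
            raise ValueError("valid_y_range must satisfy 0 <= lo < hi <= 1")
        a, b, c = self.coeffs
        # d(1/T2)/du = b + 2cu must stay positive on u = 1-Y over the range,
        # and the rate itself must be positive (finite positive T2).
        u = 1.0 - np.linspace(lo, hi, 101)
        rate = a + b * u + c * u * u
        if np.any(rate <= 0):
            raise ValueError("calibration gives non-positive relaxation rate in range")
        if np.any(b + 2 * c * u <= 0):
            raise ValueError("calibration is not strictly monotone over valid_y_range")

    def yv_to_t2(self, y: float) -> float:
        """Blood T2 (ms) at venous saturation ``y`` (fraction)."""
        lo, hi = self.valid_y_range
        if not lo <= y <= hi:
            raise CalibrationRangeError(
                f"Y = {y:.3f} outside calibrated range [{lo:.2f}, {hi:.2f}]"
            )
        a, b, c = self.coeffs
        u = 1.0 - y
        return 1000.0 / (a + b * u + c * u * u)

    def t2_to_yv(self, t2_ms: float) -> float:
        """Venous saturation (fraction) for blood T2 ``t2_ms`` (ms)."""
        t2_lo, t2_hi = self.valid_t2_range_ms
        if not t2_lo <= t2_ms <= t2_hi:
            raise CalibrationRangeError(
                f"T2 = {t2_ms:.2f} ms maps outside the calibrated saturation "
                f"range; admissible T2 interval is [{t2_lo:.2f}, {t2_hi:.2f}] ms"
            )
        a, b, c = self.coeffs
        rate = 1000.0 / t2_ms
        if c == 0:
            u = (rate - a) / b
        else:
            disc = b * b + 4.0 * c * (rate - a)
            u = (-b + np.sqrt(disc)) / (2.0 * c)
        return 1.0 - float(u)

    @property
    def valid_t2_range_ms(self) -> tuple[float, float]:
        lo, hi = self.valid_y_range
        # T2 is increasing in Y, so the admissible interval is [T2(lo), T2(hi)].
        a, b, c = self.coeffs
        rate = lambda y: a + b * (1 - y) + c * (1 - y) ** 2  # noqa: E731
        return 1000.0 / rate(lo), 1000.0 / rate(hi)


def load_calibration_params(path: str | None = None) -> dict:
    """Load the haematocrit-parametrized calibration coefficients.

    Defaults to the packaged representative 3 T coefficients; pass a JSON path
    to substitute an alternative published calibration.
    """
    if path is None:
        ref = resources.files("hemopattern.data").joinpath("blood_t2_calibration.json")
        return json.loads(ref.read_text())
    with open(path) as fh:
        return json.load(fh)


def calibration_for_hct(hct: float, params: Mapping | None = None) -> CalibrationModel:
    """Build a :class:`CalibrationModel` at haematocrit ``hct``.

    The packaged parametrization is ``a = A0 + A1*hct + A2*hct^2``,
    ``b = B0 + B1*hct`` and ``c = C * hct * (1 - hct)`` (all in 1/s).
    """
    if params is None:
        params = load_calibration_params()
    a = float(np.polyval(list(reversed(params["A_poly_hct"])), hct))
    b = float(np.polyval(list(reversed(params["B_poly_hct"])), hct))
    c = float(params["C_hct_scale"]) * hct * (1.0 - hct)
    return CalibrationModel(
        hct=hct, coeffs=(a, b, c), valid_y_range=tuple(params["valid_y_range"])
    )


def t2_to_yv(t2_ms: float, model: CalibrationModel) -> float:
    """Venous oxygen saturation (fraction) from blood T2 (ms)."""
    return model.t2_to_yv(t2_ms)


def yv_to_t2(yv: float, model: CalibrationModel) -> float:
    """Blood T2 (ms) from venous oxygen saturation (fraction)."""
    return model.yv_to_t2(yv)


# ---------------------------------------------------------------------------
# OEF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OefResult:
    yv: float  # venous oxygenation, %
    ya: float = DEFAULT_YA_PCT  # arterial oxygenation, %
    oef: float = field(init=False)  # %

    def __post_init__(self) -> None:
        if not 0 <= self.yv <= self.ya <= 100:
            raise ValueError("require 0 <= Yv <= Ya <= 100 (percent)")
        object.__setattr__(self, "oef", compute_oef(self.ya, self.yv))


def compute_oef(ya: float, yv: float) -> float:
    """Oxygen extraction fraction (%) from arterial/venous saturations (%)."""
    if not 0 < ya <= 100:
        raise ValueError("Ya must be in (0, 100] percent")
    if yv < 0:
        raise ValueError("Yv must be non-negative")
    if yv > ya:
        raise ValueError(
            f"Yv = {yv:.2f}% exceeds Ya = {ya:.2f}%: venous saturation cannot "
            "exceed arterial supply"
        )
    return (ya - yv) / ya * 100.0


def hct_default(sex: str) -> float:
    """Assumed haematocrit fraction: 0.42 for males, 0.40 for females."""
    code = str(sex).strip().lower()
    if code in {"male", "m", "1"}:
        return 0.42
    if code in {"female", "f", "0"}:
        return 0.40
    raise ValueError(f"unrecognized sex code: {sex!r}")


# ---------------------------------------------------------------------------
# Phase-contrast flow
# ---------------------------------------------------------------------------


@dataclass
class VelocityScene:
    """A phase-contrast through-plane velocity map with vessel ROI masks.

    velocity_map is in cm/s; pixel_area in cm^2; venc is the velocity-encoding
    limit of the acquisition.
    """

    velocity_map: np.ndarray
    roi_masks: Mapping[str, np.ndarray]
    pixel_area: float
    venc: float = 40.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.velocity_map = np.asarray(self.velocity_map, dtype=float)
        if self.velocity_map.ndim != 2:
            raise ValueError("velocity_map must be 2-D")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        if np.any(np.abs(self.velocity_map) > self.venc + 1e-9):
            raise ValueError("velocity magnitudes exceed the venc limit")
        masks = {}
        for name, mask in self.roi_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.velocity_map.shape:
                raise ValueError(f"ROI {name!r} shape does not match the velocity map")
            masks[name] = mask
        self.roi_masks = masks


def integrate_flow(
    scene: VelocityScene,
    roi_name: str,
    background_mask: np.ndarray | None = None,
) -> float:
    """Volumetric flow (ml/min) through one ROI of a velocity scene.

    Sums signed velocity (cm/s) x pixel area (cm^2) over the ROI and converts
    cm^3/s to ml/min. If ``background_mask`` is given, the median velocity over
    that mask is subtracted first as a static-tissue phase-offset correction.
    """
    if roi_name not in scene.roi_masks:
        raise ValueError(f"unknown ROI {roi_name!r}")
    mask = scene.roi_masks[roi_name]
    if not mask.any():
        raise ValueError(f"ROI {roi_name!r} is empty")
    offset = 0.0
    if background_mask is not None:
        background_mask = np.asarray(background_mask, dtype=bool)
        if background_mask.shape != scene.velocity_map.shape:
            raise ValueError("background mask shape does not match the velocity map")
        if background_mask.any():
            offset = float(np.median(scene.velocity_map[background_mask]))
    v = scene.velocity_map[mask] - offset
    return float(np.sum(v) * scene.pixel_area * 60.0)


@dataclass(frozen=True)
class CbfResult:
    total_flow: float  # ml/min
    brain_volume: float  # ml
    density: float  # g/ml
    cbf: float  # ml/100g/min
    warning: str | None = None


def compute_cbf(
    flows: Mapping[str, float] | Sequence[float],
    brain_volume: float,
    density: float = BRAIN_DENSITY_G_PER_ML,
) -> CbfResult:
    """Global CBF (ml/100g/min) from per-artery flows and brain volume.

    ``cbf = sum(flows) / (brain_volume * density) * 100``. A negative total
    flow (a signed phase-contrast artefact) is returned with a warning rather
    than rejected.
    """
    if brain_volume <= 0:
        raise ValueError("brain_volume must be positive")
    if density <= 0:
        raise ValueError("density must be positive")
    values = list(flows.values()) if isinstance(flows, Mapping) else list(flows)
    values = [float(f) for f in values]
    if not values or not all(np.isfinite(values)):
        raise ValueError("flows must be a non-empty collection of finite values")
    total = float(np.sum(values))
    warning = None
    if total < 0:
        warning = f"total flow {total:.1f} ml/min is negative (signed phase artefact?)"
        warnings.warn(warning, stacklevel=2)
    cbf = total / (brain_volume * density) * 100.0
    return CbfResult(
        total_flow=total, brain_volume=float(brain_volume), density=float(density),
        cbf=cbf, warning=warning,
    )
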