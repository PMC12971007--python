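"""Response-surface analysis of joint OEF/CBF effects.

Fits the second-order polynomial

    Z = b0 + b1*X + b2*Y + b3*X^2 + b4*X*Y + b5*Y^2 (+ covariates)

with X = mean-centred OEF and Y = mean-centred CBF, and tests the fitted
surface along two lines in the predictor plane:

* the **balance axis** (CBF = OEF in centred units): slope ``b1 + b2``,
  curvature ``b3 + b4 + b5`` — coordinated supply/demand states;
* the **bias (mismatch) axis** (CBF = -OEF + 2*mu in raw units): slope
  ``b1 - b2``, curvature ``b3 - b4 + b5`` — supply/demand mismatch, whose
  high-OEF/low-CBF end is the misery-perfusion corner.

Axis quantities are linear combinations ``c'b`` of the surface coefficients;
their standard errors come from the delta method, ``SE^2 = c' Sigma c``, with
Sigma the OLS coefficient covariance. Axis values are parametrized per unit
of X along the line (so slopes are exactly b1 +/- b2), not per unit arc
length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._ols import ols

__all__ = [
    "RsaFit",
    "AxisTests",
    "SurfaceGrid",
    "ResponseSurfaceRegressor",
    "fit_rsa",
    "axis_tests",
    "axis_tests_from_coefficients",
    "predict_surface",
    "AXIS_COMBINATIONS",
    "CI_Z",
]

#: Wald normal-approximation multiplier for 95% confidence intervals.
CI_Z = 1.96

#: Combination vectors over (b0, b1, b2, b3, b4, b5) defining the axis tests.
AXIS_COMBINATIONS: dict[str, np.ndarray] = {
    "balance_slope": np.array([0.0, 1, 1, 0, 0, 0]),
    "balance_curvature": np.array([0.0, 0, 0, 1, 1, 1]),
    "bias_slope": np.array([0.0, 1, -1, 0, 0, 0]),
    "bias_curvature": np.array([0.0, 0, 0, 1, -1, 1]),
}

_COEF_NAMES = ("b0", "b1_x", "b2_y", "b3_x2", "b4_xy", "b5_y2")


@dataclass
class RsaFit:
    """A fitted second-order response surface."""

    coef: np.ndarray  # b0..b5
    cov: np.ndarray | None  # 6x6 covariance of b0..b5
    mu_x: float  # centring mean of X (raw OEF units)
    mu_y: float  # centring mean of Y (raw CBF units)
    n_used: int
    outcome: str = "outcome"
    covariate_names: tuple[str, ...] = ()
    covariate_coef: np.ndarray | None = None
    covariate_mode: str = "adjust"
    x_range: tuple[float, float] = (0.0, 0.0)  # centred X range observed
    y_range: tuple[float, float] = (0.0, 0.0)
    x_sd: float = 1.0
    y_sd: float = 1.0

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (6,):
            raise ValueError("coef must hold the six surface coefficients b0..b5")
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)
            if self.cov.shape != (6, 6):
                raise ValueError("cov must be 6x6 (restricted to b0..b5)")
            if not np.allclose(self.cov, self.cov.T, atol=1e-10):
                raise ValueError("cov must be symmetric")

    def predict_surface_value(self, x, y):
        """Polynomial value at centred coordinates (x, y); covariates at 0."""
        b = self.coef
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return b[0] + b[1] * x + b[2] * y + b[3] * x * x + b[4] * x * y + b[5] * y * y


@dataclass
class AxisTests:
    """Slopes and curvatures along the balance and bias axes."""

    estimates: dict[str, float]
    ses: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    ci_z: float = CI_Z

    def __getitem__(self, key: str) -> float:
        return self.estimates[key]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": k,
                "estimate": self.estimates[k],
                "se": self.ses[k],
                "lo": self.conf_int[k][0],
                "hi": self.conf_int[k][1],
            }
            for k in self.estimates
        ]
        return pd.DataFrame(rows)


@dataclass
class SurfaceGrid:
    """Predicted surface on a rectangular grid plus the two axis polylines."""

    x: np.ndarray  # centred X grid (1-D)
    y: np.ndarray  # centred Y grid (1-D)
    z: np.ndarray  # predictions, shape (len(y), len(x))
    balance_line: pd.DataFrame  # columns t, x, y, z
    bias_line: pd.DataFrame
    mu_x: float
    mu_y: float

    def as_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "z_pred": self.z.ravel()}
        )


class ResponseSurfaceRegressor(RegressorMixin, BaseEstimator):
    """Second-order polynomial regression of an outcome on (OEF, CBF).

    Parameters
    ----------
    center : bool, default True
        Centre X and Y at their sample means before building the polynomial.
    covariate_mode : {"adjust", "residualize"}, default "adjust"
        "adjust" places covariates inside the polynomial regression;
        "residualize" first regresses the outcome on the covariates (plus an
        intercept) and fits the surface to the residuals — a sensitivity
        variant; the two generally differ and the mode is recorded on the fit.
    ci_z : float, default 1.96
        Wald multiplier used for the 95% confidence intervals.

    Attributes
    ----------
    coef_ : ndarray of shape (6,) — b0..b5.
    coef_covariance_ : ndarray (6, 6) — classical OLS covariance of b0..b5.
    mu_ : ndarray (2,) — centring means of (X, Y).
    rsa_fit_ : :class:`RsaFit` bundling everything for axis tests and grids.
    """

    def __init__(self, center: bool = True, covariate_mode: str = "adjust",
                 ci_z: float = CI_Z):
        self.center = center
        self.covariate_mode = covariate_mode
        self.ci_z = ci_z

    def fit(self, X, y, covariates=None, outcome_name: str = "outcome"):
        if self.covariate_mode not in ("adjust", "residualize"):
            raise ValueError("covariate_mode must be 'adjust' or 'residualize'")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of (OEF, CBF)")
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        cov_names: tuple[str, ...] = ()
        C = None
        if covariates is not None:
            if isinstance(covariates, pd.DataFrame):
                cov_names = tuple(covariates.columns)
                C = covariates.to_numpy(dtype=float)
            else:
                C = np.asarray(covariates, dtype=float)
                if C.ndim == 1:
                    C = C[:, None]
                cov_names = tuple(f"cov{j}" for j in range(C.shape[1]))
        n_cov = 0 if C is None else C.shape[1]
        if n < 6 + n_cov + 1:
            raise ValueError("too few observations for a second-order surface")
        if np.ptp(X[:, 0]) == 0 or np.ptp(X[:, 1]) == 0:
            raise ValueError("X and Y must be non-degenerate")

        mu = X.mean(axis=0) if self.center else np.zeros(2)
        xc = X[:, 0] - mu[0]
        yc = X[:, 1] - mu[1]
        poly = np.column_stack([np.ones(n), xc, yc, xc * xc, xc * yc, yc * yc])
        names = list(_COEF_NAMES)

        cov_coef = None
        if C is not None and self.covariate_mode == "residualize":
            base = np.column_stack([np.ones(n), C])
            bcov, _, resid, _ = ols(base, y, names=["intercept", *cov_names])
            cov_coef = bcov[1:]
            z = resid + float(bcov[0])  # keep the grand mean in b0
            design = poly
        elif C is not None:
            design = np.column_stack([poly, C])
            names = names + list(cov_names)
            z = y
        else:
            design = poly
            z = y

        beta, cov_beta, resid, df = ols(design, z, names=names)
        self.coef_ = beta[:6]
        self.coef_covariance_ = cov_beta[:6, :6]
        if C is not None and self.covariate_mode == "adjust":
            cov_coef = beta[6:]
        self.covariate_coef_ = cov_coef
        self.mu_ = mu
        self.df_resid_ = df
        self.n_features_in_ = 2
        self.rsa_fit_ = RsaFit(
            coef=self.coef_,
            cov=self.coef_covariance_,
            mu_x=float(mu[0]),
            mu_y=float(mu[1]),
            n_used=n,
            outcome=outcome_name,
            covariate_names=cov_names,
            covariate_coef=cov_coef,
            covariate_mode=self.covariate_mode,
            x_range=(float(xc.min()), float(xc.max())),
            y_range=(float(yc.min()), float(yc.max())),
            x_sd=float(np.std(xc, ddof=1)),
            y_sd=float(np.std(yc, ddof=1)),
        )
        return self

    def predict(self, X, covariates=None):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        xc = X[:, 0] - self.mu_[0]
        yc = X[:, 1] - self.mu_[1]
        out = self.rsa_fit_.predict_surface_value(xc, yc)
        if covariates is not None and self.covariate_coef_ is not None:
            C = (
                covariates.to_numpy(dtype=float)
                if isinstance(covariates, pd.DataFrame)
                else np.asarray(covariates, dtype=float)
            )
            if C.ndim == 1:
                C = C[:, None]
            out = out + C @ self.covariate_coef_
        return out

    def axis_tests(self) -> AxisTests:
        check_is_fitted(self, "coef_")
        return axis_tests(self.rsa_fit_, ci_z=self.ci_z)


def fit_rsa(x, y, z, covariates=None, center: bool = True,
            covariate_mode: str = "adjust", outcome_name: str = "outcome") -> RsaFit:
    """Fit the response surface of outcome ``z`` on OEF ``x`` and CBF ``y``."""
    reg = ResponseSurfaceRegressor(center=center, covariate_mode=covariate_mode)
    reg.fit(np.column_stack([np.asarray(x, float), np.asarray(y, float)]), z,
            covariates=covariates, outcome_name=outcome_name)
    return reg.rsa_fit_


def axis_tests(fit: RsaFit, ci_z: float = CI_Z) -> AxisTests:
    """Balance/bias axis slopes and curvatures with delta-method CIs.

    Requires the coefficient covariance stored on the fit; a zero matrix is
    accepted (SEs 0, intervals collapse to the estimates).
    """
    if fit.cov is None:
        raise ValueError("fit carries no coefficient covariance")
    return axis_tests_from_coefficients(fit.coef, fit.cov, ci_z=ci_z)


def axis_tests_from_coefficients(coef, cov=None, ci_z: float = CI_Z) -> AxisTests:
    """Axis statistics from raw surface coefficients b0..b5.

    ``cov`` defaults to a zero matrix (point estimates only) so printed
    coefficient tables can be fed in directly.
    """
    b = np.asarray(coef, dtype=float)
    if b.shape != (6,):
        raise ValueError("expected the six surface coefficients b0..b5")
    sigma = np.zeros((6, 6)) if cov is None else np.asarray(cov, dtype=float)
    est, ses, cis = {}, {}, {}
    for name, c in AXIS_COMBINATIONS.items():
        value = float(c @ b)
        se = float(np.sqrt(c @ sigma @ c))
        est[name] = value
        ses[name] = se
        cis[name] = (value - ci_z * se, value + ci_z * se)
    return AxisTests(estimates=est, ses=ses, conf_int=cis, ci_z=ci_z)


def predict_surface(fit: RsaFit, n_grid: int = 50, span: float = 2.5,
                    n_line: int = 101,
                    x_range: tuple[float, float] | None = None,
                    y_range: tuple[float, float] | None = None) -> SurfaceGrid:
    """Evaluate the fitted polynomial on a grid and along the two axes.

    By default the grid covers the observed centred X/Y ranges, clipped to
    ``span`` standard deviations from the centre (no extrapolation beyond the
    data or the trust region). Explicit ``x_range``/``y_range`` (centred
    units) are rejected if they extend beyond ``span`` SDs. The balance line
    is Y = X and the bias line Y = -X in centred units (the latter is
    CBF = -OEF + 2*mu in raw units); both are parametrized by X.
    """
    if n_grid < 2 or n_line < 2:
        raise ValueError("grid must have at least 2 points per dimension")

    def _resolve(requested, observed, sd, name):
        lim = span * sd
        if requested is None:
            return max(observed[0], -lim), min(observed[1], lim)
        lo, hi = float(requested[0]), float(requested[1])
        if lo >= hi:
            raise ValueError(f"empty {name} grid range")
        if lo < -lim - 1e-12 or hi > lim + 1e-12:
            raise ValueError(f"requested {name} range exceeds +/-{span} SD")
        return lo, hi

    x_lo, x_hi = _resolve(x_range, fit.x_range, fit.x_sd, "x")
    y_lo, y_hi = _resolve(y_range, fit.y_range, fit.y_sd, "y")
    x = np.linspace(x_lo, x_hi, n_grid)
    y = np.linspace(y_lo, y_hi, n_grid)
    xx, yy = np.meshgrid(x, y)
    z = fit.predict_surface_value(xx, yy)

    t_lim = min(max(abs(x_lo), abs(x_hi)), max(abs(y_lo), abs(y_hi)))
    t = np.linspace(-t_lim, t_lim, n_line)
    balance = pd.DataFrame(
        {"t": t, "x": t, "y": t, "z": fit.predict_surface_value(t, t)}
    )
    bias = pd.DataFrame(
        {"t": t, "x": t, "y": -t, "z": fit.predict_surface_value(t, -t)}
    )
    return SurfaceGrid(x=x, y=y, z=z, balance_line=balance, bias_line=bias,
                       mu_x=fit.mu_x, mu_y=fit.mu_y)
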