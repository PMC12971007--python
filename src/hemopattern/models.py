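"""Covariate-adjusted linear models for the haemodynamic-pattern analyses.

Quadrant contrasts (the misery-perfusion quadrant Q2 as reference),
continuous OEF/CBF slopes, vascular-risk and APOE-stratified analyses, and a
MANCOVA sensitivity analysis with Pillai's trace.

All linear fits are ordinary least squares (Gaussian GLM with identity link);
confidence intervals are Wald normal-approximation, estimate +/- 1.96 SE.
The MANCOVA builds the hypothesis (H) and error (E) cross-product matrices
explicitly and reports ``V = tr[H (H+E)^-1]`` with the standard F
approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._ols import check_full_rank
from .rsa import CI_Z

__all__ = [
    "ModelSpec",
    "ModelResult",
    "MancovaResult",
    "fit_linear",
    "run_quadrant_battery",
    "run_stratified",
    "mancova",
    "QUADRANTS",
    "REFERENCE_QUADRANT",
    "COGNITION_OUTCOMES",
]

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")
REFERENCE_QUADRANT = "Q2"

#: Global composite plus the six domain composites, in reporting order.
COGNITION_OUTCOMES = (
    "global_cognition",
    "domain_executive",
    "domain_attention",
    "domain_language",
    "domain_visuomotor",
    "domain_visuospatial",
    "domain_memory",
)


@dataclass
class ModelSpec:
    """One linear model: outcome ~ exposure + covariates on an optional subset."""

    outcome: str
    exposure: str  # "quadrant" or a continuous column such as "oef"/"cbf"
    covariates: tuple[str, ...] = ("age", "male")
    subset: str | None = None  # pandas query string, e.g. "infarct == 0"
    reference: str = REFERENCE_QUADRANT


@dataclass
class ModelResult:
    """Per-term estimates of one fitted model."""

    outcome: str
    exposure: str
    terms: pd.DataFrame  # term, beta, se, lo, hi
    n_used: int
    model_name: str = "model"

    def term(self, name: str) -> pd.Series:
        return self.terms.set_index("term").loc[name]


def _design(data: pd.DataFrame, spec: ModelSpec):
    cols = [spec.outcome, *spec.covariates]
    cols += ["quadrant"] if spec.exposure == "quadrant" else [spec.exposure]
    df = data.query(spec.subset) if spec.subset else data
    df = df.dropna(subset=[c for c in cols if c in df.columns])
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"columns missing from data: {missing}")
    if len(df) == 0:
        raise ValueError("empty subset after filtering")

    y = df[spec.outcome].to_numpy(dtype=float)
    names = ["intercept"]
    parts = [np.ones(len(df))]
    exposure_terms: list[str] = []
    if spec.exposure == "quadrant":
        levels = [q for q in QUADRANTS if q != spec.reference]
        present = set(df["quadrant"].astype(str))
        if spec.reference not in present:
            raise ValueError(f"reference level {spec.reference!r} absent from data")
        for q in levels:
            names.append(q)
            exposure_terms.append(q)
            parts.append((df["quadrant"].astype(str) == q).to_numpy(dtype=float))
    else:
        names.append(spec.exposure)
        exposure_terms.append(spec.exposure)
        parts.append(df[spec.exposure].to_numpy(dtype=float))
    for c in spec.covariates:
        names.append(c)
        parts.append(df[c].to_numpy(dtype=float))
    X = np.column_stack(parts)
    return X, y, names, exposure_terms, len(df)


def fit_linear(spec: ModelSpec, data: pd.DataFrame, model_name: str = "model") -> ModelResult:
    """OLS fit of ``spec`` on ``data`` with Wald 95% CIs.

    Quadrant exposure is dummy-coded against the Q2 (high OEF + low CBF)
    reference; the reference level is reported with a coefficient of exactly
    zero. Rank-deficient designs raise an error naming the collinear columns.
    """
    X, y, names, exposure_terms, n = _design(data, spec)
    if n <= X.shape[1]:
        raise ValueError(f"n = {n} does not exceed the {X.shape[1]} parameters")
    check_full_rank(X, names)
    res = sm.OLS(y, X).fit()
    rows = []
    for name, beta, se in zip(names, res.params, res.bse):
        rows.append(
            {"term": name, "beta": float(beta), "se": float(se),
             "lo": float(beta - CI_Z * se), "hi": float(beta + CI_Z * se)}
        )
    if spec.exposure == "quadrant":
        rows.append({"term": spec.reference, "beta": 0.0, "se": 0.0, "lo": 0.0, "hi": 0.0})
    return ModelResult(
        outcome=spec.outcome, exposure=spec.exposure,
        terms=pd.DataFrame(rows), n_used=n, model_name=model_name,
    )


def run_quadrant_battery(data: pd.DataFrame) -> pd.DataFrame:
    """The full quadrant-contrast battery in tidy long format.

    Outcomes and covariate sets:

    * ``log_wmh`` on the infarct-free subset — model 1 adjusts for age and
      sex, model 2 additionally for the vascular risk score;
    * global cognition and the six domain composites — model 1 adjusts for
      age, sex and education, model 2 additionally for the vascular risk
      score.

    Returns one row per (outcome, model, non-reference quadrant contrast):
    columns outcome, model, term, beta, se, lo, hi, n.
    """
    batteries = [("log_wmh", ("age", "male"), "infarct == 0")]
    batteries += [(o, ("age", "male", "education"), None) for o in COGNITION_OUTCOMES]
    records = []
    for outcome, covs, subset in batteries:
        for model_name, covariates in (
            ("model1", covs),
            ("model2", covs + ("vrs",)),
        ):
            spec = ModelSpec(outcome=outcome, exposure="quadrant",
                             covariates=covariates, subset=subset)
            result = fit_linear(spec, data, model_name=model_name)
            contrasts = result.terms[result.terms["term"].isin(
                [q for q in QUADRANTS if q != spec.reference]
            )]
            for _, row in contrasts.iterrows():
                records.append(
                    {"outcome": outcome, "model": model_name, **row.to_dict(),
                     "n": result.n_used}
                )
    return pd.DataFrame.from_records(records)


def run_stratified(data: pd.DataFrame, stratifier: str) -> pd.DataFrame:
    """Continuous OEF/CBF slope models within strata.

    ``stratifier`` is ``"vrs"`` (low: score <= 2, high: >= 3) or ``"apoe"``
    (carrier vs non-carrier; ungenotyped subjects are dropped). Within each
    stratum, each of OEF and CBF is the exposure for ``log_wmh`` (age + sex,
    infarct-free) and ``global_cognition`` (age + sex + education). Strata too
    small for the parameter count are skipped with a warning.
    """
    if stratifier == "vrs":
        groups = {"low": data["vrs"] <= 2, "high": data["vrs"] >= 3}
    elif stratifier == "apoe":
        groups = {"non_carrier": data["apoe4"] == 0, "carrier": data["apoe4"] == 1}
    else:
        raise ValueError("stratifier must be 'vrs' or 'apoe'")
    non_empty = {k: m for k, m in groups.items() if m.sum() > 0}
    if len(non_empty) < 2:
        warnings.warn(
            f"stratifier {stratifier!r} yields {len(non_empty)} non-empty stratum(era); "
            "reporting what exists", stacklevel=2,
        )
    records = []
    outcome_specs = [
        ("log_wmh", ("age", "male"), "infarct == 0"),
        ("global_cognition", ("age", "male", "education"), None),
    ]
    for stratum, mask in non_empty.items():
        sub = data[mask]
        for outcome, covs, subset in outcome_specs:
            for exposure in ("oef", "cbf"):
                spec = ModelSpec(outcome=outcome, exposure=exposure,
                                 covariates=covs, subset=subset)
                try:
                    result = fit_linear(spec, sub, model_name=f"{stratifier}_{stratum}")
                except ValueError as exc:
                    warnings.warn(
                        f"skipping {outcome}~{exposure} in stratum {stratum!r}: {exc}",
                        stacklevel=2,
                    )
                    continue
                row = result.term(exposure)
                records.append(
                    {"stratifier": stratifier, "stratum": stratum,
                     "outcome": outcome, "exposure": exposure,
                     "beta": row["beta"], "se": row["se"],
                     "lo": row["lo"], "hi": row["hi"], "n": result.n_used}
                )
    return pd.DataFrame.from_records(records)


@dataclass
class MancovaResult:
    """Pillai-trace tests per exposure term plus univariate follow-ups."""

    terms: pd.DataFrame  # term, pillai, F, df1, df2, p
    followup: pd.DataFrame  # term, outcome, F, df1, df2, p

    def term(self, name: str) -> pd.Series:
        return self.terms.set_index("term").loc[name]


def _pillai_f(V: float, p: int, q: int, dfe: int):
    """Standard F approximation for Pillai's trace."""
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    n_ = (dfe - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n_ + s + 1)
    F = (df2 / df1) * (V / (s - V))
    return F, df1, df2


def mancova(
    outcomes: pd.DataFrame,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> MancovaResult:
    """MANCOVA of several outcomes on exposure terms, adjusting for covariates.

    For each exposure column, the hypothesis cross-product matrix is
    ``H = (L b)' [L (X'X)^-1 L']^-1 (L b)`` with L selecting that term from
    the full design (intercept + covariates + exposures), and E is the
    residual cross-product matrix. Pillai's trace ``V = tr[H (H+E)^-1]`` is
    reported with its F approximation, plus per-outcome follow-up ANCOVA
    F tests of the same term.
    """
    from scipy import stats

    Y = pd.DataFrame(outcomes)
    E_x = pd.DataFrame(exposures)
    names = ["intercept"]
    parts = [np.ones(len(Y))]
    if covariates is not None:
        C = pd.DataFrame(covariates)
        for c in C.columns:
            names.append(str(c))
            parts.append(C[c].to_numpy(dtype=float))
    exposure_names = [str(c) for c in E_x.columns]
    for c in E_x.columns:
        names.append(str(c))
        parts.append(E_x[c].to_numpy(dtype=float))
    X = np.column_stack(parts)
    n, k = X.shape
    p = Y.shape[1]
    if n <= p + k:
        raise ValueError("too few observations for the outcome and parameter count")
    check_full_rank(X, names)

    Ymat = Y.to_numpy(dtype=float)
    G = np.linalg.inv(X.T @ X)
    B = G @ X.T @ Ymat  # k x p coefficient matrix
    resid = Ymat - X @ B
    E = resid.T @ resid
    if np.linalg.matrix_rank(E) < p:
        raise np.linalg.LinAlgError("singular error cross-product matrix")
    dfe = n - k

    term_rows, follow_rows = [], []
    for term in exposure_names:
        j = names.index(term)
        L = np.zeros((1, k))
        L[0, j] = 1.0
        LB = L @ B  # 1 x p
        M = np.linalg.inv(L @ G @ L.T)  # 1 x 1
        H = LB.T @ M @ LB  # p x p
        q = 1
        V = float(np.trace(H @ np.linalg.inv(H + E)))
        F, df1, df2 = _pillai_f(V, p, q, dfe)
        pval = float(stats.f.sf(F, df1, df2))
        term_rows.append(
            {"term": term, "pillai": V, "F": F, "df1": df1, "df2": df2, "p": pval}
        )
        for i, outcome in enumerate(Y.columns):
            Fu = float(H[i, i] / q / (E[i, i] / dfe))
            follow_rows.append(
                {"term": term, "outcome": str(outcome), "F": Fu, "df1": q,
                 "df2": dfe, "p": float(stats.f.sf(Fu, q, dfe))}
            )
    return MancovaResult(
        terms=pd.DataFrame(term_rows), followup=pd.DataFrame(follow_rows)
    )
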