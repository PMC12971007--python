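"""Derived analysis variables for the haemodynamic cohort.

Builds, from a per-subject table of demographics, risk factors, OEF/CBF and
raw neuropsychological scores:

* per-test, per-domain and global cognitive Z-composites (whole-sample
  standardization at every level, so the global composite is 0 +/- 1 by
  construction);
* log-transformed white-matter-hyperintensity volume;
* the 0-5 vascular risk score (hypertension, diabetes, hyperlipidaemia,
  ever smoking, obesity BMI > 28) and its low (<=2) / high (>=3) strata;
* joint OEF x CBF quadrant labels from median splits, where Q2
  (high OEF + low CBF) is the "misery perfusion" phenotype.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "COGNITIVE_DOMAINS",
    "TIMED_TESTS",
    "CognitiveStandardizer",
    "QuadrantAssigner",
    "standardize_cognition",
    "log_wmh",
    "vascular_risk_score",
    "assign_quadrants",
    "derive_variables",
    "describe_cohort",
    "WMH_LOG_FLOOR_CM3",
    "VRS_COMPONENTS",
    "OBESITY_BMI_THRESHOLD",
]

#: Test battery grouped into the six cognitive domains.
COGNITIVE_DOMAINS: dict[str, tuple[str, ...]] = {
    "executive": ("colour_trails_a", "colour_trails_b"),
    "attention": ("digit_span_forward", "digit_span_backward"),
    "language": ("boston_naming",),
    "visuomotor": ("symbol_digit",),
    "visuospatial": ("rcft_copy",),
    "memory": (
        "rcft_immediate",
        "rcft_delayed",
        "rcft_recognition",
        "hvlt_immediate",
        "hvlt_delayed",
        "hvlt_recognition",
    ),
}

#: Timed tests where a higher raw value means worse performance; these are
#: sign-flipped before standardization so higher Z = better everywhere.
TIMED_TESTS = frozenset({"colour_trails_a", "colour_trails_b"})

#: Floor added before the log transform of WMH volume (cm^3).
WMH_LOG_FLOOR_CM3 = 0.01

#: Binary components of the vascular risk score (obesity is derived from BMI).
VRS_COMPONENTS = ("hypertension", "diabetes", "hyperlipidaemia", "smoking_ever")

#: Obesity cut-off (strict inequality).
OBESITY_BMI_THRESHOLD = 28.0


class CognitiveStandardizer(TransformerMixin, BaseEstimator):
    """Whole-sample Z-score composites: tests -> domains -> global cognition.

    ``fit`` learns, from the fitting sample, the per-test means/SDs (after
    sign-flipping the timed tests), then the mean/SD of each domain composite
    (the mean of its tests' Z-scores), then the mean/SD of the global
    composite (the mean of the domain Z-scores). ``transform`` applies those
    constants, so on the fitting sample itself every composite has mean 0 and
    SD 1 (sample SD, ``ddof=1``).

    Parameters
    ----------
    domains : mapping of domain name -> test column names, optional
        Defaults to the six-domain battery in :data:`COGNITIVE_DOMAINS`.
    negate : collection of test names whose raw scale is "higher = worse".
    ddof : delta degrees of freedom of the SD (1 = sample SD).
    """

    def __init__(self, domains=None, negate=None, ddof: int = 1):
        self.domains = domains
        self.negate = negate
        self.ddof = ddof

    def _resolved(self):
        domains = dict(self.domains) if self.domains is not None else dict(COGNITIVE_DOMAINS)
        negate = frozenset(self.negate) if self.negate is not None else TIMED_TESTS
        return domains, negate

    def fit(self, X: pd.DataFrame, y=None) -> "CognitiveStandardizer":
        domains, negate = self._resolved()
        X = pd.DataFrame(X)
        if len(X) < 2:
            raise ValueError("standardization needs at least 2 subjects")
        tests = [t for tests in domains.values() for t in tests]
        missing = [t for t in tests if t not in X.columns]
        if missing:
            raise ValueError(f"missing test columns: {missing}")
        signed = X[tests].astype(float)
        for t in tests:
            if t in negate:
                signed[t] = -signed[t]
        means = signed.mean()
        sds = signed.std(ddof=self.ddof)
        zero_var = sds.index[sds == 0].tolist()
        if zero_var:
            raise ValueError(f"zero-variance test(s): {zero_var}")
        z = (signed - means) / sds
        domain_raw = pd.DataFrame({d: z[list(ts)].mean(axis=1) for d, ts in domains.items()})
        d_means = domain_raw.mean()
        d_sds = domain_raw.std(ddof=self.ddof)
        if (d_sds == 0).any():
            raise ValueError(
                f"zero-variance domain(s): {d_sds.index[d_sds == 0].tolist()}"
            )
        domain_z = (domain_raw - d_means) / d_sds
        global_raw = domain_z.mean(axis=1)
        g_sd = global_raw.std(ddof=self.ddof)
        if g_sd == 0:
            raise ValueError("zero-variance global composite")
        self.test_means_ = means
        self.test_sds_ = sds
        self.domain_means_ = d_means
        self.domain_sds_ = d_sds
        self.global_mean_ = float(global_raw.mean())
        self.global_sd_ = float(g_sd)
        self.n_features_in_ = len(tests)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "test_means_")
        domains, negate = self._resolved()
        X = pd.DataFrame(X)
        tests = list(self.test_means_.index)
        signed = X[tests].astype(float)
        for t in tests:
            if t in negate:
                signed[t] = -signed[t]
        z = (signed - self.test_means_) / self.test_sds_
        out = z.add_prefix("z_")
        domain_raw = pd.DataFrame({d: z[list(ts)].mean(axis=1) for d, ts in domains.items()})
        domain_z = (domain_raw - self.domain_means_) / self.domain_sds_
        for d in domains:
            out[f"domain_{d}"] = domain_z[d]
        out["global_cognition"] = (
            domain_z.mean(axis=1) - self.global_mean_
        ) / self.global_sd_
        out.index = X.index
        return out


def standardize_cognition(
    raw: pd.DataFrame,
    domains: Mapping[str, Sequence[str]] | None = None,
    negate=None,
) -> pd.DataFrame:
    """Z-score composites of ``raw`` against its own sample (fit + transform)."""
    return CognitiveStandardizer(domains=domains, negate=negate).fit_transform(raw)


def log_wmh(volume, floor: float = WMH_LOG_FLOOR_CM3):
    """Natural log of WMH volume (cm^3) with a small floor for zero lesions."""
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise ValueError("WMH volume cannot be negative")
    out = np.log(v + floor)
    return float(out) if np.isscalar(volume) or out.ndim == 0 else out


def _vrs_one(record: Mapping) -> tuple[int, str]:
    needed = list(VRS_COMPONENTS) + ["bmi"]
    for key in needed:
        if key not in record or record[key] is None or (
            isinstance(record[key], float) and np.isnan(record[key])
        ):
            raise ValueError(f"vascular risk component {key!r} is missing (no imputation)")
    score = sum(int(bool(record[k])) for k in VRS_COMPONENTS)
    score += int(float(record["bmi"]) > OBESITY_BMI_THRESHOLD)
    return score, ("low" if score <= 2 else "high")


def vascular_risk_score(record):
    """Vascular risk score 0-5 and low/high stratum.

    Sums hypertension, diabetes, hyperlipidaemia, ever smoking and obesity
    (BMI strictly greater than 28). Accepts a mapping (returns
    ``(score, stratum)``) or a DataFrame (returns a DataFrame with ``vrs``,
    ``vrs_stratum`` and ``obese`` columns). Missing components raise.
    """
    if isinstance(record, pd.DataFrame):
        needed = list(VRS_COMPONENTS) + ["bmi"]
        missing = [c for c in needed if c not in record.columns]
        if missing:
            raise ValueError(f"vascular risk component(s) {missing} are missing")
        if record[needed].isna().any().any():
            bad = record[needed].columns[record[needed].isna().any()].tolist()
            raise ValueError(f"vascular risk component(s) {bad} contain missing values")
        obese = record["bmi"].astype(float) > OBESITY_BMI_THRESHOLD
        vrs = record[list(VRS_COMPONENTS)].astype(bool).sum(axis=1) + obese.astype(int)
        return pd.DataFrame(
            {
                "vrs": vrs.astype(int),
                "vrs_stratum": np.where(vrs <= 2, "low", "high"),
                "obese": obese.astype(int),
            },
            index=record.index,
        )
    return _vrs_one(record)


class QuadrantAssigner(TransformerMixin, BaseEstimator):
    """Median-split OEF x CBF quadrant labels.

    ``fit`` learns the sample medians of OEF and CBF; ``predict`` labels each
    subject Q1 (high OEF + high CBF), Q2 (high OEF + low CBF, "misery
    perfusion"), Q3 (low OEF + low CBF) or Q4 (low OEF + high CBF). "High"
    means strictly above the median; values equal to the median go to "low",
    which keeps the rule deterministic.
    """

    def fit(self, X, y=None) -> "QuadrantAssigner":
        X = self._as_array(X)
        if len(X) < 4:
            raise ValueError("quadrant assignment needs at least 4 subjects")
        if not np.all(np.isfinite(X)):
            raise ValueError("OEF/CBF values must be finite")
        if np.ptp(X[:, 0]) == 0 or np.ptp(X[:, 1]) == 0:
            raise ValueError("degenerate split: all OEF or all CBF values identical")
        self.median_oef_ = float(np.median(X[:, 0]))
        self.median_cbf_ = float(np.median(X[:, 1]))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "median_oef_")
        X = self._as_array(X)
        high_oef = X[:, 0] > self.median_oef_
        high_cbf = X[:, 1] > self.median_cbf_
        labels = np.where(
            high_oef,
            np.where(high_cbf, "Q1", "Q2"),
            np.where(high_cbf, "Q4", "Q3"),
        )
        return labels

    def transform(self, X) -> np.ndarray:
        return self.predict(X)[:, None]

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[["oef", "cbf"]] if {"oef", "cbf"} <= set(X.columns) else X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected a 2-column array of (OEF, CBF)")
        return X


def assign_quadrants(oef, cbf):
    """Quadrant labels plus the (median OEF, median CBF) split points."""
    X = np.column_stack([np.asarray(oef, float), np.asarray(cbf, float)])
    qa = QuadrantAssigner().fit(X)
    return qa.predict(X), (qa.median_oef_, qa.median_cbf_)


def derive_variables(cohort: pd.DataFrame) -> pd.DataFrame:
    """All derived analysis variables for a cohort table.

    Returns the cohort with cognitive Z-composites, ``log_wmh``, ``vrs``/
    ``vrs_stratum``/``obese``, ``quadrant``, and a 0/1 ``male`` indicator.
    Simulation-truth columns (``sim_*``) are dropped.
    """
    df = cohort.copy()
    df = df.drop(columns=[c for c in df.columns if c.startswith("sim_")])
    comps = standardize_cognition(df)
    keep = [c for c in comps.columns if not c.startswith("z_")]
    df = pd.concat([df, comps[keep]], axis=1)
    df["log_wmh"] = log_wmh(df["wmh_volume"].to_numpy())
    df = pd.concat([df, vascular_risk_score(df)], axis=1)
    labels, (med_oef, med_cbf) = assign_quadrants(df["oef"], df["cbf"])
    df["quadrant"] = labels
    df.attrs["median_oef"] = med_oef
    df.attrs["median_cbf"] = med_cbf
    df["male"] = (df["sex"].astype(str).str.lower().isin(["male", "m", "1"])).astype(int)
    return df


def describe_cohort(cohort: pd.DataFrame) -> dict:
    """Table-1-style summary counts and percentages."""
    n = len(cohort)
    male = (cohort["sex"].astype(str).str.lower().isin(["male", "m", "1"])).sum()
    female = n - male
    out = {
        "n": int(n),
        "n_male": int(male),
        "pct_male": round(100.0 * male / n, 2),
        "female_male_ratio": round(female / male, 2) if male else float("inf"),
    }
    if "apoe4" in cohort.columns:
        genotyped = cohort["apoe4"].notna()
        n_gen = int(genotyped.sum())
        out["n_genotyped"] = n_gen
        if n_gen:
            carriers = int(cohort.loc[genotyped, "apoe4"].astype(float).sum())
            out["n_apoe4_carriers"] = carriers
            out["pct_apoe4_carriers"] = round(100.0 * carriers / n_gen, 1)
    for col in ("oef", "cbf", "age", "bmi", "wmh_volume"):
        if col in cohort.columns:
            out[f"{col}_mean"] = float(cohort[col].mean())
            out[f"{col}_sd"] = float(cohort[col].std(ddof=1))
    return out
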