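"""Linear models, quadrant battery, stratified analyses and MANCOVA."""

import numpy as np
import pandas as pd
import pytest

from hemopattern import SimulationConfig, generate_cohort
from hemopattern.cohort import derive_variables
from hemopattern.models import (
    ModelSpec,
    fit_linear,
    mancova,
    run_quadrant_battery,
    run_stratified,
)
from hemopattern._ols import RankDeficiencyError, check_full_rank


class TestFitLinear:
    def test_orthogonal_toy_design_exact(self):
        data = pd.DataFrame({"y": [0.0, 2.0, 0.0, 2.0], "x": [0, 1, 0, 1]})
        res = fit_linear(ModelSpec(outcome="y", exposure="x", covariates=()), data)
        assert res.term("x")["beta"] == pytest.approx(2.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        n = 60
        data = pd.DataFrame(
            {
                "age": rng.normal(68, 9, n),
                "male": rng.integers(0, 2, n),
                "quadrant": rng.choice(["Q1", "Q2", "Q3", "Q4"], n),
                "y": rng.normal(size=n),
            }
        )
        res = fit_linear(ModelSpec(outcome="y", exposure="quadrant",
                                   covariates=("age", "male")), data)
        X = np.column_stack(
            [
                np.ones(n),
                (data["quadrant"] == "Q1").astype(float),
                (data["quadrant"] == "Q3").astype(float),
                (data["quadrant"] == "Q4").astype(float),
                data["age"],
                data["male"],
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ data["y"].to_numpy())
        for term, b in zip(("Q1", "Q3", "Q4"), beta[1:4]):
            assert res.term(term)["beta"] == pytest.approx(b, abs=1e-10)

    def test_reference_level_is_zero(self, small_derived):
        res = fit_linear(
            ModelSpec(outcome="global_cognition", exposure="quadrant",
                      covariates=("age", "male", "education")),
            small_derived,
        )
        assert res.term("Q2")["beta"] == 0.0
        assert res.term("Q2")["se"] == 0.0

    def test_wald_interval_width(self, small_derived):
        res = fit_linear(
            ModelSpec(outcome="global_cognition", exposure="oef",
                      covariates=("age", "male")),
            small_derived,
        )
        row = res.term("oef")
        assert row["hi"] - row["lo"] == pytest.approx(2 * 1.96 * row["se"], abs=1e-10)

    def test_collinear_design_names_columns(self, rng):
        n = 30
        data = pd.DataFrame({"y": rng.normal(size=n), "x": rng.normal(size=n)})
        data["x_copy"] = data["x"]
        with pytest.raises(RankDeficiencyError, match="x"):
            fit_linear(ModelSpec(outcome="y", exposure="x",
                                 covariates=("x_copy",)), data)

    def test_invariant_to_covariate_order_and_scale(self, small_derived):
        a = fit_linear(ModelSpec(outcome="global_cognition", exposure="quadrant",
                                 covariates=("age", "male", "education")),
                       small_derived)
        data2 = small_derived.copy()
        data2["age"] = data2["age"] * 12.0 + 5.0  # affine rescale
        b = fit_linear(ModelSpec(outcome="global_cognition", exposure="quadrant",
                                 covariates=("education", "age", "male")),
                       data2)
        for q in ("Q1", "Q3", "Q4"):
            assert a.term(q)["beta"] == pytest.approx(b.term(q)["beta"], abs=1e-10)


class TestQuadrantBattery:
    def test_row_bookkeeping(self, small_derived):
        out = run_quadrant_battery(small_derived)
        # (1 WMH + 7 cognition outcomes) x 3 contrasts x 2 models
        assert len(out) == 8 * 3 * 2
        wmh_n = out.loc[out["outcome"] == "log_wmh", "n"].unique()
        assert list(wmh_n) == [int((small_derived["infarct"] == 0).sum())]

    def test_null_generator_contrasts_unbiased(self):
        """Zero-effect generator: every Q contrast mean is within MC error of 0."""
        cfg_base = dict(
            n_subjects=200,
            surface_coeffs={"cognition": (0.0,) * 6, "log_wmh": (0.0,) * 6},
            covariate_effects={"age": -0.02, "education": 0.1, "male": 0.0},
        )
        betas = {q: [] for q in ("Q1", "Q3", "Q4")}
        for seed in range(300):
            df = derive_variables(generate_cohort(SimulationConfig(seed=seed, **cfg_base)))
            res = fit_linear(
                ModelSpec(outcome="global_cognition", exposure="quadrant",
                          covariates=("age", "male", "education")), df)
            for q in betas:
                betas[q].append(res.term(q)["beta"])
        for q, vals in betas.items():
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals)) < 2.5 * se, q

    def test_recovers_injected_wmh_contrast(self):
        """A known multiplicative Q4-vs-Q2 WMH difference is recovered."""
        effect = -0.55
        est = []
        for seed in range(120):
            df = derive_variables(generate_cohort(SimulationConfig(seed=1000 + seed)))
            df = df[df["infarct"] == 0]
            mask = df["quadrant"] == "Q4"
            df.loc[mask, "log_wmh"] = df.loc[mask, "log_wmh"] + effect
            res = fit_linear(ModelSpec(outcome="log_wmh", exposure="quadrant",
                                       covariates=("age", "male")), df)
            est.append(res.term("Q4")["beta"])
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - effect) < 3 * se + 1e-3


class TestStratified:
    def test_vrs_split_at_two(self, small_derived):
        out = run_stratified(small_derived, "vrs")
        low_n = out.loc[(out["stratum"] == "low") &
                        (out["outcome"] == "global_cognition"), "n"].unique()
        assert list(low_n) == [int((small_derived["vrs"] <= 2).sum())]

    def test_unknown_stratifier(self, small_derived):
        with pytest.raises(ValueError):
            run_stratified(small_derived, "sex")

    def test_single_stratum_warns(self, small_derived):
        data = small_derived.copy()
        data["vrs"] = 0
        with pytest.warns(UserWarning, match="non-empty"):
            out = run_stratified(data, "vrs")
        assert set(out["stratum"]) == {"low"}

    def test_homogeneous_strata_match_pooled(self):
        """When strata are generated identically, stratum slopes agree with the
        pooled slope within Monte-Carlo error."""
        diffs = []
        for seed in range(60):
            df = derive_variables(generate_cohort(SimulationConfig(
                n_subjects=300, seed=seed)))
            pooled = fit_linear(ModelSpec(outcome="global_cognition", exposure="oef",
                                          covariates=("age", "male", "education")),
                                df).term("oef")["beta"]
            strat = run_stratified(df, "vrs")
            rows = strat[(strat["outcome"] == "global_cognition") &
                         (strat["exposure"] == "oef")]
            diffs.append(rows["beta"].mean() - pooled)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 1e-3


class TestMancova:
    def _toy(self, rng, n=80, p=3):
        Y = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"y{i}" for i in range(p)])
        exposures = pd.DataFrame({"oef": rng.normal(size=n)})
        covs = pd.DataFrame({"age": rng.normal(size=n),
                             "male": rng.integers(0, 2, n)})
        return Y, exposures, covs

    def test_single_outcome_reduces_to_univariate_f(self, rng):
        Y, ex, covs = self._toy(rng, p=1)
        res = mancova(Y, ex, covs)
        import statsmodels.api as sm

        X = np.column_stack([np.ones(len(Y)), covs, ex])
        fit = sm.OLS(Y.to_numpy().ravel(), X).fit()
        f_uni = float(fit.tvalues[-1] ** 2)
        assert res.term("oef")["F"] == pytest.approx(f_uni, rel=1e-10)
        assert res.followup.iloc[0]["F"] == pytest.approx(f_uni, rel=1e-10)

    def test_matches_statsmodels_manova(self, rng):
        Y, ex, covs = self._toy(rng)
        res = mancova(Y, ex, covs)
        from statsmodels.multivariate.manova import MANOVA

        data = pd.concat([Y, ex, covs], axis=1)
        mv = MANOVA.from_formula("y0 + y1 + y2 ~ age + male + oef", data=data)
        tab = mv.mv_test().results["oef"]["stat"]
        assert res.term("oef")["pillai"] == pytest.approx(
            float(tab.loc["Pillai's trace", "Value"]), abs=1e-10)
        assert res.term("oef")["F"] == pytest.approx(
            float(tab.loc["Pillai's trace", "F Value"]), rel=1e-8)

    def test_pillai_equals_eigenvalue_sum_oracle(self, rng):
        """tr[H(H+E)^-1] equals sum(lambda/(1+lambda)) over eig(H E^-1)."""
        Y, ex, covs = self._toy(rng)
        res = mancova(Y, ex, covs)
        # rebuild H and E from scratch with hat matrices
        X_full = np.column_stack([np.ones(len(Y)), covs, ex])
        X_red = np.column_stack([np.ones(len(Y)), covs])
        P_full = X_full @ np.linalg.pinv(X_full)
        P_red = X_red @ np.linalg.pinv(X_red)
        Ym = Y.to_numpy()
        H = Ym.T @ (P_full - P_red) @ Ym
        E = Ym.T @ (np.eye(len(Y)) - P_full) @ Ym
        lam = np.linalg.eigvals(H @ np.linalg.inv(E)).real
        assert res.term("oef")["pillai"] == pytest.approx(
            float(np.sum(lam / (1 + lam))), abs=1e-10)

    def test_singular_error_matrix_rejected(self, rng):
        Y, ex, covs = self._toy(rng)
        Y["y1"] = Y["y0"]  # perfectly collinear outcomes
        with pytest.raises(np.linalg.LinAlgError):
            mancova(Y, ex, covs)

    def test_permutation_null_p_values_uniform(self, rng):
        """With the outcome rows permuted, exposure p-values are U(0,1)."""
        from scipy import stats

        Y, ex, covs = self._toy(rng, n=60)
        pvals = []
        for _ in range(400):
            perm = rng.permutation(len(Y))
            pvals.append(mancova(Y.iloc[perm].reset_index(drop=True), ex, covs)
                         .term("oef")["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_check_full_rank_passes_well_conditioned(rng):
    X = rng.normal(size=(30, 4))
    check_full_rank(X)  # no raise
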