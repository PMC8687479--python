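"""Regression stage: design construction, Box-Cox, OLS, LRT, ANOVA, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tepkit.io import CohortTable
from tepkit.regression import (
    MODEL_SPECS,
    SingularDesignError,
    anova_percent_variance,
    boxcox,
    boxcox_transform,
    build_design,
    diagnostics,
    fit_ols,
    likelihood_ratio_test,
    lilliefors,
    run_model_suite,
)

from conftest import make_cohort_df


def scores_for(df, local=1.0, glob=2.0, base=3.0):
    rows = []
    for _, r in df.iterrows():
        for t in r["completed_targets"]:
            rows.append(dict(subject_id=r["subject_id"], target=t,
                             local_auc=local, global_auc=glob,
                             baseline_activity=base))
    return pd.DataFrame(rows)


def random_instance(rng, n=50, k=3):
    X = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])
    X.insert(0, "const", 1.0)
    beta = rng.normal(size=k + 1)
    y = X.values @ beta + rng.normal(size=n)
    return X, y


def ols_oracle(X, y):
    """Normal-equations brute force: beta, t, F, R2adj, llf."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    rss = resid @ resid
    tss = ((y - y.mean()) ** 2).sum()
    sigma2 = rss / (n - k)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = beta / se
    r2 = 1 - rss / tss
    r2_adj = 1 - (1 - r2) * (n - 1) / (n - k)
    F = ((tss - rss) / (k - 1)) / sigma2
    llf = -n / 2 * (np.log(2 * np.pi * rss / n) + 1)
    return beta, t, F, r2_adj, llf, rss


class TestBuildDesign:
    def test_full_model_has_eight_predictors(self, small_cohort):
        X, y, _ = build_design(small_cohort, scores_for(small_cohort.df),
                               MODEL_SPECS["full_dlpfc"])
        assert X.shape[1] == 9  # 8 predictors + intercept
        assert list(X.columns)[0] == "const"

    def test_reduced_model_has_two_predictors(self, small_cohort):
        X, y, _ = build_design(small_cohort, scores_for(small_cohort.df),
                               MODEL_SPECS["reduced_dlpfc"])
        assert list(X.columns) == ["const", "local_auc", "education_years"]

    def test_hand_built_matrix(self):
        df = make_cohort_df(3)
        scores = pd.DataFrame([
            dict(subject_id="sub-001", target="DLPFC", local_auc=10.0,
                 global_auc=20.0, baseline_activity=1.0),
            dict(subject_id="sub-002", target="DLPFC", local_auc=11.0,
                 global_auc=21.0, baseline_activity=1.0),
            dict(subject_id="sub-003", target="DLPFC", local_auc=12.0,
                 global_auc=22.0, baseline_activity=1.0),
        ])
        X, y, n_dropped = build_design(CohortTable(df), scores,
                                       MODEL_SPECS["full_dlpfc"])
        assert n_dropped == 0
        # sub-001: functional (i=0 -> method=1), male, age 50, edu 12
        r = X.loc["sub-001"]
        assert r["local_auc"] == 10.0
        assert r["local_auc_x_method"] == 10.0
        assert r["global_auc_x_method"] == 20.0
        assert r["gender"] == 1.0 and r["age"] == 50.0 and r["education_years"] == 12.0
        # sub-002: anatomical -> interactions zero; female
        r2 = X.loc["sub-002"]
        assert r2["local_auc_x_method"] == 0.0 and r2["gender"] == 0.0
        # response: mean of [2, 1, 2]
        assert y.loc["sub-001"] == pytest.approx(5 / 3)

    def test_missing_target_drops_subject(self):
        df = make_cohort_df(3)
        df.at[2, "completed_targets"] = ["IPL"]
        scores = scores_for(df)
        X, _, n_dropped = build_design(CohortTable(df), scores,
                                       MODEL_SPECS["reduced_dlpfc"])
        assert n_dropped == 1
        assert "sub-003" not in X.index


class TestBoxCox:
    def test_identity_recovered_for_normal_data(self, rng):
        y = rng.normal(10.0, 3.0, 500)
        _, lam, shift = boxcox(y)
        assert abs(lam - 1.0) < 0.3
        assert shift == 0.0

    def test_log_recovered_for_lognormal_data(self, rng):
        y = np.exp(rng.normal(0.0, 0.5, 500))
        _, lam, _ = boxcox(y)
        assert abs(lam) < 0.3

    def test_matches_scipy_optimizer(self, rng):
        y = rng.normal(10.0, 3.0, 200)
        _, lam, _ = boxcox(y)
        assert lam == pytest.approx(stats.boxcox(y)[1], abs=2e-3)

    def test_lambda_one_is_shift_by_one(self):
        y = np.array([1.0, 2.0, 5.0])
        np.testing.assert_allclose(boxcox_transform(y, 1.0), y - 1.0)

    def test_shift_applied_for_nonpositive_response(self):
        y = np.array([0.0, 1.0, 2.0, 4.0, 0.0, 3.0])
        _, _, shift = boxcox(y)
        assert shift == 1.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(lam=st.floats(-3, 3), seed=st.integers(0, 99))
    def test_transform_is_monotone(self, lam, seed):
        r = np.random.default_rng(seed)
        y = np.sort(r.uniform(0.1, 50.0, 20))
        z = boxcox_transform(y, lam)
        assert np.all(np.diff(z) > 0)


class TestOLS:
    def test_exact_linear_data(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"const": 1.0, "x": x})
        fit = fit_ols(X, 3.0 + 2.0 * x)
        assert fit.params["const"] == pytest.approx(3.0)
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.rsquared == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(10):
            X, y = random_instance(rng)
            fit = fit_ols(X, y)
            beta, t, F, r2_adj, llf, _ = ols_oracle(X, y)
            np.testing.assert_allclose(list(fit.params.values()), beta, atol=1e-8)
            np.testing.assert_allclose(list(fit.tvalues.values()), t, atol=1e-8)
            assert fit.fvalue == pytest.approx(F, abs=1e-8)
            assert fit.rsquared_adj == pytest.approx(r2_adj, abs=1e-10)
            assert fit.llf == pytest.approx(llf, abs=1e-8)

    def test_information_criteria_recompute_from_llf(self, rng):
        X, y = random_instance(rng, n=40, k=2)
        fit = fit_ols(X, y)
        k_star = X.shape[1] + 1
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * k_star, abs=1e-12)
        assert fit.bic == pytest.approx(-2 * fit.llf + k_star * np.log(fit.n), abs=1e-12)
        assert fit.df_model + fit.df_resid + 1 == fit.n

    def test_parameter_recovery_is_unbiased(self, rng):
        beta = np.array([1.0, 0.5, -2.0])
        est = []
        for _ in range(200):
            X = pd.DataFrame({"const": np.ones(200),
                              "x1": rng.normal(size=200),
                              "x2": rng.normal(size=200)})
            y = X.values @ beta + rng.normal(size=200)
            est.append(list(fit_ols(X, y).params.values()))
        est = np.array(est)
        se = est.std(axis=0) / np.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0) - beta) < 2 * se + 0.02)

    def test_rank_deficiency_is_explicit(self, rng):
        X = pd.DataFrame({"const": np.ones(20), "x": np.arange(20.0)})
        X["x2"] = 2.0 * X["x"]
        with pytest.raises(SingularDesignError):
            fit_ols(X, rng.normal(size=20))


class TestLilliefors:
    def test_calibrated_rejection_rate_under_null(self, rng):
        n_rej = 0
        reps = 200
        for i in range(reps):
            d, p = lilliefors(rng.normal(size=100), n_sim=1000, seed=i)
            n_rej += p < 0.05
        rate = n_rej / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se + 0.01

    def test_detects_exponential_residuals(self, rng):
        n_sig = sum(
            lilliefors(rng.exponential(size=100), n_sim=2000, seed=i)[1] < 0.01
            for i in range(40)
        )
        assert n_sig >= 38  # >= 95%

    def test_statistic_matches_statsmodels(self, rng):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors
        x = rng.normal(size=80)
        d_sm, _ = sm_lilliefors(x, dist="norm", pvalmethod="table")
        d_ours, _ = lilliefors(x, n_sim=100, seed=0)
        assert d_ours == pytest.approx(d_sm, abs=1e-10)

    def test_statistic_affine_invariant(self, rng):
        x = rng.normal(size=60)
        d1, _ = lilliefors(x, n_sim=100, seed=0)
        d2, _ = lilliefors(5.0 * x - 3.0, n_sim=100, seed=0)
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestLRT:
    def test_identical_models_give_zero(self, rng):
        X, y = random_instance(rng)
        fit = fit_ols(X, y)
        res = likelihood_ratio_test(fit, fit)
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_chi2_equals_rss_ratio_form(self, rng):
        X, y = random_instance(rng, n=60, k=8)
        full = fit_ols(X, y)
        red = fit_ols(X[["const", "x0", "x1"]], y)
        res = likelihood_ratio_test(full, red)
        assert res.df == 6
        rss_f = (full.residuals**2).sum()
        rss_r = (red.residuals**2).sum()
        assert res.chi2 == pytest.approx(full.n * np.log(rss_r / rss_f), abs=1e-8)
        assert res.chi2 == pytest.approx(2 * (full.llf - red.llf), abs=1e-8)

    def test_non_nested_rejected(self, rng):
        X, y = random_instance(rng, k=4)
        full = fit_ols(X[["const", "x0", "x1"]], y)
        other = fit_ols(X[["const", "x2", "x3"]], y)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(full, other)


class TestAnova:
    def test_orthogonal_design_order_invariant(self, rng):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        X = pd.DataFrame({"const": 1.0, "x1": x1, "x2": x2})
        y = 2.0 * x1 - x2 + rng.normal(size=n)
        fit = fit_ols(X, y)
        a = anova_percent_variance(fit, ["x1", "x2"])
        b = anova_percent_variance(fit, ["x2", "x1"])
        assert a["x1"] == pytest.approx(b["x1"], abs=1e-8)
        assert sum(a.values()) == pytest.approx(100.0, abs=1e-8)

    def test_pure_single_predictor_signal(self):
        x1 = np.arange(30.0)
        x2 = np.cos(x1)
        X = pd.DataFrame({"const": 1.0, "x1": x1, "x2": x2})
        fit = fit_ols(X, 2.0 * x1)
        a = anova_percent_variance(fit, ["x1", "x2"])
        assert a["x1"] == pytest.approx(100.0, abs=1e-6)
        assert a["x2"] == pytest.approx(0.0, abs=1e-6)

    def test_matches_nested_rss_decrement_oracle(self, rng):
        X, y = random_instance(rng, n=40, k=3)
        fit = fit_ols(X, y)
        order = ["x2", "x0", "x1"]
        got = anova_percent_variance(fit, order)
        tss = ((y - y.mean()) ** 2).sum()
        prev = tss
        for i, p in enumerate(order):
            cols = ["const"] + order[: i + 1]
            _, _, _, _, _, rss = ols_oracle(X[cols], y)
            assert got[p] == pytest.approx(100 * (prev - rss) / tss, abs=1e-8)
            prev = rss

    def test_wrong_order_rejected(self, rng):
        X, y = random_instance(rng, k=2)
        fit = fit_ols(X, y)
        with pytest.raises(ValueError, match="permutation"):
            anova_percent_variance(fit, ["x0"])


class TestDiagnostics:
    def test_orthonormal_predictors_have_unit_vif(self, rng):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        X = pd.DataFrame({"const": 1.0, "x1": x1, "x2": x2})
        fit = fit_ols(X, rng.normal(size=n))
        d = diagnostics(fit)
        assert d["vif"]["x1"] == pytest.approx(1.0, abs=1e-10)
        assert d["vif"]["x2"] == pytest.approx(1.0, abs=1e-10)

    def test_iid_residuals_have_dw_near_two(self, rng):
        X = pd.DataFrame({"const": np.ones(500), "x": rng.normal(size=500)})
        fit = fit_ols(X, rng.normal(size=500))
        assert abs(diagnostics(fit)["durbin_watson"] - 2.0) < 0.3

    def test_heteroscedasticity_detected(self, rng):
        n_sig = 0
        for _ in range(25):
            x = rng.uniform(0.5, 3.0, 200)
            X = pd.DataFrame({"const": np.ones(200), "x": x})
            y = 1.0 + x + rng.normal(size=200) * x**2
            fit = fit_ols(X, y)
            n_sig += diagnostics(fit)["breusch_pagan_p"] < 0.05
        assert n_sig >= 20  # >= 80%


class TestModelSuite:
    def test_suite_structure_on_synthetic_cohort(self, rng):
        from tepkit.experiments import _score_cohort, fast_config
        from tepkit.simulate import simulate_cohort_table
        cfg = fast_config(n_subjects=40, n_roi_vertices=10, n_sensors=6)
        cohort, profiles = simulate_cohort_table(cfg, rng)
        scores = _score_cohort(cohort, profiles, cfg, rng)
        report = run_model_suite(cohort, scores, lilliefors_seed=0)
        assert set(report["models"]) == set(MODEL_SPECS)
        lrt = report["lrt_full_vs_reduced_dlpfc"]
        assert lrt["df"] == 6 and lrt["chi2"] >= 0.0
        anova = report["anova_reduced_dlpfc"]
        assert sum(anova.values()) == pytest.approx(100.0, abs=1e-8)
        full, red = report["models"]["full_dlpfc"], report["models"]["reduced_dlpfc"]
        assert full["df_model"] == 8 and red["df_model"] == 2
        for entry in report["models"].values():
            assert entry["r2_adj"] <= entry["r2"]
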