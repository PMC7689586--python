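"""Logistic MLE / Firth and OLS engines against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit

from famprs.regression import (
    ModelSpec,
    RankError,
    SeparationError,
    build_design,
    fit_linear,
    fit_logistic_mle,
    fit_model,
    logistic_fit,
)


def _two_by_two(case_exp, case_unexp, ctrl_exp, ctrl_unexp):
    y = np.r_[np.ones(case_exp + case_unexp), np.zeros(ctrl_exp + ctrl_unexp)]
    x = np.r_[np.ones(case_exp), np.zeros(case_unexp),
              np.ones(ctrl_exp), np.zeros(ctrl_unexp)]
    return np.column_stack([np.ones_like(x), x]), y


class TestLogisticMLE:
    def test_saturated_2x2_equals_ad_over_bc(self):
        X, y = _two_by_two(30, 70, 10, 90)
        fit = logistic_fit(X, y)
        assert np.exp(fit.params.iloc[1]) == pytest.approx(30 * 90 / (70 * 10),
                                                           abs=1e-6)

    def test_null_data_gives_unit_or(self, rng):
        n = 20_000
        x = rng.standard_normal(n)
        y = (rng.random(n) < 0.4).astype(float)
        fit = logistic_fit(np.column_stack([np.ones(n), x]), y)
        assert abs(fit.zvalues.iloc[1]) < 3
        assert np.exp(fit.params.iloc[1]) == pytest.approx(1.0, abs=0.05)

    def test_affine_equivariance(self, rng):
        n = 500
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(0.8 * x)).astype(float)
        f1 = logistic_fit(np.column_stack([np.ones(n), x]), y)
        f2 = logistic_fit(np.column_stack([np.ones(n), 2 * x]), y)
        assert f2.params.iloc[1] == pytest.approx(f1.params.iloc[1] / 2, rel=1e-6)
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-8)

    def test_matches_derivative_free_optimizer_small_n(self, rng):
        n = 150
        X = np.column_stack([np.ones(n), rng.standard_normal(n),
                             rng.standard_normal(n)])
        y = (rng.random(n) < expit(X @ [-0.3, 0.7, -0.4])).astype(float)
        fit = logistic_fit(X, y)

        def negll(b):
            p = expit(X @ b)
            return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))

        brute = optimize.minimize(negll, np.zeros(3), method="Nelder-Mead",
                                  options={"xatol": 1e-8, "fatol": 1e-10,
                                           "maxiter": 10_000})
        np.testing.assert_allclose(fit.params.to_numpy(), brute.x, atol=1e-4)

    def test_matches_statsmodels(self, rng):
        n = 400
        X = np.column_stack([np.ones(n), rng.standard_normal(n),
                             rng.random(n) < 0.5])
        y = (rng.random(n) < expit(X @ [-0.2, 0.5, 0.3])).astype(float)
        ours = logistic_fit(X, y)
        sm_fit = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.params, sm_fit.params, atol=1e-6)
        np.testing.assert_allclose(ours.bse, sm_fit.bse, rtol=1e-4)

    def test_loglik_never_decreases(self, rng):
        n = 300
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < expit(2.5 * X[:, 1])).astype(float)
        fit = logistic_fit(X, y)
        diffs = np.diff(fit.loglik_path)
        assert (diffs >= -1e-9).all()

    def test_separation_raises_advice(self):
        x = np.r_[np.linspace(1, 2, 20), np.linspace(-2, -1, 20)]
        y = np.r_[np.ones(20), np.zeros(20)]
        with pytest.raises(SeparationError, match="firth"):
            logistic_fit(np.column_stack([np.ones(40), x]), y)

    def test_rank_deficiency_names_column(self, rng):
        n = 100
        x = rng.standard_normal(n)
        X = pd.DataFrame({"intercept": 1.0, "a": x, "b": 2 * x})
        y = (rng.random(n) < 0.5).astype(float)
        with pytest.raises(RankError, match="a|b"):
            logistic_fit(X, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            logistic_fit(np.ones((10, 1)), np.ones(10))


class TestFirth:
    def test_2x2_zero_cell_equals_haldane_correction(self):
        # cases: 10 exposed / 0 unexposed; controls 5/5
        X, y = _two_by_two(10, 0, 5, 5)
        fit = logistic_fit(X, y, firth=True)
        expected = (10.5 * 5.5) / (0.5 * 5.5)  # +0.5 cell correction
        assert np.exp(fit.params.iloc[1]) == pytest.approx(expected, abs=1e-4)

    def test_2x2_matches_brute_force_penalized_likelihood(self):
        X, y = _two_by_two(10, 0, 5, 5)
        fit = logistic_fit(X, y, firth=True)

        def neg_pen_ll(b):
            p = expit(X @ b)
            w = p * (1 - p)
            info = (X * w[:, None]).T @ X
            ll = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
            return -(ll + 0.5 * np.linalg.slogdet(info)[1])

        brute = optimize.minimize(neg_pen_ll, np.zeros(2), method="Nelder-Mead",
                                  options={"xatol": 1e-9, "fatol": 1e-12,
                                           "maxiter": 20_000})
        np.testing.assert_allclose(fit.params.to_numpy(), brute.x, atol=1e-4)

    def test_finite_under_complete_separation(self):
        x = np.r_[np.linspace(1, 2, 20), np.linspace(-2, -1, 20)]
        y = np.r_[np.ones(20), np.zeros(20)]
        fit = logistic_fit(np.column_stack([np.ones(40), x]), y, firth=True)
        assert np.isfinite(fit.params).all()
        assert np.isfinite(fit.bse).all()

    def test_agrees_with_mle_at_large_n(self, rng):
        n = 10_000
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(-0.5 + 0.6 * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        mle = logistic_fit(X, y)
        firth = logistic_fit(X, y, firth=True)
        np.testing.assert_allclose(firth.params, mle.params, rtol=0.01)

    def test_penalized_loglik_ascends(self):
        X, y = _two_by_two(10, 0, 5, 5)
        fit = logistic_fit(X, y, firth=True)
        assert (np.diff(fit.loglik_path) >= -1e-9).all()


class TestLinear:
    def test_exact_fit(self):
        df = pd.DataFrame({"sgrq_total": 2.0 * np.arange(10.0),
                           "prs_z": np.arange(10.0),
                           "cohort": "x", "prs_raw": np.arange(10.0)})
        spec = ModelSpec(outcome="sgrq_total", predictor_set="prs_only",
                         covariates=(), extra_covariates=(), n_pcs=0)
        fit = fit_linear(df, spec)
        assert fit.params["prs_z"] == pytest.approx(2.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.mse == pytest.approx(0.0, abs=1e-18)

    def test_pure_noise_adjusted_r2_near_zero(self, rng):
        n = 10_000
        df = pd.DataFrame({"sgrq_total": rng.standard_normal(n),
                           "prs_z": rng.standard_normal(n)})
        spec = ModelSpec(outcome="sgrq_total", predictor_set="prs_only",
                         covariates=(), extra_covariates=(), n_pcs=0)
        fit = fit_linear(df, spec)
        assert abs(fit.r_squared_adj) < 0.01

    def test_four_point_normal_equations(self):
        # y on x for points (0,1),(1,3),(2,4),(3,8): hand-solved slope/intercept
        x = np.array([0.0, 1, 2, 3])
        y = np.array([1.0, 3, 4, 8])
        # normal equations: slope = Sxy/Sxx = 11/5, intercept = ybar - b*xbar
        df = pd.DataFrame({"sgrq_total": y, "prs_z": x})
        spec = ModelSpec(outcome="sgrq_total", predictor_set="prs_only",
                         covariates=(), extra_covariates=(), n_pcs=0)
        fit = fit_linear(df, spec)
        assert fit.params["prs_z"] == pytest.approx(11 / 5, abs=1e-12)
        assert fit.params["intercept"] == pytest.approx(4 - (11 / 5) * 1.5,
                                                        abs=1e-12)


class TestModelSpecs:
    def test_model1_excludes_prs_and_pcs(self, cohort_small):
        spec = ModelSpec(outcome="copd_case", predictor_set="fh_only")
        _, X = build_design(cohort_small, spec)
        assert "prs_z" not in X.columns
        assert not any(c.startswith("pc") for c in X.columns)

    def test_models_2_3_include_pcs(self, cohort_small):
        for pset in ("prs_only", "fh_plus_prs"):
            spec = ModelSpec(outcome="copd_case", predictor_set=pset)
            _, X = build_design(cohort_small, spec)
            assert "prs_z" in X.columns
            assert sum(c.startswith("pc") for c in X.columns) == 5

    def test_outcome_specific_covariates(self, cohort_small):
        spec = ModelSpec(outcome="frequent_exacerbations",
                         predictor_set="fh_plus_prs")
        _, X = build_design(cohort_small, spec)
        assert {"fev1_pp", "current_smoker"} <= set(X.columns)
        spec = ModelSpec(outcome="pi10", predictor_set="fh_plus_prs")
        _, X = build_design(cohort_small, spec)
        assert any(c.startswith("ct_scanner") for c in X.columns)

    def test_row_permutation_invariance(self, cohort_small):
        spec = ModelSpec(outcome="copd_case", predictor_set="fh_plus_prs")
        a = fit_model(cohort_small, spec)
        shuffled = cohort_small.sample(frac=1, random_state=1)
        b = fit_model(shuffled, spec)
        np.testing.assert_allclose(a.params, b.params, atol=1e-8)

    def test_nested_constraint_reproduces_model1(self, cohort_small):
        """Model 3 with PRS and PC columns constrained out equals model 1."""
        m1 = fit_logistic_mle(cohort_small, ModelSpec(
            outcome="copd_case", predictor_set="fh_only"))
        drop = ["prs_z"] + [f"pc{j}" for j in range(1, 6)]
        m3c = fit_logistic_mle(cohort_small, ModelSpec(
            outcome="copd_case", predictor_set="fh_plus_prs"), drop=drop)
        np.testing.assert_allclose(
            m3c.params[m1.params.index], m1.params, atol=1e-8)

    def test_missing_column_reported(self, cohort_small):
        spec = ModelSpec(outcome="nonexistent", predictor_set="fh_only",
                         family="binary")
        with pytest.raises(KeyError, match="nonexistent"):
            build_design(cohort_small, spec)

    def test_wald_ci_exponentiates_to_or_ci(self, cohort_small):
        fit = fit_model(cohort_small, ModelSpec(outcome="copd_case",
                                                predictor_set="fh_plus_prs"))
        tidy = fit.to_frame().set_index("term")
        np.testing.assert_allclose(tidy["or"], np.exp(tidy["estimate"]))
        np.testing.assert_allclose(tidy["or_ci_low"], np.exp(tidy["ci_low"]))
        assert (tidy["ci_low"] <= tidy["ci_high"]).all()
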