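"""Fitting routes against closed forms and independent likelihood oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import optimize, special

from countcompare.datasets import CountDataset, GeneratorConfig, generate
from countcompare.fitting import (
    build_design,
    choose_family,
    dispersion_statistic,
    fit_glm_irls,
    fit_intercept_only,
    fit_ols,
)
from countcompare.transforms import TransformSpec

SQRT = TransformSpec("sqrt")
LOG1P = TransformSpec("log")


def poisson_negloglik(beta, X, y):
    mu = np.exp(X @ beta)
    return -np.sum(y * np.log(mu) - mu - special.gammaln(y + 1))


def negbin_negloglik(beta, X, y, theta):
    mu = np.exp(X @ beta)
    return -np.sum(
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def direct_ml(X, y, negloglik, *args):
    """Independent maximum-likelihood oracle via simplex minimisation."""
    start = np.zeros(X.shape[1])
    start[0] = np.log(y.mean() + 0.5)
    res = optimize.minimize(
        negloglik, start, args=(X, y) + args, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20_000},
    )
    assert res.success
    return res.x


class TestOLS:
    def test_oneway_closed_form_group_means(self):
        ds = CountDataset(y=[1, 3, 5, 5], x=list("aabb"), kind="oneway")
        fit = fit_ols(ds, SQRT)
        mean_a = (1 + np.sqrt(3)) / 2
        assert fit.coef("intercept") == pytest.approx(mean_a, abs=1e-12)
        assert fit.coef("x[b]") == pytest.approx(np.sqrt(5) - mean_a, abs=1e-12)
        # identical values in group b contribute nothing to the RSS
        rss_a = (1 - mean_a) ** 2 + (np.sqrt(3) - mean_a) ** 2
        assert fit.scale_info["rss"] == pytest.approx(rss_a, abs=1e-12)

    def test_two_point_exact_line(self):
        ds = CountDataset(y=[1, 9], x=[0.0, 1.0], kind="regression")
        fit = fit_ols(ds, SQRT)  # sqrt maps counts to (0,1) -> 1 and (1,9) -> 3
        assert fit.coef("intercept") == pytest.approx(1.0, abs=1e-12)
        assert fit.coef("x") == pytest.approx(2.0, abs=1e-12)
        assert fit.scale_info["rss"] == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_oracle(self, rng):
        y = rng.poisson(6.0, 12)
        x = rng.uniform(0, 4, 12)
        ds = CountDataset(y=y, x=x, kind="regression")
        for spec in (SQRT, LOG1P):
            fit = fit_ols(ds, spec)
            z = np.sqrt(y) if spec.name == "sqrt" else np.log(y + 1.0)
            X = np.column_stack([np.ones(12), x])
            beta_oracle = np.linalg.inv(X.T @ X) @ X.T @ z
            assert np.allclose(fit.coefficients, beta_oracle, atol=1e-8)

    def test_f_test_matches_statsmodels(self, oneway_dataset):
        fit = fit_ols(oneway_dataset, SQRT)
        X = build_design(oneway_dataset).X
        z = np.sqrt(oneway_dataset.y)
        sm_fit = sm.OLS(z, X).fit()
        assert fit.p_value == pytest.approx(sm_fit.f_pvalue, abs=1e-10)

    def test_identical_response_gives_p_value_one(self):
        ds = CountDataset(y=[4] * 10, x=list("aaaaabbbbb"), kind="oneway")
        assert fit_ols(ds, SQRT).p_value == 1.0


class TestGLM:
    def test_intercept_only_is_log_sample_mean(self):
        assert fit_intercept_only([2, 4, 6]) == pytest.approx(np.log(4.0), abs=1e-10)

    def test_oneway_reproduces_group_means(self):
        ds = CountDataset(y=[3, 3, 3, 7, 7, 7], x=list("aaabbb"), kind="oneway")
        fit = fit_glm_irls(ds, "poisson")
        assert fit.coef("intercept") == pytest.approx(np.log(3.0), abs=1e-8)
        assert fit.coef("x[b]") == pytest.approx(np.log(7.0 / 3.0), abs=1e-8)

    def test_oneway_fitted_equal_sample_means(self, oneway_dataset):
        fit = fit_glm_irls(oneway_dataset, "poisson")
        for level in oneway_dataset.levels:
            mask = oneway_dataset.x == level
            assert np.allclose(fit.fitted[mask], oneway_dataset.group_mean(level), atol=1e-8)

    def test_poisson_matches_direct_ml_oracle(self, rng):
        x = np.linspace(0, 3, 10)
        y = rng.poisson(np.exp(0.8 + 0.4 * x))
        ds = CountDataset(y=y, x=x, kind="regression")
        fit = fit_glm_irls(ds, "poisson")
        X = build_design(ds).X
        beta_oracle = direct_ml(X, y.astype(float), poisson_negloglik)
        assert np.allclose(fit.coefficients, beta_oracle, atol=1e-6)

    def test_negbin_fixed_theta_matches_direct_ml_oracle(self, rng):
        x = np.linspace(0, 3, 12)
        mu = np.exp(1.0 + 0.3 * x)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        ds = CountDataset(y=y, x=x, kind="regression")
        fit = fit_glm_irls(ds, "negbin", theta=2.0)
        X = build_design(ds).X
        beta_oracle = direct_ml(X, y.astype(float), negbin_negloglik, 2.0)
        assert np.allclose(fit.coefficients, beta_oracle, atol=1e-6)

    def test_matches_statsmodels_glm(self, regression_dataset):
        fit = fit_glm_irls(regression_dataset, "poisson")
        X = build_design(regression_dataset).X
        sm_fit = sm.GLM(
            regression_dataset.y, X, family=sm.families.Poisson()
        ).fit()
        assert np.allclose(fit.coefficients, sm_fit.params, atol=1e-7)
        assert np.allclose(fit.standard_errors, sm_fit.bse, atol=1e-6)

    def test_negbin_huge_theta_equals_poisson(self, regression_dataset):
        pois = fit_glm_irls(regression_dataset, "poisson")
        nb = fit_glm_irls(regression_dataset, "negbin", theta=1e8)
        assert np.allclose(pois.coefficients, nb.coefficients, atol=1e-6)

    def test_theta_estimate_recovers_truth(self):
        ds = generate(
            GeneratorConfig(
                "oneway", n=2000, group_means=(5.0, 10.0), family="negbin", theta=2.0, seed=9
            )
        )
        fit = fit_glm_irls(ds, "negbin")
        assert 1.5 < fit.theta < 2.7

    def test_all_zero_response_rejected(self):
        ds = CountDataset(y=[0, 0, 0, 0], x=list("aabb"), kind="oneway")
        with pytest.raises(ValueError, match="all-zero"):
            fit_glm_irls(ds, "poisson")

    def test_p_value_invariant_to_level_relabeling(self, oneway_dataset):
        relabeled = CountDataset(
            y=oneway_dataset.y,
            x=np.where(oneway_dataset.x == "a", "zebra", "ant"),
            kind="oneway",
        )
        for fitter in (lambda d: fit_ols(d, SQRT), lambda d: fit_glm_irls(d, "poisson")):
            assert fitter(oneway_dataset).p_value == pytest.approx(
                fitter(relabeled).p_value, abs=1e-10
            )


class TestDispersion:
    def test_zero_residuals_give_zero(self):
        ds = CountDataset(y=[3, 3, 7, 7], x=list("aabb"), kind="oneway")
        fit = fit_glm_irls(ds, "poisson")
        assert dispersion_statistic(fit, ds) == pytest.approx(0.0, abs=1e-12)

    def test_equidispersed_near_one(self):
        ds = generate(GeneratorConfig("oneway", n=5000, group_means=(5.0, 5.0), seed=2))
        fit = fit_glm_irls(ds, "poisson")
        assert 0.9 < dispersion_statistic(fit, ds) < 1.1

    def test_overdispersed_flagged(self):
        ds = generate(
            GeneratorConfig(
                "oneway", n=5000, group_means=(5.0, 5.0), family="negbin", theta=1.0, seed=2
            )
        )
        fit = fit_glm_irls(ds, "poisson")
        assert dispersion_statistic(fit, ds) > 2.0

    def test_choose_family(self):
        equi = generate(GeneratorConfig("oneway", n=500, group_means=(5.0, 8.0), seed=3))
        over = generate(
            GeneratorConfig(
                "oneway", n=500, group_means=(5.0, 8.0), family="negbin", theta=0.5, seed=3
            )
        )
        assert choose_family(equi) == "poisson"
        assert choose_family(over) == "negbin"
        assert choose_family(over, threshold=np.inf) == "poisson"
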