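import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from propdiff.estimators import (
    beta_const_loglik,
    beta_vardisp_loglik,
    effect_from_fit,
    fit_beta_const,
    fit_beta_vardisp,
    fit_fraclogit,
    fit_linear,
    FitResult,
)
from propdiff.generators import (
    BetaParams,
    BetaScenario,
    TwoSampleData,
    draw_beta_two_sample,
)

from conftest import numerical_gradient


def _independent_beta_ll(theta_mu_phi, data):
    """Oracle log-likelihood built directly from scipy's beta logpdf."""
    mu, phi = theta_mu_phi
    return float(np.sum(stats.beta.logpdf(data, mu * phi, (1 - mu) * phi)))


class TestLinear:
    def test_closed_form_example(self, small_data):
        fit = fit_linear(small_data)
        assert fit.coef[0] == pytest.approx(0.3)
        assert fit.coef[1] == pytest.approx(0.3)

    def test_matches_lstsq(self, beta_data_n50):
        fit = fit_linear(beta_data_n50)
        X = np.column_stack([np.ones(beta_data_n50.y.size), beta_data_n50.x])
        beta, *_ = np.linalg.lstsq(X, beta_data_n50.y, rcond=None)
        np.testing.assert_allclose(fit.coef[:2], beta, atol=1e-12)

    def test_cov_matches_statsmodels(self, beta_data_n50):
        sm = pytest.importorskip("statsmodels.api")
        fit = fit_linear(beta_data_n50)
        X = np.column_stack([np.ones(beta_data_n50.y.size), beta_data_n50.x])
        res = sm.OLS(beta_data_n50.y, X).fit()
        np.testing.assert_allclose(fit.coef[:2], res.params, atol=1e-12)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.cov)[:2]), res.bse, rtol=1e-10)

    def test_permutation_invariance(self, beta_data_n50):
        fit = fit_linear(beta_data_n50)
        rng = np.random.default_rng(1)
        order = rng.permutation(beta_data_n50.y.size)
        shuffled = TwoSampleData(y=beta_data_n50.y[order], x=beta_data_n50.x[order])
        fit2 = fit_linear(shuffled)
        np.testing.assert_allclose(fit.coef, fit2.coef, atol=1e-14)

    def test_empty_group_raises(self):
        data = TwoSampleData(y=np.array([0.2, 0.4]), x=np.array([0, 0]))
        with pytest.raises(ValueError):
            fit_linear(data)

    def test_degenerate_zero_variance(self):
        data = TwoSampleData(y=np.array([0.3, 0.3, 0.6, 0.6]), x=np.array([0, 0, 1, 1]))
        fit = fit_linear(data)
        assert fit.degenerate
        assert fit.cov[1, 1] == 0.0


class TestBetaConst:
    def test_grid_search_oracle(self):
        # tiny dataset; brute-force grid over (b0, b1, log phi) using the
        # scipy-based oracle likelihood
        data = TwoSampleData(
            y=np.array([0.31, 0.52, 0.44, 0.18, 0.59, 0.66, 0.47, 0.73]),
            x=np.array([0, 0, 0, 0, 1, 1, 1, 1]),
        )
        fit = fit_beta_const(data)
        assert fit.converged

        def oracle_ll(b0, b1, log_phi):
            phi = math.exp(log_phi)
            mu0, mu1 = expit(b0), expit(b0 + b1)
            return _independent_beta_ll((mu0, phi), data.group(0)) + _independent_beta_ll(
                (mu1, phi), data.group(1)
            )

        best = -np.inf
        for b0 in np.linspace(-1.5, 1.5, 41):
            for b1 in np.linspace(-1.5, 1.5, 41):
                for lp in np.linspace(0, 4, 41):
                    best = max(best, oracle_ll(b0, b1, lp))
        assert fit.objective >= best - 1e-9
        assert fit.objective == pytest.approx(best, abs=0.05)

    def test_score_zero_at_optimum(self, beta_data_n50):
        fit = fit_beta_const(beta_data_n50)
        assert fit.converged

        def oracle(theta):
            b0, b1, phi = theta
            return _independent_beta_ll((expit(b0), phi), beta_data_n50.group(0)) + (
                _independent_beta_ll((expit(b0 + b1), phi), beta_data_n50.group(1))
            )

        score = numerical_gradient(oracle, fit.coef)
        assert np.max(np.abs(score)) < 1e-6

    def test_loglik_function_agrees_with_oracle(self, beta_data_n50):
        theta = np.array([0.2, -0.4, 6.0])
        ours = beta_const_loglik(theta, beta_data_n50)
        oracle = _independent_beta_ll((expit(0.2), 6.0), beta_data_n50.group(0)) + (
            _independent_beta_ll((expit(-0.2), 6.0), beta_data_n50.group(1))
        )
        assert ours == pytest.approx(oracle, rel=1e-12)

    def test_large_sample_consistency_null(self):
        scenario = BetaScenario(BetaParams(0.4, 6.0), BetaParams(0.4, 6.0), 5000, 5000)
        data = draw_beta_two_sample(scenario, 31)
        fit = fit_beta_const(data)
        assert fit.converged
        assert abs(fit.coef[1]) < 0.05
        assert fit.coef[2] == pytest.approx(6.0, rel=0.1)

    def test_matches_statsmodels_betamodel(self):
        betareg = pytest.importorskip("statsmodels.othermod.betareg")
        scenario = BetaScenario(BetaParams(0.3, 5.0), BetaParams(0.45, 5.0), 150, 150)
        data = draw_beta_two_sample(scenario, 77)
        fit = fit_beta_const(data)
        X = np.column_stack([np.ones(data.y.size), data.x])
        res = betareg.BetaModel(data.y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coef[:2], res.params[:2], atol=1e-4)
        # statsmodels carries log-precision
        assert math.log(fit.coef[2]) == pytest.approx(res.params[2], abs=1e-4)


class TestBetaVardisp:
    def test_intercept_only_reproduces_const_fit(self, beta_data_n50):
        const = fit_beta_const(beta_data_n50)
        restricted = fit_beta_vardisp(beta_data_n50, dispersion_covariate=False)
        assert restricted.converged
        np.testing.assert_allclose(restricted.coef[:2], const.coef[:2], atol=1e-6)
        assert math.exp(restricted.coef[2]) == pytest.approx(const.coef[2], rel=1e-6)
        assert restricted.objective == pytest.approx(const.objective, abs=1e-8)

    def test_group_dispersion_recovery(self):
        scenario = BetaScenario(BetaParams(0.4, 5.0), BetaParams(0.4, 10.0), 4000, 4000)
        data = draw_beta_two_sample(scenario, 55)
        fit = fit_beta_vardisp(data)
        assert fit.converged
        assert math.exp(fit.coef[2]) == pytest.approx(5.0, rel=0.1)
        assert math.exp(fit.coef[2] + fit.coef[3]) == pytest.approx(10.0, rel=0.1)

    def test_score_zero_at_optimum(self, beta_data_n50):
        fit = fit_beta_vardisp(beta_data_n50)
        assert fit.converged

        def oracle(theta):
            b0, b1, g0, g1 = theta
            return _independent_beta_ll(
                (expit(b0), math.exp(g0)), beta_data_n50.group(0)
            ) + _independent_beta_ll(
                (expit(b0 + b1), math.exp(g0 + g1)), beta_data_n50.group(1)
            )

        score = numerical_gradient(oracle, fit.coef)
        assert np.max(np.abs(score)) < 1e-6

    def test_loglik_function_agrees_with_oracle(self, beta_data_n50):
        theta = np.array([0.1, -0.3, 1.5, 0.4])
        ours = beta_vardisp_loglik(theta, beta_data_n50)
        oracle = _independent_beta_ll(
            (expit(0.1), math.exp(1.5)), beta_data_n50.group(0)
        ) + _independent_beta_ll(
            (expit(-0.2), math.exp(1.9)), beta_data_n50.group(1)
        )
        assert ours == pytest.approx(oracle, rel=1e-12)


class TestFracLogit:
    def test_mean_matching(self, beta_data_n50):
        fit = fit_fraclogit(beta_data_n50)
        mu0 = expit(fit.coef[0])
        mu1 = expit(fit.coef[0] + fit.coef[1])
        assert mu0 == pytest.approx(beta_data_n50.group(0).mean(), abs=1e-10)
        assert mu1 == pytest.approx(beta_data_n50.group(1).mean(), abs=1e-10)

    def test_delta_equals_linear_delta(self, beta_data_n50):
        lin = effect_from_fit(fit_linear(beta_data_n50))
        frac = effect_from_fit(fit_fraclogit(beta_data_n50))
        assert frac.delta_hat == pytest.approx(lin.delta_hat, abs=1e-12)

    def test_sandwich_matches_brute_force(self, six_obs_data):
        fit = fit_fraclogit(six_obs_data)
        y, x = six_obs_data.y, six_obs_data.x
        mu = expit(fit.coef[0] + fit.coef[1] * x)
        a_mat = np.zeros((2, 2))
        m_mat = np.zeros((2, 2))
        for i in range(y.size):
            xi = np.array([1.0, float(x[i])])
            a_mat += mu[i] * (1 - mu[i]) * np.outer(xi, xi)
            score_i = (y[i] - mu[i]) * xi
            m_mat += np.outer(score_i, score_i)
        oracle = np.linalg.inv(a_mat) @ m_mat @ np.linalg.inv(a_mat)
        np.testing.assert_allclose(fit.cov, oracle, rtol=1e-10)

    def test_quasi_score_zero(self, six_obs_data):
        fit = fit_fraclogit(six_obs_data)

        def quasi_ll(theta):
            mu = expit(theta[0] + theta[1] * six_obs_data.x)
            return float(
                np.sum(six_obs_data.y * np.log(mu) + (1 - six_obs_data.y) * np.log1p(-mu))
            )

        score = numerical_gradient(quasi_ll, fit.coef)
        assert np.max(np.abs(score)) < 1e-6


class TestEffect:
    def _logit_fit(self, coef, cov):
        coef = np.asarray(coef, dtype=float)
        return FitResult(
            model_tag="fraclogit" if coef.size == 2 else "beta_const",
            coef=coef,
            cov=np.asarray(cov, dtype=float),
            objective=0.0,
            converged=True,
        )

    def test_null_identity(self):
        eff = effect_from_fit(self._logit_fit([0.0, 0.0], np.eye(2)))
        assert eff.delta_hat == 0.0
        assert not eff.reject

    def test_log3_delta(self):
        eff = effect_from_fit(self._logit_fit([0.0, math.log(3)], np.eye(2)))
        assert eff.delta_hat == pytest.approx(0.25)

    def test_delta_method_identity_cov(self):
        eff = effect_from_fit(self._logit_fit([0.0, math.log(3)], np.eye(2)))
        assert eff.se**2 == pytest.approx(0.0390625)

    def test_delta_method_matches_fd_gradient(self, beta_data_n50):
        fit = fit_beta_vardisp(beta_data_n50)
        eff = effect_from_fit(fit)

        def delta_fn(theta):
            return expit(theta[0] + theta[1]) - expit(theta[0])

        grad = numerical_gradient(delta_fn, fit.coef)
        oracle_var = float(grad @ fit.cov @ grad)
        assert eff.se**2 == pytest.approx(oracle_var, rel=1e-6)

    def test_linear_effect_is_slope(self, beta_data_n50):
        fit = fit_linear(beta_data_n50)
        eff = effect_from_fit(fit)
        assert eff.delta_hat == fit.coef[1]
        assert eff.se == pytest.approx(math.sqrt(fit.cov[1, 1]))

    def test_reject_rule(self):
        eff = effect_from_fit(self._logit_fit([0.0, 1.0], 1e-8 * np.eye(2)))
        assert eff.reject and abs(eff.wald) > 1.96

    def test_non_converged_raises(self):
        bad = FitResult(
            model_tag="beta_const",
            coef=np.zeros(3),
            cov=np.eye(3),
            objective=0.0,
            converged=False,
        )
        with pytest.raises(ValueError):
            effect_from_fit(bad)


@pytest.mark.parametrize("fitter", [fit_linear, fit_beta_const, fit_beta_vardisp, fit_fraclogit])
def test_group_relabel_equivariance(fitter, beta_data_n50):
    """x -> 1-x negates delta and wald, leaves |wald| and reject unchanged."""
    eff = effect_from_fit(fitter(beta_data_n50))
    flipped = TwoSampleData(y=beta_data_n50.y, x=1 - beta_data_n50.x)
    eff_f = effect_from_fit(fitter(flipped))
    assert eff_f.delta_hat == pytest.approx(-eff.delta_hat, abs=1e-8)
    assert eff_f.wald == pytest.approx(-eff.wald, rel=1e-5, abs=1e-8)
    assert eff_f.reject == eff.reject
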