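"""EM machinery: NB pmf, initialization, M-step, E-step, likelihood, full fits."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from zinba.covariates import WindowTable, assemble_design
from zinba.simulate import benchmark_scenarios, model_design, simulate_dataset
from zinba.zinb_mixture import (
    MixtureParams,
    PosteriorMatrix,
    e_step,
    fit_mixture,
    init_partitions,
    m_step,
    marginal_log_likelihood,
    nb_log_pmf,
)


class TestNBLogPmf:
    def test_closed_form_at_zero(self):
        assert np.isclose(nb_log_pmf(0, 2.0, 1.0), np.log(1 / 3))

    def test_poisson_limit(self):
        y = np.arange(21)
        nb = nb_log_pmf(y, 3.0, 1e8)
        pois = stats.poisson.logpmf(y, 3.0)
        assert np.max(np.abs(nb - pois)) < 1e-5

    def test_normalization(self):
        y = np.arange(10_001)
        total = np.exp(nb_log_pmf(y, 5.0, 2.0)).sum()
        assert abs(total - 1.0) < 1e-8

    def test_matches_scipy_nbinom(self):
        y = np.arange(50)
        mu, theta = 7.3, 1.7
        ours = nb_log_pmf(y, mu, theta)
        ref = stats.nbinom.logpmf(y, theta, theta / (theta + mu))
        assert np.allclose(ours, ref, atol=1e-10)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_log_pmf(np.array([-1]), 2.0, 1.0)
        with pytest.raises(ValueError):
            nb_log_pmf(np.array([1.5]), 2.0, 1.0)


class TestInitPartitions:
    def test_rank_rule_assigns_largest_to_enrichment(self):
        y = np.array([0, 1, 2, 3, 100])
        (tau,) = init_partitions(y, fractions=[0.15])
        assert tau.tau2[4] == 1.0  # ceil(0.75) = 1 top window
        assert np.all(tau.tau1[[1, 2, 3]] == 1.0)
        assert tau.tau0[0] == 1.0

    def test_ties_broken_by_genome_order(self):
        y = np.full(10, 5)
        (tau,) = init_partitions(y, fractions=[0.3])
        assert list(np.flatnonzero(tau.tau2 == 1.0)) == [0, 1, 2]

    def test_five_fractions_give_five_partitions(self):
        y = np.arange(100)
        parts = init_partitions(y)
        assert len(parts) == 5
        sizes = [int(p.tau2.sum()) for p in parts]
        assert sizes == sorted(sizes)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            init_partitions(np.zeros(10, dtype=int))


def _hard_tau(y, enriched_mask):
    tau0 = (y == 0).astype(float)
    tau2 = enriched_mask.astype(float)
    tau1 = 1.0 - tau0 - tau2
    return PosteriorMatrix(tau0, tau1, tau2)


class TestMStep:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([rng.poisson(3, 500) + 1, rng.poisson(50, 50)])
        enriched = np.arange(len(y)) >= 500
        tau = _hard_tau(y, enriched)
        X = np.ones((len(y), 1))
        params = m_step(y, X, X, X, tau)
        assert np.isclose(params.beta1[0], np.log(y[~enriched & (y > 0)].mean()), atol=1e-6)
        assert np.isclose(params.beta2[0], np.log(y[enriched].mean()), atol=1e-6)

    def test_degenerate_enrichment_weights_floor_pi(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(3, 500) + 1
        tau = PosteriorMatrix(np.zeros(500), np.ones(500), np.zeros(500))
        prev = MixtureParams(
            np.zeros(1), np.array([1.0]), np.array([3.0]), 1.0, 1.0, 0.99, 0.01
        )
        X = np.ones((500, 1))
        params = m_step(y, X, X, X, tau, prev=prev)
        assert params.pi2 == pytest.approx(1e-6)
        assert np.allclose(params.beta2, prev.beta2)  # skipped update

    def test_single_covariate_recovery_vs_direct_likelihood(self):
        """Weighted NB IRLS matches direct NLL minimization and recovers truth."""
        rng = np.random.default_rng(2)
        n = 5000
        x = rng.normal(size=n)
        beta_true = np.array([1.0, 0.5])
        mu = np.exp(beta_true[0] + beta_true[1] * x)
        theta_true = 2.0
        y = rng.negative_binomial(theta_true, theta_true / (theta_true + mu))
        y = np.maximum(y, 0)
        X = np.column_stack([np.ones(n), x])
        tau = PosteriorMatrix(np.zeros(n), np.ones(n), np.zeros(n))
        # background weights all one; enrichment gets a token subset
        tau2 = np.zeros(n)
        tau2[:20] = 1.0
        tau = PosteriorMatrix(np.zeros(n), 1 - tau2, tau2)
        params = m_step(y, X, X, X, tau)
        assert np.allclose(params.beta1, beta_true, atol=0.05)
        assert abs(params.theta1 - theta_true) < 0.3

        # independent oracle: direct joint NLL minimization over (beta, log theta)
        w = tau.tau1

        def nll(p):
            b, lt = p[:2], p[2]
            th = np.exp(lt)
            m = np.exp(X @ b)
            return -(w * (stats.nbinom.logpmf(y, th, th / (th + m)))).sum()

        res = minimize(nll, np.array([0.5, 0.0, 0.0]), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 5000})
        assert np.allclose(params.beta1, res.x[:2], atol=1e-3)


class TestEStep:
    @staticmethod
    def _intercept_params(gamma0, mu1, mu2, th1, th2, pi1, pi2):
        return MixtureParams(
            np.array([gamma0]),
            np.array([np.log(mu1)]),
            np.array([np.log(mu2)]),
            th1,
            th2,
            pi1,
            pi2,
        )

    def test_zero_indicator_annihilates_tau0_for_positive_counts(self):
        y = np.array([0, 5, 1, 0])
        X = np.ones((4, 1))
        params = self._intercept_params(0.0, 3.0, 30.0, 1.0, 1.0, 0.9, 0.1)
        tau = e_step(y, X, X, X, params)
        assert tau.tau0[1] == 0.0 and tau.tau0[2] == 0.0
        assert tau.tau0[0] > 0

    def test_hand_computed_bayes_rule(self):
        # pi_i0 = 0.5, pi1 = pi2 = 0.5, f1(0) = 0.25 (mu=3, th=1),
        # f2(0) = 0.01 (mu=99, th=1)
        y = np.array([0])
        X = np.ones((1, 1))
        params = self._intercept_params(0.0, 3.0, 99.0, 1.0, 1.0, 0.5, 0.5)
        tau = e_step(y, X, X, X, params)
        expected = np.array([0.5, 0.0625, 0.0025]) / 0.565
        assert np.allclose(
            [tau.tau0[0], tau.tau1[0], tau.tau2[0]], expected, atol=1e-10
        )
        assert np.allclose(expected, [0.8850, 0.1106, 0.0044], atol=5e-4)

    def test_equal_densities_give_mixture_proportion_ratio(self):
        y = np.array([4])
        X = np.ones((1, 1))
        params = self._intercept_params(-30.0, 6.0, 6.0, 2.0, 2.0, 0.7, 0.3)
        tau = e_step(y, X, X, X, params)
        assert np.isclose(tau.tau1[0] / tau.tau2[0], 0.7 / 0.3, rtol=1e-9)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(3, 200)
        X = np.ones((200, 1))
        params = self._intercept_params(0.0, 3.0, 30.0, 1.0, 2.0, 0.9, 0.1)
        tau = e_step(y, X, X, X, params)
        assert np.allclose(tau.tau0 + tau.tau1 + tau.tau2, 1.0, atol=1e-10)


class TestMarginalLogLikelihood:
    def test_pure_zero_inflation_single_window(self):
        y = np.array([0])
        X = np.ones((1, 1))
        params = MixtureParams(
            np.array([30.0]), np.array([1.0]), np.array([3.0]), 1.0, 1.0, 0.5, 0.5
        )
        assert abs(marginal_log_likelihood(y, X, X, X, params)) < 1e-6

    def test_matches_direct_density_summation(self):
        rng = np.random.default_rng(4)
        y = rng.poisson(4, 20)
        X = np.ones((20, 1))
        params = MixtureParams(
            np.array([-1.0]), np.array([1.2]), np.array([3.1]), 1.5, 2.5, 0.95, 0.05
        )
        ll = marginal_log_likelihood(y, X, X, X, params)
        # independent evaluation through scipy distributions
        pi0 = 1 / (1 + np.exp(1.0))
        f1 = stats.nbinom.pmf(y, 1.5, 1.5 / (1.5 + np.exp(1.2)))
        f2 = stats.nbinom.pmf(y, 2.5, 2.5 / (2.5 + np.exp(3.1)))
        direct = np.log(pi0 * (y == 0) + (1 - pi0) * (0.95 * f1 + 0.05 * f2)).sum()
        assert abs(ll - direct) < 1e-10

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(4, 50)
        X = np.ones((50, 1))
        params = MixtureParams(
            np.array([-1.0]), np.array([1.2]), np.array([3.1]), 1.5, 2.5, 0.9, 0.1
        )
        perm = rng.permutation(50)
        assert np.isclose(
            marginal_log_likelihood(y, X, X, X, params),
            marginal_log_likelihood(y[perm], X, X, X, params),
            atol=1e-12,
        )


class TestFitMixture:
    def test_recovers_generating_coefficients(self):
        cfg = benchmark_scenarios(seed=5, n_windows=20_000)[("tfbs", "neg")]
        sim = simulate_dataset(cfg)
        fit = fit_mixture(model_design(sim, 3))
        # generating values: background intercept 1.1, GC slope +0.5 per sd
        assert abs(fit.params.beta1[0] - 1.1) < 0.1
        assert abs(fit.params.beta1[1] - 0.5) < 0.1
        assert fit.params.beta2[1] < 0  # enrichment falls with G/C

    def test_loglik_trace_monotone(self):
        cfg = benchmark_scenarios(seed=6, n_windows=5_000)[("faire", "neg")]
        sim = simulate_dataset(cfg)
        fit = fit_mixture(model_design(sim, 3))
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6)

    def test_window_order_exchangeability(self):
        cfg = benchmark_scenarios(seed=7, n_windows=3_000)[("tfbs", "neg")]
        sim = simulate_dataset(cfg)
        wt = model_design(sim, 3)
        fit = fit_mixture(wt)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(sim.y))
        wt_p = WindowTable(
            sim.y[perm], wt.X0[perm], wt.X1[perm], wt.X2[perm]
        )
        fit_p = fit_mixture(wt_p)
        # agreement is limited by the EM stopping rule, not by window order
        assert np.allclose(fit.params.beta1, fit_p.params.beta1, atol=1e-4)
        assert np.allclose(fit.params.beta2, fit_p.params.beta2, atol=1e-4)
        assert np.isclose(fit.params.pi2, fit_p.params.pi2, atol=1e-6)

    def test_posterior_invariants(self):
        cfg = benchmark_scenarios(seed=8, n_windows=4_000)[("faire", "zero")]
        sim = simulate_dataset(cfg)
        fit = fit_mixture(model_design(sim, 2))
        tau = fit.posteriors
        assert np.allclose(tau.tau0 + tau.tau1 + tau.tau2, 1.0, atol=1e-10)
        assert np.all(tau.tau0[sim.y > 0] == 0.0)
        assert np.all((tau.as_array() >= 0) & (tau.as_array() <= 1))

    def test_reduces_to_single_nb_glm_when_forced(self):
        """With zero-inflation off and one component emptied, the fit matches
        an unweighted NB regression obtained by direct likelihood optimization."""
        rng = np.random.default_rng(9)
        n = 2000
        x = rng.normal(size=n)
        mu = np.exp(1.0 + 0.4 * x)
        y = rng.negative_binomial(2.0, 2.0 / (2.0 + mu))
        X = np.column_stack([np.ones(n), x])
        tau = PosteriorMatrix(np.zeros(n), np.ones(n), np.zeros(n))
        prev = MixtureParams(np.array([-30.0]), np.zeros(2), np.zeros(2), 1.0, 1.0, 0.5, 0.5)
        params = m_step(y, np.ones((n, 1)), X, X, tau, prev=prev)

        def nll(p):
            b, lt = p[:2], p[2]
            th = np.exp(lt)
            m = np.exp(X @ b)
            return -stats.nbinom.logpmf(y, th, th / (th + m)).sum()

        res = minimize(nll, np.array([0.5, 0.0, 0.5]), method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-9, "maxiter": 6000})
        assert np.allclose(params.beta1, res.x[:2], atol=1e-4)

    def test_requires_distinct_positive_counts(self):
        wt = WindowTable(
            np.array([0, 1, 1, 0]), np.ones((4, 1)), np.ones((4, 1)), np.ones((4, 1))
        )
        with pytest.raises(ValueError):
            fit_mixture(wt)
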