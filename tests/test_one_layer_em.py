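import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

from deepcdm.model_core import (
    EffectBasis,
    LayerCoefficients,
    conditional_prob_table,
    enumerate_profiles,
)
from deepcdm.one_layer_em import (
    BETA_MAX,
    ExpandedRegression,
    LayerFit,
    PenaltyConfig,
    ProfilePosterior,
    bic,
    count_parameters,
    e_step,
    expand_weighted_regression,
    fit_one_layer,
    fitting_basis,
    m_step_beta,
    m_step_pi,
    _fit_units_logistic,
)
from deepcdm.spectral_init import spectral_init
from conftest import random_coefficients


def _bayes_posterior_oracle(data, coeffs, pi):
    """Independent brute-force Bayes rule, probability by probability."""
    P = len(pi)
    profiles = enumerate_profiles(coeffs.K)
    theta = conditional_prob_table(coeffs, "inverse_logit")
    W = np.zeros((len(data), P))
    for i, row in enumerate(data):
        for m in range(P):
            lik = pi[m]
            for j, z in enumerate(row):
                lik *= theta[j, m] if z else 1 - theta[j, m]
            W[i, m] = lik
        W[i] /= W[i].sum()
    return W


class TestEStep:
    def test_flat_likelihood_returns_prior(self, rng):
        coeffs = LayerCoefficients("main_effect", 2, np.zeros((4, 3)))
        pi = rng.dirichlet(np.ones(4))
        data = rng.integers(0, 2, size=(6, 4))
        post, _ = e_step(data, coeffs, pi)
        assert np.allclose(post.weights, pi[None, :], atol=1e-12)

    def test_degenerate_prior(self, rng):
        coeffs = random_coefficients(rng, 3, 2)
        pi = np.array([0.0, 0.0, 1.0, 0.0])
        data = rng.integers(0, 2, size=(5, 3))
        post, _ = e_step(data, coeffs, pi)
        assert np.allclose(post.weights[:, 2], 1.0)

    def test_matches_enumeration_bayes_oracle(self, rng):
        coeffs = random_coefficients(rng, 3, 2)
        pi = rng.dirichlet(np.ones(4))
        data = rng.integers(0, 2, size=(4, 3))
        post, ll = e_step(data, coeffs, pi)
        oracle = _bayes_posterior_oracle(data, coeffs, pi)
        assert np.allclose(post.weights, oracle, atol=1e-9)

    @pytest.mark.parametrize("K", [1, 2, 3])
    def test_oracle_over_profile_sizes(self, rng, K):
        coeffs = random_coefficients(rng, 4, K, scale=1.5)
        pi = rng.dirichlet(np.ones(2**K))
        data = rng.integers(0, 2, size=(8, 4))
        post, _ = e_step(data, coeffs, pi)
        assert np.allclose(post.weights, _bayes_posterior_oracle(data, coeffs, pi),
                           atol=1e-9)


class TestExpandWeightedRegression:
    def test_n1_k1_two_rows(self):
        basis = EffectBasis.main_effect(1)
        post = ProfilePosterior(np.array([[0.3, 0.7]]))
        exp = expand_weighted_regression(np.array([[1, 0]]), post, basis)
        assert exp.design.shape == (2, 2)
        assert np.allclose(exp.weights, [0.3, 0.7])
        assert np.allclose(exp.outcomes, [[1, 0], [1, 0]])

    def test_degenerate_posterior_collapses(self):
        basis = EffectBasis.main_effect(2)
        W = np.zeros((3, 4))
        W[:, 1] = 1.0
        exp = expand_weighted_regression(np.zeros((3, 2)), ProfilePosterior(W), basis)
        assert np.all(exp.profile_index == 1)
        assert len(exp.weights) == 3

    def test_weighted_sums_preserved_after_drop(self, rng):
        basis = EffectBasis.main_effect(2)
        W = rng.dirichlet(np.full(4, 0.05), size=10)  # many near-zero weights
        data = rng.integers(0, 2, size=(10, 3)).astype(float)
        exp = expand_weighted_regression(data, ProfilePosterior(W), basis)
        n, s = exp.sufficient_stats()
        assert n.sum() == pytest.approx(10.0, abs=1e-9)
        for j in range(3):
            assert s[:, j].sum() == pytest.approx((W.sum(1) * data[:, j]).sum(), abs=1e-9)

    def test_expanded_loglik_equals_direct_weighted_sum(self, rng):
        basis = EffectBasis.main_effect(2)
        coeffs = random_coefficients(rng, 3, 2)
        W = rng.dirichlet(np.ones(4), size=5)
        data = rng.integers(0, 2, size=(5, 3)).astype(float)
        exp = expand_weighted_regression(data, ProfilePosterior(W), basis)
        theta = conditional_prob_table(coeffs, "inverse_logit")
        # expanded-view weighted log-likelihood
        p_rows = expit(exp.design @ coeffs.values.T)  # (rows, units)
        ll_exp = np.sum(exp.weights[:, None] * (
            exp.outcomes * np.log(p_rows) + (1 - exp.outcomes) * np.log1p(-p_rows)))
        # direct posterior-weighted sum
        ll_direct = sum(
            W[i, m] * (data[i, j] * np.log(theta[j, m])
                       + (1 - data[i, j]) * np.log(1 - theta[j, m]))
            for i in range(5) for m in range(4) for j in range(3)
        )
        assert ll_exp == pytest.approx(ll_direct, abs=1e-9)


class TestMStepBeta:
    def _expanded(self, rng, N=200, K=1, M=2):
        basis = EffectBasis.main_effect(K)
        W = rng.dirichlet(np.ones(2**K), size=N)
        data = rng.integers(0, 2, size=(N, M)).astype(float)
        return expand_weighted_regression(data, ProfilePosterior(W), basis), data, W

    def test_huge_lambda_gives_weighted_mean_intercept(self, rng):
        exp, data, W = self._expanded(rng)
        values = m_step_beta(exp, lam=1e6)
        assert np.all(values[:, 1:] == 0.0)
        pbar = data.mean(axis=0)  # weights sum to 1 per person
        assert np.allclose(values[:, 0], logit(pbar), atol=1e-6)

    def test_lambda_zero_matches_generic_optimizer(self, rng):
        exp, _, _ = self._expanded(rng, N=200, K=1, M=1)
        values = m_step_beta(exp, lam=0.0)
        X, w, y = exp.design, exp.weights, exp.outcomes[:, 0]

        def negll(beta):
            eta = X @ beta
            return -np.sum(w * (y * eta - np.logaddexp(0.0, eta)))

        res = minimize(negll, np.zeros(2), method="BFGS")
        assert np.allclose(values[0], res.x, atol=1e-4)

    def test_duplicate_rows_half_weight_invariance(self, rng):
        exp, _, _ = self._expanded(rng, N=100, K=1, M=2)
        doubled = ExpandedRegression(
            np.vstack([exp.design, exp.design]),
            np.vstack([exp.outcomes, exp.outcomes]),
            np.concatenate([exp.weights / 2, exp.weights / 2]),
            np.concatenate([exp.profile_index, exp.profile_index]),
            exp.basis,
        )
        a = m_step_beta(exp, lam=0.5)
        b = m_step_beta(doubled, lam=0.5)
        assert np.allclose(a, b, atol=1e-8)

    def test_support_mask_pins_zero(self, rng):
        exp, _, _ = self._expanded(rng, N=100, K=1, M=2)
        mask = np.array([[True, False], [True, True]])
        values = m_step_beta(exp, lam=0.0, support_mask=mask)
        assert values[0, 1] == 0.0
        assert values[1, 1] != 0.0

    def test_single_coordinate_soft_threshold_closed_form(self):
        # one quadratic (IRLS) step from zero must equal the closed form
        X = np.array([[1.0], [2.0], [3.0]])
        n = np.array([4.0, 2.0, 1.0])
        s = np.array([3.0, 1.0, 1.0])
        lam = 0.8
        out = _fit_units_logistic(
            X, n, s[:, None], lam, np.zeros((1, 1)),
            penalized=np.array([True]), support=np.array([[True]]),
            max_outer=1, max_sweeps=1,
        )
        w = n * 0.25  # p = 0.5 at beta = 0
        z = (s - n * 0.5) / w
        rho = (X[:, 0] * w) @ z
        expected = np.sign(rho) * max(abs(rho) - lam, 0) / (w @ X[:, 0] ** 2)
        assert out[0, 0] == pytest.approx(expected, abs=1e-12)


class TestMStepPi:
    def test_mean_of_rows(self):
        W = ProfilePosterior(np.array([[0.2, 0.8], [0.6, 0.4]]))
        assert np.allclose(m_step_pi(W), [0.4, 0.6])

    def test_single_person(self):
        W = ProfilePosterior(np.array([[0.1, 0.3, 0.2, 0.4]]))
        assert np.allclose(m_step_pi(W), [0.1, 0.3, 0.2, 0.4])

    def test_local_optimality(self, rng):
        W = rng.dirichlet(np.ones(4), size=20)
        pi_hat = m_step_pi(ProfilePosterior(W))

        def objective(pi):
            return float(np.sum(W * np.log(pi)[None, :]))

        base = objective(pi_hat)
        for _ in range(50):
            delta = rng.normal(scale=0.01, size=4)
            pert = np.maximum(pi_hat + delta - delta.mean(), 1e-9)
            pert /= pert.sum()
            assert objective(pert) <= base + 1e-12


def _ascent_ok(trace, slack=1e-8):
    trace = np.asarray(trace)
    return np.all(np.diff(trace) >= -slack * (np.abs(trace[:-1]) + 1.0))


class TestFitOneLayer:
    def test_objective_trace_non_decreasing(self, rng):
        coeffs = random_coefficients(rng, 6, 2, scale=1.5)
        pi = rng.dirichlet(np.ones(4))
        theta = conditional_prob_table(coeffs, "inverse_logit")
        idx = rng.choice(4, size=400, p=pi)
        data = (rng.random((400, 6)) < theta[:, idx].T).astype(float)
        init = spectral_init(data, 2, "main_effect")
        for lam in (0.0, 1.0, 10.0):
            fit = fit_one_layer(data, 2, "main_effect", lam,
                                (init.coeffs, init.pi0), tol=1e-5, max_iter=100)
            assert _ascent_ok(fit.objective_trace)

    def test_noiseless_fixed_point(self):
        values = np.tile([-BETA_MAX, 2 * BETA_MAX], (3, 1))
        coeffs = LayerCoefficients("main_effect", 1, values)
        pi = np.array([0.5, 0.5])
        a = np.repeat([0, 1], 20)
        data = np.tile(a[:, None], (1, 3)).astype(float)
        fit = fit_one_layer(data, 1, "main_effect", 0.0, (coeffs, pi), tol=1e-6)
        assert fit.n_iter <= 2
        assert fit.objective_trace[-1] == pytest.approx(fit.objective_trace[0], abs=1e-6)

    def test_em_improves_on_init(self, rng):
        from deepcdm.synthetic_data import make_design, sample
        import dataclasses

        d = make_design("main_effect", 2000, 3, widths=(8, 2, 1), slopes=(2.5, 1.5))
        t = sample(d)
        data = t.responses.astype(float)
        init = spectral_init(data, 2, "main_effect")
        _, ll_init = e_step(data, init.coeffs, np.maximum(init.pi0, 1e-12) /
                            np.maximum(init.pi0, 1e-12).sum())
        fit = fit_one_layer(data, 2, "main_effect", 0.01, (init.coeffs, init.pi0),
                            tol=1e-5, max_iter=200)
        assert fit.loglik >= ll_init - 1e-6

    def test_flat_truth_recovered(self, rng):
        data = (rng.random((5000, 4)) < 0.5).astype(float)
        init = spectral_init(data, 1, "main_effect")
        fit = fit_one_layer(data, 1, "main_effect", 0.0, (init.coeffs, init.pi0),
                            tol=1e-6, max_iter=200)
        theta = conditional_prob_table(fit.coeffs, "inverse_logit")
        marg = theta @ fit.pi
        assert np.allclose(marg, 0.5, atol=0.03)


class TestBic:
    def test_extra_nonzero_costs_log_n(self):
        c1 = LayerCoefficients("main_effect", 1, np.array([[0.5, 0.0]]))
        c2 = LayerCoefficients("main_effect", 1, np.array([[0.5, 0.3]]))
        f1 = LayerFit(c1, np.array([0.5, 0.5]), [0.0], 1, True, -100.0, np.nan, 0.0)
        f2 = LayerFit(c2, np.array([0.5, 0.5]), [0.0], 1, True, -100.0, np.nan, 0.0)
        N = 321
        assert bic(f2, N) - bic(f1, N) == pytest.approx(np.log(N))

    def test_n1_has_zero_penalty(self):
        c = LayerCoefficients("main_effect", 1, np.array([[0.5, 0.3]]))
        f = LayerFit(c, np.array([0.5, 0.5]), [0.0], 1, True, -10.0, np.nan, 0.0)
        assert bic(f, 1) == pytest.approx(20.0)

    def test_sparse_truth_preferred(self, rng):
        # simulated D=1 data with a sparse generating Q: the true support's
        # BIC should usually beat the saturated support's
        from deepcdm.synthetic_data import make_design, sample
        import dataclasses

        from deepcdm.layerwise_driver import q_support_mask

        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            d = make_design("main_effect", 2000, seed, widths=(8, 2, 1),
                            slopes=(2.5, 1.5))
            t = sample(d)
            data = t.responses.astype(float)
            # start both fits from the generating values so the comparison
            # isolates BIC's preference rather than optimizer luck
            truth_values = d.B_true[0].values
            p1 = d.params().layer_marginals()[0]
            mask = q_support_mask(d.Q_true[0], "main_effect")
            sparse = fit_one_layer(data, 2, "main_effect", 0.0,
                                   (truth_values, p1), tol=1e-4, max_iter=200,
                                   support_mask=mask)
            sat = fit_one_layer(data, 2, "main_effect", 0.0,
                                (truth_values, p1), tol=1e-4, max_iter=200)
            if sparse.bic < sat.bic:
                wins += 1
        assert wins >= 0.9 * n_seeds


class TestValidation:
    def test_posterior_rows_must_normalize(self):
        with pytest.raises(ValueError):
            ProfilePosterior(np.array([[0.5, 0.2]]))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            PenaltyConfig(lambda_=-1.0)

    def test_count_parameters(self):
        c = LayerCoefficients("main_effect", 2, np.array([[0.5, 0.0, 1.0]]))
        f = LayerFit(c, np.ones(4) / 4, [0.0], 1, True, -10.0, np.nan, 0.0)
        assert count_parameters(f) == 2 + 3
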