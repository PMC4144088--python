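"""Unit and property tests for the regression-HMM core."""
import itertools

import numpy as np
import pytest
from scipy import stats

from reghmm import core, synthetic
from reghmm.types import RegHMMParams
from .conftest import enumerate_paths_loglik, random_instance

LOG2PI = np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# emissions


class TestEmissionLogdensity:
    def test_at_fitted_mean_unit_sigma(self):
        X = np.array([[1.0, 2.0]])
        betas = np.array([[0.5, 1.0, -1.0]])
        y = np.array([0.5 + 1.0 * 1.0 - 1.0 * 2.0])
        out = core.emission_logdensity(X, y, betas, np.array([1.0]))
        assert out.shape == (1, 1)
        assert np.isclose(out[0, 0], -0.5 * LOG2PI)

    def test_zero_coefficients_standard_normal(self):
        out = core.emission_logdensity(
            np.array([[3.0]]), np.array([0.0]), np.array([[0.0, 0.0]]), np.array([1.0])
        )
        assert np.isclose(out[0, 0], -0.5 * LOG2PI)

    def test_matches_direct_normal_pdf(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 4))
        y = rng.standard_normal(20)
        betas = rng.standard_normal((3, 5))
        sigmas = rng.uniform(0.2, 3.0, 3)
        out = core.emission_logdensity(X, y, betas, sigmas)
        mu = betas[:, 0] + X @ betas[:, 1:].T
        expected = stats.norm.logpdf(y[:, None], loc=mu, scale=sigmas[None, :])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            core.emission_logdensity(np.array([[1.0]]), np.array([np.nan]),
                                     np.array([[0.0, 1.0]]), np.array([1.0]))
        with pytest.raises(ValueError):
            core.emission_logdensity(np.array([[1.0]]), np.array([1.0]),
                                     np.array([[0.0, 1.0]]), np.array([0.0]))


# ---------------------------------------------------------------------------
# transitions


class TestTransitionMatrix:
    P = np.array([[0.5, 0.5], [0.3, 0.7]])

    def test_zero_distance_is_identity(self):
        np.testing.assert_allclose(core.transition_matrix(0.0, self.P, 4000), np.eye(2))

    def test_large_distance_recovers_baseline(self):
        np.testing.assert_allclose(core.transition_matrix(1e12, self.P, 4000), self.P,
                                   atol=1e-9)

    def test_d_equals_D_half_stay(self):
        # e^{-1} + (1 - e^{-1}) * 0.5 with p_ii = 0.5, d = D = 4000
        A = core.transition_matrix(4000.0, self.P, 4000.0)
        expected = np.exp(-1) + (1 - np.exp(-1)) * 0.5
        assert np.isclose(A[0, 0], expected)
        assert np.isclose(expected, 0.6839, atol=5e-5)

    def test_rows_sum_to_one_and_monotone(self):
        ds = np.linspace(0, 50000, 40)
        prev = None
        for d in ds:
            A = core.transition_matrix(d, self.P, 4000)
            np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)
            if prev is not None:
                assert np.all(np.diag(A) <= np.diag(prev) + 1e-12)
            prev = A
        # self-transition increasing in D at fixed d
        diags = [np.diag(core.transition_matrix(4000, self.P, D)) for D in (500, 4000, 40000)]
        assert np.all(np.diff(np.array(diags), axis=0) > 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            core.transition_matrix(-1.0, self.P, 4000)


# ---------------------------------------------------------------------------
# forward-backward


class TestForwardBackward:
    def test_single_observation(self):
        X, y, d, params = random_instance(np.random.default_rng(0))
        X, y, d = X[:1], y[:1], d[:1]
        logB = core.emission_logdensity(X, y, params.betas, params.sigmas)
        ll, gamma, xi = core.forward_backward(d, logB, params)
        expected = np.log(np.sum(params.pi * np.exp(logB[0])))
        assert np.isclose(ll, expected)
        np.testing.assert_allclose(gamma[0], params.pi * np.exp(logB[0]) /
                                   np.sum(params.pi * np.exp(logB[0])))

    def test_identical_emissions_decouple(self):
        # emissions identical across states: loglik = plain emission sum
        rng = np.random.default_rng(1)
        T, M = 10, 3
        logB = np.tile(rng.standard_normal(T)[:, None], (1, M))
        d = np.concatenate([[np.nan], rng.uniform(100, 5000, T - 1)])
        params = RegHMMParams(pi=np.full(M, 1 / M),
                              baseline_transitions=rng.dirichlet(np.ones(M), size=M),
                              distance_constant=4000,
                              betas=np.zeros((M, 2)), sigmas=np.ones(M))
        ll, gamma, _ = core.forward_backward(d, logB, params)
        assert np.isclose(ll, logB[:, 0].sum())
        # gamma follows the chain's marginal state law
        marg = params.pi.copy()
        np.testing.assert_allclose(gamma[0], marg, atol=1e-12)
        for t in range(1, T):
            A = core.transition_matrix(d[t], params.baseline_transitions, 4000)
            marg = marg @ A
            np.testing.assert_allclose(gamma[t], marg, atol=1e-10)

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_path_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        X, y, d, params = random_instance(rng)
        logB = core.emission_logdensity(X, y, params.betas, params.sigmas)
        ll, gamma, xi = core.forward_backward(d, logB, params)
        oracle_ll, _, _ = enumerate_paths_loglik(d, logB, params)
        assert abs(ll - oracle_ll) < 1e-9
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)

    def test_rejects_nan_emissions(self):
        params = RegHMMParams(pi=[1.0], baseline_transitions=[[1.0]],
                              distance_constant=4000, betas=[[0.0, 1.0]], sigmas=[1.0])
        with pytest.raises(ValueError):
            core.forward_backward(np.array([np.nan]), np.array([[np.nan]]), params)


# ---------------------------------------------------------------------------
# M-step


class TestMStep:
    def _setup(self, seed=0, T=200, p=3):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((T, p))
        true = rng.integers(0, 2, T)
        betas = np.array([[0.0, 1.0, -1.0, 0.5], [2.0, -0.5, 0.5, 0.0]])
        y = betas[true, 0] + np.einsum("tp,tp->t", X, betas[true, 1:])
        d = np.concatenate([[np.nan], rng.uniform(100, 5000, T - 1)])
        params = RegHMMParams(pi=[0.5, 0.5], baseline_transitions=[[0.5, 0.5], [0.5, 0.5]],
                              distance_constant=4000, betas=betas, sigmas=[0.5, 0.5])
        return X, y, true, d, params

    def test_all_mass_one_state_reduces_to_ols(self):
        X, y, true, d, params = self._setup()
        y = y + 0.1 * np.random.default_rng(1).standard_normal(len(y))
        gamma = np.column_stack([np.ones(len(y)), np.zeros(len(y))])
        xi = np.zeros((len(y), 2, 2))
        new = core.m_step(X, y, gamma, xi, d, params)
        Z = np.column_stack([np.ones(len(y)), X])
        ols, *_ = np.linalg.lstsq(Z, y, rcond=None)
        np.testing.assert_allclose(new.betas[0], ols, atol=1e-8)

    def test_true_indicators_give_per_group_ols(self):
        X, y, true, d, params = self._setup()
        gamma = np.eye(2)[true]
        xi = np.zeros((len(y), 2, 2))
        new = core.m_step(X, y, gamma, xi, d, params)
        Z = np.column_stack([np.ones(len(y)), X])
        for i in range(2):
            sel = true == i
            ols, *_ = np.linalg.lstsq(Z[sel], y[sel], rcond=None)
            np.testing.assert_allclose(new.betas[i], ols, atol=1e-8)

    def test_fixed_point_on_noiseless_data(self):
        # at the truth, with noiseless responses and well-separated surfaces
        # (posteriors fully degenerate), one EM step leaves the regression
        # coefficients unchanged
        rng = np.random.default_rng(0)
        T, p = 200, 3
        X = rng.standard_normal((T, p))
        true = rng.integers(0, 2, T)
        betas = np.array([[0.0, 1.0, -1.0, 0.5], [8.0, 1.0, -1.0, 0.5]])
        y = betas[true, 0] + np.einsum("tp,tp->t", X, betas[true, 1:])
        d = np.concatenate([[np.nan], rng.uniform(100, 5000, T - 1)])
        params = RegHMMParams(pi=[0.5, 0.5], baseline_transitions=[[0.5, 0.5], [0.5, 0.5]],
                              distance_constant=4000, betas=betas, sigmas=[0.5, 0.5])
        logB = core.emission_logdensity(X, y, params.betas, params.sigmas)
        _, gamma, xi = core.forward_backward(d, logB, params)
        new = core.m_step(X, y, gamma, xi, d, params)
        np.testing.assert_allclose(new.betas, params.betas, atol=1e-6)


# ---------------------------------------------------------------------------
# Viterbi


class TestViterbi:
    def test_single_state_constant_path(self):
        rng = np.random.default_rng(0)
        X, y, d, _ = random_instance(rng)
        params = RegHMMParams(pi=[1.0], baseline_transitions=[[1.0]],
                              distance_constant=4000,
                              betas=np.zeros((1, X.shape[1] + 1)), sigmas=[1.0])
        logB = core.emission_logdensity(X, y, params.betas, params.sigmas)
        path = core.viterbi(d, logB, params)
        assert np.all(path == 1)

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_enumeration_argmax(self, trial):
        rng = np.random.default_rng(2000 + trial)
        X, y, d, params = random_instance(rng)
        logB = core.emission_logdensity(X, y, params.betas, params.sigmas)
        path = core.viterbi(d, logB, params)
        _, _, best_lp = enumerate_paths_loglik(d, logB, params)
        # the decoded path must attain the enumerated maximum
        lp = self._path_logprob(d, logB, params, path - 1)
        assert np.isclose(lp, best_lp, atol=1e-9)

    @staticmethod
    def _path_logprob(d, logB, params, path0):
        starts = np.isnan(np.asarray(d, dtype=float))
        lp = 0.0
        for t in range(len(path0)):
            lp += logB[t, path0[t]]
            if starts[t]:
                lp += np.log(params.pi[path0[t]])
            else:
                A = core.transition_matrix(d[t], params.baseline_transitions,
                                           params.distance_constant)
                lp += np.log(A[path0[t - 1], path0[t]])
        return lp

    def test_near_deterministic_emissions_pointwise(self):
        rng = np.random.default_rng(7)
        T = 50
        labels = rng.integers(0, 2, T)
        logB = np.where(np.arange(2)[None, :] == labels[:, None], 0.0, -1e6)
        d = np.concatenate([[np.nan], rng.uniform(100, 5000, T - 1)])
        params = RegHMMParams(pi=[0.5, 0.5], baseline_transitions=[[0.5, 0.5], [0.5, 0.5]],
                              distance_constant=4000, betas=np.zeros((2, 2)), sigmas=[1, 1])
        path = core.viterbi(d, logB, params)
        np.testing.assert_array_equal(path - 1, labels)


# ---------------------------------------------------------------------------
# BIC


class TestBic:
    def test_zero_case(self):
        assert core.bic(0.0, 0, 1) == 0.0

    def test_ln_e_squared(self):
        assert np.isclose(core.bic(-100.0, 10, int(np.e**2)), -100 - 0.5 * 10 *
                          np.log(int(np.e**2)))
        # with T exactly e^2 the value is -110
        assert np.isclose(-100 - 0.5 * 10 * 2.0, -110.0)

    @pytest.mark.parametrize("M,p", [(1, 3), (2, 10), (3, 5), (4, 70)])
    def test_free_parameter_count(self, M, p):
        # count directly: M(p+1) slopes+intercepts, M variances,
        # M rows of P with M-1 free entries each, pi with M-1 free entries
        direct = M * (p + 1) + M + M * (M - 1) + (M - 1)
        assert core.n_free_params(M, p) == direct
        assert core.n_free_params(M, p) == M * (p + 2) + M * (M - 1) + (M - 1)


# ---------------------------------------------------------------------------
# EM driver


class TestFitEM:
    def test_single_state_equals_ols(self):
        rng = np.random.default_rng(0)
        T, p = 120, 3
        X = rng.standard_normal((T, p))
        y = 1.0 + X @ np.array([1.0, -0.5, 0.2]) + 0.5 * rng.standard_normal(T)
        d = np.concatenate([[np.nan], rng.uniform(100, 5000, T - 1)])
        fit = core.fit_em(X, y, d, 1, n_restarts=2, seed=0)
        Z = np.column_stack([np.ones(T), X])
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        np.testing.assert_allclose(fit.params.betas[0], coef, atol=1e-4)
        resid = y - Z @ coef
        sigma2 = np.mean(resid**2)
        expected_ll = np.sum(stats.norm.logpdf(resid, scale=np.sqrt(sigma2)))
        assert np.isclose(fit.loglik, expected_ll, atol=1e-3)

    def test_em_monotone_loglik(self, recovery_dataset):
        ds = recovery_dataset
        fit = core.fit_em(ds.predictors.values, ds.expression, ds.distances, 2,
                          n_restarts=3, seed=1)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)
        np.testing.assert_allclose(fit.gamma.sum(axis=1), 1.0, atol=1e-10)

    def test_two_state_recovery(self, recovery_dataset):
        ds = recovery_dataset
        fit = core.fit_em(ds.predictors.values, ds.expression, ds.distances, 2,
                          n_restarts=5, seed=3)
        fit = core.relabel_by_r2(fit, ds.predictors.values, ds.expression)
        agree = np.mean(fit.viterbi_path == ds.true_states)
        agree = max(agree, 1 - agree)
        assert agree > 0.85
        rmse = np.sqrt(np.mean((fit.params.betas - ds.spec.betas) ** 2))
        assert rmse < 0.15  # T=800 here; the full-size experiment is tighter

    def test_requires_more_genes_than_predictors(self):
        with pytest.raises(ValueError):
            core.fit_em(np.zeros((5, 10)), np.zeros(5),
                        np.concatenate([[np.nan], np.ones(4)]), 2)

    def test_label_permutation_invariance(self, recovery_dataset):
        ds = recovery_dataset
        X, y, d = ds.predictors.values, ds.expression, ds.distances
        fit = core.fit_em(X, y, d, 2, n_restarts=2, seed=4)
        ll = core.loglik_at(X, y, d, fit.params)
        ll_perm = core.loglik_at(X, y, d, fit.params.permuted([1, 0]))
        assert np.isclose(ll, ll_perm, atol=1e-8)


class TestModelSelection:
    def test_single_candidate_returned(self, recovery_dataset):
        ds = recovery_dataset
        best, scores = core.select_num_states(ds.predictors.values, ds.expression,
                                              ds.distances, [2], n_restarts=2, seed=0)
        assert best == 2 and len(scores) == 1
        s = scores[0]
        assert np.isclose(s.bic, s.loglik - 0.5 * s.n_params * np.log(len(ds.genes)))

    def test_two_state_data_prefers_two_states(self, recovery_dataset):
        ds = recovery_dataset
        best, _ = core.select_num_states(ds.predictors.values, ds.expression,
                                         ds.distances, [1, 2], n_restarts=3, seed=1)
        assert best == 2


class TestMixtureNoMarkov:
    def test_single_component_equals_ols(self):
        rng = np.random.default_rng(0)
        T, p = 100, 2
        X = rng.standard_normal((T, p))
        y = 0.5 + X @ np.array([1.0, -1.0]) + 0.3 * rng.standard_normal(T)
        fit = core.fit_mixture_no_markov(X, y, 1, n_restarts=1, seed=0)
        Z = np.column_stack([np.ones(T), X])
        coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
        np.testing.assert_allclose(fit.params.betas[0], coef, atol=1e-4)

    def test_equivalent_to_reghmm_when_order_free(self):
        # constant distances and identical baseline rows: the chain carries
        # no information, so the regHMM likelihood at matched parameters
        # equals the independent mixture's
        rng = np.random.default_rng(5)
        T, p = 150, 2
        X = rng.standard_normal((T, p))
        true = rng.integers(0, 2, T)
        betas = np.array([[0.0, 2.0, 0.0], [2.0, -2.0, 0.0]])
        y = betas[true, 0] + np.einsum("tp,tp->t", X, betas[true, 1:]) \
            + 0.4 * rng.standard_normal(T)
        mix = core.fit_mixture_no_markov(X, y, 2, n_restarts=5, seed=1)
        w = mix.params.pi
        d = np.concatenate([[np.nan], np.full(T - 1, 1e9)])  # e ~ 0: A = P
        hmm_params = RegHMMParams(pi=w, baseline_transitions=np.tile(w, (2, 1)),
                                  distance_constant=4000.0, betas=mix.params.betas,
                                  sigmas=mix.params.sigmas)
        ll_hmm = core.loglik_at(X, y, d, hmm_params)
        assert np.isclose(ll_hmm, mix.loglik, atol=1e-6)

    def test_markov_advantage_on_persistent_data(self, recovery_dataset):
        ds = recovery_dataset
        X, y, d = ds.predictors.values, ds.expression, ds.distances
        hmm = core.fit_em(X, y, d, 2, n_restarts=3, seed=2)
        mix = core.fit_mixture_no_markov(X, y, 2, n_restarts=3, seed=2)
        assert hmm.bic > mix.bic


class TestRelabelByR2:
    def test_state1_is_stronger_association(self, recovery_dataset):
        ds = recovery_dataset
        X, y = ds.predictors.values, ds.expression
        fit = core.fit_em(X, y, ds.distances, 2, n_restarts=3, seed=6)
        fit = core.relabel_by_r2(fit, X, y)
        from reghmm.state_analysis import ols_r2

        sel1 = fit.viterbi_path == 1
        sel2 = fit.viterbi_path == 2
        assert ols_r2(X[sel1], y[sel1]) >= ols_r2(X[sel2], y[sel2])
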