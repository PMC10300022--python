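"""HMM engine: enumeration oracles for forward-backward and Viterbi,
closed-form degenerate cases, label-permutation equivalence, sufficiency,
parameter recovery and model-order selection."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from dynstates import (GaussianHMM, HMMParams, fit_hmm, forward_backward,
                       match_states, permute_states, select_model_order,
                       state_correlation_matrix, viterbi)
from dynstates.hmm import _e_step, _m_step, n_hmm_parameters


def random_params(K, M, rng, sticky=0.7):
    A = rng.uniform(0.1, 1.0, size=(K, K))
    A += sticky * K * np.eye(K)
    A /= A.sum(axis=1, keepdims=True)
    pi = rng.uniform(0.2, 1.0, size=K)
    pi /= pi.sum()
    mu = rng.normal(0, 1.5, size=(K, M))
    Sigma = np.empty((K, M, M))
    for k in range(K):
        L = rng.normal(size=(M, M)) * 0.3
        Sigma[k] = L @ L.T + np.eye(M)
    return HMMParams(pi=pi, A=A, mu=mu, Sigma=Sigma)


def enumerate_paths_loglik(params, X):
    """Brute-force log p(X) and the best path by summing over all K^T paths."""
    K, T = params.K, X.shape[0]
    logB = np.stack([multivariate_normal.logpdf(X, params.mu[k], params.Sigma[k])
                     for k in range(params.K)], axis=1)
    log_pi = np.log(params.pi)
    log_A = np.log(params.A)
    terms = []
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        lp = log_pi[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += log_A[path[t - 1], path[t]] + logB[t, path[t]]
        terms.append(lp)
        if lp > best_lp:
            best_lp, best_path = lp, path
    return logsumexp(terms), np.asarray(best_path) + 1, best_lp


class TestForwardBackward:
    def test_single_state_posterior_and_loglik(self, rng):
        X = rng.normal(size=(30, 2))
        params = HMMParams(pi=np.array([1.0]), A=np.ones((1, 1)),
                           mu=np.zeros((1, 2)), Sigma=np.eye(2)[None])
        gamma, _, ll = forward_backward(params, X)
        np.testing.assert_allclose(gamma, 1.0)
        expect = multivariate_normal.logpdf(X, np.zeros(2), np.eye(2)).sum()
        assert ll == pytest.approx(expect, abs=1e-8)

    def test_symmetric_states_give_uniform_posterior(self):
        # two identical states: the data cannot distinguish them
        params = HMMParams(pi=np.array([0.5, 0.5]),
                           A=np.full((2, 2), 0.5),
                           mu=np.zeros((2, 1)), Sigma=np.ones((2, 1, 1)))
        X = np.array([[0.3], [-0.2], [0.1], [0.0], [0.5], [-0.4]])
        gamma, _, _ = forward_backward(params, X)
        np.testing.assert_allclose(gamma, 0.5, atol=1e-12)

    def test_loglik_matches_path_enumeration(self, rng):
        params = random_params(3, 2, rng)
        X = rng.normal(size=(7, 2))
        _, _, ll = forward_backward(params, X)
        expect, _, _ = enumerate_paths_loglik(params, X)
        assert ll == pytest.approx(expect, abs=1e-8)

    def test_gamma_rows_sum_to_one(self, rng):
        params = random_params(3, 2, rng)
        X = rng.normal(size=(50, 2))
        gamma, _, _ = forward_backward(params, X)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-8)

    def test_loglik_matches_hmmlearn(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        params = random_params(3, 2, rng)
        X = rng.normal(size=(40, 2))
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="full",
                                   init_params="")
        ref.startprob_ = params.pi
        ref.transmat_ = params.A
        ref.means_ = params.mu
        ref.covars_ = params.Sigma
        _, _, ll = forward_backward(params, X)
        assert ll == pytest.approx(ref.score(X), abs=1e-6)


class TestViterbi:
    def test_single_state_constant(self, rng):
        params = HMMParams(pi=np.array([1.0]), A=np.ones((1, 1)),
                           mu=np.zeros((1, 2)), Sigma=np.eye(2)[None])
        path = viterbi(params, rng.normal(size=(20, 2)))
        assert np.all(path == 1)

    def test_matches_enumerated_optimum(self, rng):
        params = random_params(3, 2, rng)
        X = rng.normal(size=(7, 2))
        path = viterbi(params, X)
        _, best_path, best_lp = enumerate_paths_loglik(params, X)
        np.testing.assert_array_equal(path, best_path)

    def test_recovers_truth_under_near_deterministic_emissions(self, rng):
        from dynstates import SimConfig, make_ground_truth, simulate_subject
        cfg = SimConfig(K=3, M=5, n_blocks=2, n_pathological=1,
                        mean_scale=10.0, seed=31)  # 10-SD mean separation
        gt = make_ground_truth(cfg)
        sub = simulate_subject(gt, "control", 300, 1.0, rng)
        params = HMMParams(pi=gt.pi["control"], A=gt.A["control"],
                           mu=gt.mu, Sigma=gt.Sigma)
        path = viterbi(params, sub.series)
        assert (path == sub.true_path).mean() == 1.0


class TestFit:
    def test_k1_closed_form(self, rng):
        X = rng.normal(size=(200, 3))
        res = GaussianHMM(X, k_states=1).fit(n_restarts=1, max_iter=10, seed=0)
        np.testing.assert_allclose(res.params.mu[0], X.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(res.params.Sigma[0],
                                   np.cov(X.T, bias=True) + 1e-6 * np.eye(3),
                                   atol=1e-8)
        expect = multivariate_normal.logpdf(X, res.params.mu[0],
                                            res.params.Sigma[0]).sum()
        assert res.loglik == pytest.approx(expect, abs=1e-6)

    def test_em_loglik_monotone(self, small_fit):
        *_, res = small_fit
        h = np.asarray(res.history)
        assert np.all(np.diff(h) > -1e-8 * np.maximum(1.0, np.abs(h[:-1])))

    def test_two_state_recovery_within_tolerance(self, rng):
        # well-separated two-state chain, single long sequence
        params = random_params(2, 2, rng)
        params.mu = np.array([[-2.5, -2.5], [2.5, 2.5]])  # 5 SD apart
        params.Sigma = np.stack([np.eye(2), np.eye(2)])
        A = np.array([[0.9, 0.1], [0.2, 0.8]])
        states = [0]
        for _ in range(1999):
            states.append(rng.choice(2, p=A[states[-1]]))
        states = np.asarray(states)
        X = params.mu[states] + rng.standard_normal((2000, 2))
        res = GaussianHMM(X, k_states=2).fit(n_restarts=2, seed=1)
        perm = match_states(res.params, HMMParams(pi=np.array([0.5, 0.5]), A=A,
                                                  mu=params.mu,
                                                  Sigma=params.Sigma))
        A_hat = permute_states(res.params, perm).A
        assert np.abs(A_hat - A).max() < 0.05

    def test_duplicated_dataset_leaves_em_update_invariant(self, rng):
        # sufficiency: one EM step from the same parameters on X and on
        # X stacked twice gives identical updates
        X = rng.normal(size=(80, 2))
        params = random_params(2, 2, rng)
        post1, sg1 = _e_step(X, [(0, 80)], params)
        up1 = _m_step(X, post1, sg1, 1, 1e-6)
        X2 = np.vstack([X, X])
        post2, sg2 = _e_step(X2, [(0, 80), (80, 160)], params)
        up2 = _m_step(X2, post2, sg2, 2, 1e-6)
        np.testing.assert_allclose(up1.A, up2.A, atol=1e-6)
        np.testing.assert_allclose(up1.mu, up2.mu, atol=1e-6)
        np.testing.assert_allclose(up1.Sigma, up2.Sigma, atol=1e-6)
        np.testing.assert_allclose(up1.pi, up2.pi, atol=1e-6)

    def test_label_permutation_equivalence(self, rng):
        params = random_params(3, 2, rng)
        X = rng.normal(size=(40, 2))
        gamma, _, ll = forward_backward(params, X)
        perm = np.array([2, 0, 1])
        gamma_p, _, ll_p = forward_backward(permute_states(params, perm), X)
        assert ll_p == pytest.approx(ll, abs=1e-8)
        np.testing.assert_allclose(gamma_p, gamma[:, perm], atol=1e-8)

    def test_subject_ranges_must_tile(self, rng):
        with pytest.raises(ValueError):
            GaussianHMM(rng.normal(size=(50, 2)), ranges=[(0, 30)], k_states=2)


class TestModelOrder:
    def test_bic_recovers_two_states(self, rng):
        mu = np.array([[-3.0, -3.0], [3.0, 3.0]])
        states = rng.integers(0, 2, size=600)
        # make runs sticky so transitions are informative
        for t in range(1, 600):
            if rng.random() < 0.85:
                states[t] = states[t - 1]
        X = mu[states] + rng.standard_normal((600, 2))
        scan = select_model_order(X, [(0, 600)], K_range=[2, 3, 4],
                                  n_restarts=2, max_iter=100, seed=3)
        assert scan.recommended_K == 2
        assert set(scan.table.columns) >= {"K", "loglik", "avLL", "BIC", "cv_fo"}

    def test_bic_recovers_single_state(self, rng):
        X = rng.normal(size=(400, 2))
        scan = select_model_order(X, [(0, 400)], K_range=[1, 2, 3],
                                  n_restarts=2, max_iter=100, seed=4)
        assert scan.recommended_K == 1

    def test_parameter_count(self):
        # (K-1) + K(K-1) + K*M + K*M(M+1)/2
        assert n_hmm_parameters(6, 45) == 5 + 30 + 270 + 6 * 45 * 46 // 2


class TestStateCorrelation:
    def test_diagonal_covariance_gives_identity(self):
        params = HMMParams(pi=np.array([1.0]), A=np.ones((1, 1)),
                           mu=np.zeros((1, 3)),
                           Sigma=np.diag([2.0, 5.0, 0.3])[None])
        np.testing.assert_allclose(state_correlation_matrix(params, 1),
                                   np.eye(3), atol=1e-12)

    def test_two_by_two_example(self):
        params = HMMParams(pi=np.array([1.0]), A=np.ones((1, 1)),
                           mu=np.zeros((1, 2)),
                           Sigma=np.array([[[4.0, 2.0], [2.0, 4.0]]]))
        R = state_correlation_matrix(params, 1)
        assert R[0, 1] == pytest.approx(0.5)

    def test_random_pd_unit_diagonal_symmetric(self, rng):
        for _ in range(5):
            L = rng.normal(size=(4, 4))
            params = HMMParams(pi=np.array([1.0]), A=np.ones((1, 1)),
                               mu=np.zeros((1, 4)),
                               Sigma=(L @ L.T + np.eye(4))[None])
            R = state_correlation_matrix(params, 1)
            np.testing.assert_allclose(R, R.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-12)

    def test_out_of_range_state_rejected(self):
        params = HMMParams(pi=np.array([1.0]), A=np.ones((1, 1)),
                           mu=np.zeros((1, 2)), Sigma=np.eye(2)[None])
        with pytest.raises(ValueError):
            state_correlation_matrix(params, 2)
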