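"""Gaussian hidden Markov model for concatenated BOLD component time courses.

The model: a single set of K states, each with a multivariate-Gaussian
observation distribution (mean activation vector and full covariance across
components), shared across all subjects. Subject boundaries break the chain:
the forward recursion restarts at every subject's first volume, while the
initial distribution, transition matrix and observation parameters are
estimated at the group level from the temporal concatenation.

Estimation is maximum-likelihood EM (Baum-Welch) with scaled forward-backward
recursions, k-means initialisation and random restarts; model order is chosen
by scanning K and comparing BIC alongside the average log-likelihood and the
coefficient of variation of occupancy estimates across restarts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

__all__ = [
    "HMMParams",
    "StatePosteriors",
    "GaussianHMM",
    "HMMResults",
    "OrderScanResult",
    "fit_hmm",
    "forward_backward",
    "viterbi",
    "select_model_order",
    "state_correlation_matrix",
    "permute_states",
    "match_states",
    "n_hmm_parameters",
]


@dataclass
class HMMParams:
    """K-state Gaussian HMM parameters."""

    pi: np.ndarray  # (K,)
    A: np.ndarray  # (K, K)
    mu: np.ndarray  # (K, M)
    Sigma: np.ndarray  # (K, M, M)

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def M(self) -> int:
        return self.mu.shape[1]

    def validate(self) -> None:
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi does not sum to 1")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition rows do not sum to 1")
        for k in range(self.K):
            S = self.Sigma[k]
            if not np.allclose(S, S.T, atol=1e-8):
                raise ValueError(f"Sigma[{k}] not symmetric")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError(f"Sigma[{k}] not positive definite")


@dataclass
class StatePosteriors:
    """E-step quantities pooled over the concatenation."""

    gamma: np.ndarray  # (N, K) state probabilities per time point
    xi_sum: np.ndarray  # (K, K) expected transition counts
    loglik: float


@dataclass
class OrderScanResult:
    """Model-order scan: one row per candidate K."""

    table: "object"  # pandas DataFrame: K, loglik, avLL, n_params, BIC, cv_fo
    recommended_K: int
    failures: dict = field(default_factory=dict)


def n_hmm_parameters(K: int, M: int) -> int:
    """Free parameters: (K-1) initial + K(K-1) transition + K*M means +
    K*M(M+1)/2 covariance terms."""
    return (K - 1) + K * (K - 1) + K * M + K * M * (M + 1) // 2


# ---------------------------------------------------------------------------
# emission probabilities


def _log_emissions(X: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Log N(x_t | mu_k, Sigma_k) for every time point and state -> (N, K)."""
    N, M = X.shape
    K = mu.shape[0]
    out = np.empty((N, K))
    for k in range(K):
        L = np.linalg.cholesky(Sigma[k])
        dev = X - mu[k]
        sol = solve_triangular(L, dev.T, lower=True)
        maha = np.einsum("ij,ij->j", sol, sol)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, k] = -0.5 * (M * np.log(2.0 * np.pi) + logdet + maha)
    return out


# ---------------------------------------------------------------------------
# scaled forward-backward, batched across equal-length sequences


def _group_by_length(ranges: list) -> dict:
    groups: dict = {}
    for idx, (start, stop) in enumerate(ranges):
        groups.setdefault(stop - start, []).append(idx)
    return groups


def _fb_batch(logB: np.ndarray, pi: np.ndarray, A: np.ndarray):
    """Scaled forward-backward for a batch of sequences of equal length.

    logB: (n, T, K) emission log-probabilities. Returns per-sequence gamma
    (n, T, K), pooled xi_sum (K, K), per-sequence logliks (n,).
    """
    n, T, K = logB.shape
    c = logB.max(axis=2, keepdims=True)  # per-frame shift against underflow
    b = np.exp(logB - c)

    alpha = np.empty((n, T, K))
    norm = np.empty((n, T))
    a = pi[None, :] * b[:, 0]
    norm[:, 0] = a.sum(axis=1)
    if np.any(norm[:, 0] <= 0) or not np.all(np.isfinite(norm[:, 0])):
        raise FloatingPointError("zero or non-finite likelihood at sequence start")
    alpha[:, 0] = a / norm[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * b[:, t]
        norm[:, t] = a.sum(axis=1)
        if np.any(norm[:, t] <= 0) or not np.all(np.isfinite(norm[:, t])):
            raise FloatingPointError(f"zero or non-finite likelihood at frame {t}")
        alpha[:, t] = a / norm[:, t, None]

    beta = np.empty((n, T, K))
    beta[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[:, t] = (b[:, t + 1] * beta[:, t + 1]) @ A.T / norm[:, t + 1, None]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)

    if T > 1:
        P = b[:, 1:] * beta[:, 1:] / norm[:, 1:, None]
        xi_sum = A * np.einsum("nti,ntj->ij", alpha[:, :-1], P)
    else:
        xi_sum = np.zeros((K, K))
    loglik = np.log(norm).sum(axis=1) + c[:, :, 0].sum(axis=1)
    return gamma, xi_sum, loglik


def _e_step(X: np.ndarray, ranges: list, params: HMMParams):
    """Pooled E-step across all subjects (chain restarts at each boundary)."""
    logB = _log_emissions(X, params.mu, params.Sigma)
    N, K = logB.shape
    gamma = np.empty((N, K))
    xi_sum = np.zeros((K, K))
    start_gamma = np.zeros(K)
    total_ll = 0.0
    for T, idxs in _group_by_length(ranges).items():
        batch = np.stack([logB[ranges[i][0]: ranges[i][1]] for i in idxs])
        g, xi, ll = _fb_batch(batch, params.pi, params.A)
        for row, i in enumerate(idxs):
            gamma[ranges[i][0]: ranges[i][1]] = g[row]
        xi_sum += xi
        start_gamma += g[:, 0].sum(axis=0)
        total_ll += ll.sum()
    return StatePosteriors(gamma=gamma, xi_sum=xi_sum, loglik=float(total_ll)), start_gamma


def forward_backward(params: HMMParams, series: np.ndarray):
    """Posterior state probabilities for a single sequence.

    Returns (gamma, xi_sum, loglik); gamma rows sum to 1 and loglik is
    log p(series | params), computed with scaled recursions (no underflow).
    """
    X = np.asarray(series, dtype=float)
    post, _ = _e_step(X, [(0, X.shape[0])], params)
    return post.gamma, post.xi_sum, post.loglik


# ---------------------------------------------------------------------------
# Viterbi


def _viterbi_batch(logB: np.ndarray, log_pi: np.ndarray, log_A: np.ndarray) -> np.ndarray:
    n, T, K = logB.shape
    psi = np.empty((n, T, K), dtype=np.int64)
    delta = log_pi[None, :] + logB[:, 0]
    if np.any(delta.max(axis=1) == -np.inf):
        raise ValueError("zero-probability start: no state can emit the first frame")
    for t in range(1, T):
        cand = delta[:, :, None] + log_A[None, :, :]  # (n, from, to)
        psi[:, t] = cand.argmax(axis=1)  # first max -> lower state index on ties
        delta = cand.max(axis=1) + logB[:, t]
    paths = np.empty((n, T), dtype=np.int64)
    paths[:, T - 1] = delta.argmax(axis=1)
    for t in range(T - 2, -1, -1):
        paths[:, t] = psi[np.arange(n), t + 1, paths[:, t + 1]]
    return paths


def viterbi(params: HMMParams, series: np.ndarray) -> np.ndarray:
    """Most probable state path for one sequence (1-based labels).

    Ties are broken toward the lower state index.
    """
    X = np.asarray(series, dtype=float)
    logB = _log_emissions(X, params.mu, params.Sigma)
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
        log_A = np.log(params.A)
    return _viterbi_batch(logB[None], log_pi, log_A)[0] + 1


def decode_cohort(params: HMMParams, matrix: np.ndarray, ranges: list) -> list:
    """Viterbi paths for every subject range of a concatenated matrix."""
    logB = _log_emissions(matrix, params.mu, params.Sigma)
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
        log_A = np.log(params.A)
    paths = [None] * len(ranges)
    for T, idxs in _group_by_length(ranges).items():
        batch = np.stack([logB[ranges[i][0]: ranges[i][1]] for i in idxs])
        decoded = _viterbi_batch(batch, log_pi, log_A)
        for row, i in enumerate(idxs):
            paths[i] = decoded[row] + 1
    return paths


# ---------------------------------------------------------------------------
# EM


def _kmeans_init(X: np.ndarray, K: int, reg: float, rng: np.random.Generator) -> HMMParams:
    from sklearn.cluster import KMeans

    N, M = X.shape
    sub = X
    if N > 20000:  # k-means init only needs a representative subsample
        sub = X[rng.choice(N, 20000, replace=False)]
    km = KMeans(n_clusters=K, n_init=1, random_state=int(rng.integers(2**31 - 1)))
    labels = km.fit_predict(sub)
    mu = km.cluster_centers_.copy()
    Sigma = np.empty((K, M, M))
    for k in range(K):
        pts = sub[labels == k]
        if pts.shape[0] > M:
            Sigma[k] = np.cov(pts.T) + reg * np.eye(M)
        else:
            Sigma[k] = np.cov(X.T) + reg * np.eye(M)
    A = np.full((K, K), 0.2 / max(K - 1, 1))
    np.fill_diagonal(A, 0.8 if K > 1 else 1.0)
    pi = np.full(K, 1.0 / K)
    return HMMParams(pi=pi, A=A, mu=mu, Sigma=Sigma)


def _m_step(X: np.ndarray, post: StatePosteriors, start_gamma: np.ndarray,
            n_seq: int, reg: float) -> HMMParams:
    gamma = post.gamma
    K = gamma.shape[1]
    M = X.shape[1]
    w = gamma.sum(axis=0)  # (K,)
    pi = start_gamma / n_seq
    pi = pi / pi.sum()
    if K > 1:
        rows = post.xi_sum.sum(axis=1, keepdims=True)
        A = np.where(rows > 0, post.xi_sum / np.where(rows > 0, rows, 1.0),
                     1.0 / K)
    else:
        A = np.ones((1, 1))
    mu = (gamma.T @ X) / w[:, None]
    Sigma = np.empty((K, M, M))
    for k in range(K):
        dev = X - mu[k]
        Sigma[k] = (dev.T * gamma[:, k]) @ dev / w[k] + reg * np.eye(M)
    return HMMParams(pi=pi, A=A, mu=mu, Sigma=Sigma)


def _fit_single(X: np.ndarray, ranges: list, K: int, max_iter: int, tol: float,
                reg: float, rng: np.random.Generator):
    params = _kmeans_init(X, K, reg, rng)
    history = []
    prev = -np.inf
    converged = False
    post = None
    for it in range(max_iter):
        post, start_gamma = _e_step(X, ranges, params)
        if not np.isfinite(post.loglik):
            raise FloatingPointError("non-finite log-likelihood")
        if post.loglik < prev - 1e-8 * max(1.0, abs(prev)):
            logger.warning("log-likelihood decreased at iter %d (%.6g -> %.6g)",
                           it, prev, post.loglik)
        history.append(post.loglik)
        # per-sample tolerance on the log-likelihood improvement
        if it > 0 and (post.loglik - prev) < tol * X.shape[0]:
            converged = True
            break
        prev = post.loglik
        params = _m_step(X, post, start_gamma, len(ranges), reg)
    else:
        post, start_gamma = _e_step(X, ranges, params)
        history.append(post.loglik)
    params.validate()
    return params, post, history, converged


class GaussianHMM:
    """Group-level Gaussian HMM on a temporally concatenated cohort matrix.

    Parameters
    ----------
    endog : (N, M) array
        Concatenated (z-scored) component time courses.
    ranges : list of (start, stop), optional
        Per-subject row ranges; defaults to a single sequence. The chain is
        re-initialised at each range (subjects are independent realisations
        of the same hidden process).
    k_states : int
        Number of hidden states K.
    """

    def __init__(self, endog: np.ndarray, ranges: list | None = None, k_states: int = 6):
        self.endog = np.asarray(endog, dtype=float)
        if self.endog.ndim != 2:
            raise ValueError("endog must be N x M")
        self.ranges = list(ranges) if ranges is not None else [(0, self.endog.shape[0])]
        covered = sum(stop - start for start, stop in self.ranges)
        if covered != self.endog.shape[0]:
            raise ValueError("subject ranges do not tile the concatenated matrix")
        if k_states < 1:
            raise ValueError("k_states must be >= 1")
        self.k_states = int(k_states)

    @classmethod
    def from_concat(cls, concat, k_states: int = 6) -> "GaussianHMM":
        """Build from a :class:`~dynstates.preprocess.ConcatResult`."""
        model = cls(concat.matrix, concat.ranges, k_states)
        model._concat = concat
        return model

    def fit(self, n_restarts: int = 5, max_iter: int = 500, tol: float = 1e-5,
            reg: float = 1e-6, seed: int | None = None) -> "HMMResults":
        """EM with random restarts; the restart with the best final
        log-likelihood wins. ``tol`` is the per-sample log-likelihood
        improvement below which EM stops; ``reg`` is the ridge added to every
        covariance."""
        X, K = self.endog, self.k_states
        N, M = X.shape
        if N <= K * M:
            warnings.warn(f"few samples ({N}) for K*M = {K * M} parameters")
        ss = np.random.SeedSequence(seed)
        best = None
        errors = []
        for r, child in enumerate(ss.spawn(n_restarts)):
            rng = np.random.default_rng(child)
            try:
                fitted = _fit_single(X, self.ranges, K, max_iter, tol, reg, rng)
            except FloatingPointError as exc:
                logger.warning("restart %d aborted: %s", r, exc)
                errors.append(str(exc))
                continue
            if best is None or fitted[1].loglik > best[1].loglik:
                best = fitted
        if best is None:
            raise RuntimeError(f"all {n_restarts} restarts failed: {errors}")
        params, post, history, converged = best
        return HMMResults(model=self, params=params, posteriors=post,
                          history=history, converged=converged,
                          n_restarts=n_restarts, seed=seed)


@dataclass
class HMMResults:
    """Fitted HMM: parameters, posteriors and decoding utilities."""

    model: GaussianHMM
    params: HMMParams
    posteriors: StatePosteriors
    history: list
    converged: bool
    n_restarts: int
    seed: int | None

    @property
    def loglik(self) -> float:
        return self.posteriors.loglik

    @property
    def k_states(self) -> int:
        return self.params.K

    @property
    def n_obs(self) -> int:
        return self.model.endog.shape[0]

    @property
    def avLL(self) -> float:
        """Average log-likelihood per time point."""
        return self.loglik / self.n_obs

    @property
    def bic(self) -> float:
        p = n_hmm_parameters(self.params.K, self.params.M)
        return -2.0 * self.loglik + p * np.log(self.n_obs)

    def viterbi_paths(self) -> list:
        """Per-subject most probable state paths (1-based labels)."""
        return decode_cohort(self.params, self.model.endog, self.model.ranges)

    def state_correlation_matrix(self, k: int) -> np.ndarray:
        """Correlation matrix of state k (1-based)."""
        return state_correlation_matrix(self.params, k)

    def state_correlations(self) -> np.ndarray:
        return np.stack([self.state_correlation_matrix(k)
                         for k in range(1, self.params.K + 1)])

    def fractional_occupancy(self, from_gamma: bool = False) -> np.ndarray:
        """(n_subjects, K) occupancy fractions, from Viterbi paths (default)
        or posterior column means."""
        K = self.params.K
        if from_gamma:
            return np.stack([
                self.posteriors.gamma[start:stop].mean(axis=0)
                for start, stop in self.model.ranges
            ])
        from .dynamics import fractional_occupancy
        return np.stack([fractional_occupancy(p, K) for p in self.viterbi_paths()])

    def summary(self) -> str:
        lines = [
            "Gaussian HMM results",
            "====================",
            f"states (K):        {self.params.K}",
            f"components (M):    {self.params.M}",
            f"observations (N):  {self.n_obs}",
            f"subjects:          {len(self.model.ranges)}",
            f"log-likelihood:    {self.loglik:.2f}",
            f"avLL per frame:    {self.avLL:.4f}",
            f"BIC:               {self.bic:.2f}",
            f"EM converged:      {self.converged} ({len(self.history)} iterations,"
            f" {self.n_restarts} restarts)",
            "",
            "pooled fractional occupancy (posterior):",
        ]
        fo = self.posteriors.gamma.mean(axis=0)
        lines.append("  " + "  ".join(f"S{k + 1}:{fo[k]:.3f}" for k in range(self.params.K)))
        lines.append("")
        lines.append("transition matrix:")
        for row in self.params.A:
            lines.append("  " + " ".join(f"{v:6.3f}" for v in row))
        return "\n".join(lines)


def fit_hmm(concat: np.ndarray, subject_ranges: list, K: int, n_restarts: int = 5,
            max_iter: int = 500, tol: float = 1e-5, reg: float = 1e-6,
            seed: int | None = None) -> HMMResults:
    """Functional wrapper: fit a K-state model to a concatenated matrix."""
    return GaussianHMM(concat, subject_ranges, K).fit(
        n_restarts=n_restarts, max_iter=max_iter, tol=tol, reg=reg, seed=seed)


def select_model_order(concat: np.ndarray, subject_ranges: list,
                       K_range=range(2, 16), n_restarts: int = 3,
                       max_iter: int = 200, tol: float = 1e-5, reg: float = 1e-6,
                       seed: int | None = None) -> OrderScanResult:
    """Scan candidate state counts and report goodness-of-fit indices.

    For every K the model is refitted ``n_restarts`` times; the table holds
    the best restart's log-likelihood, avLL and BIC, plus the coefficient of
    variation (across restarts) of the pooled, rank-sorted occupancy
    estimates — a precision index for the state decomposition. The
    recommended K minimises BIC; the other indices are reported so the final
    choice can weigh fit quality against estimate stability.
    """
    import pandas as pd

    K_range = list(K_range)
    if not K_range:
        raise ValueError("empty K range")
    X = np.asarray(concat, dtype=float)
    N, M = X.shape
    rows = []
    failures = {}
    ss = np.random.SeedSequence(seed)
    for K, child in zip(K_range, ss.spawn(len(K_range))):
        restart_ll, restart_fo = [], []
        best = None
        for sub in child.spawn(n_restarts):
            rng = np.random.default_rng(sub)
            try:
                params, post, history, conv = _fit_single(X, subject_ranges, K,
                                                          max_iter, tol, reg, rng)
            except FloatingPointError as exc:
                logger.warning("K=%d restart failed: %s", K, exc)
                continue
            restart_ll.append(post.loglik)
            fo = np.sort(post.gamma.mean(axis=0))[::-1]
            restart_fo.append(fo)
            if best is None or post.loglik > best[1].loglik:
                best = (params, post)
        if best is None:
            failures[K] = "all restarts failed"
            continue
        ll = best[1].loglik
        fo_mat = np.stack(restart_fo)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.nanmean(np.where(fo_mat.mean(0) > 0,
                                     fo_mat.std(0) / fo_mat.mean(0), np.nan))
        p = n_hmm_parameters(K, M)
        rows.append({"K": K, "loglik": ll, "avLL": ll / N, "n_params": p,
                     "BIC": -2.0 * ll + p * np.log(N), "cv_fo": float(cv)})
    if not rows:
        raise RuntimeError("model-order scan failed for every K")
    table = pd.DataFrame(rows)
    recommended = int(table.loc[table["BIC"].idxmin(), "K"])
    return OrderScanResult(table=table, recommended_K=recommended, failures=failures)


def state_correlation_matrix(params: HMMParams, k: int) -> np.ndarray:
    """Correlation matrix R = D^{-1/2} Sigma_k D^{-1/2} of state k (1-based)."""
    if not 1 <= k <= params.K:
        raise ValueError(f"state {k} outside 1..{params.K}")
    S = params.Sigma[k - 1]
    d = np.diag(S)
    if np.any(d <= 0):
        raise ValueError("zero variance channel in state covariance")
    inv = 1.0 / np.sqrt(d)
    R = S * inv[:, None] * inv[None, :]
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R


def permute_states(params: HMMParams, perm) -> HMMParams:
    """Relabel states: new state i is old state perm[i] (0-based)."""
    perm = np.asarray(perm)
    return HMMParams(pi=params.pi[perm], A=params.A[np.ix_(perm, perm)],
                     mu=params.mu[perm], Sigma=params.Sigma[perm])


def match_states(params: HMMParams, reference: HMMParams) -> np.ndarray:
    """Hungarian matching of states to a reference model.

    Cost is the Frobenius distance between state correlation matrices plus
    the Euclidean distance between state means (which decides ties when
    correlation structures coincide). Returns perm such that
    ``permute_states(params, perm)`` aligns with the reference labelling.
    """
    if params.K != reference.K:
        raise ValueError("state counts differ")
    K = params.K
    Ra = [state_correlation_matrix(params, k) for k in range(1, K + 1)]
    Rb = [state_correlation_matrix(reference, k) for k in range(1, K + 1)]
    cost = np.array([[np.linalg.norm(Rb[i] - Ra[j])
                      + np.linalg.norm(reference.mu[i] - params.mu[j])
                      for j in range(K)] for i in range(K)])
    _, cols = linear_sum_assignment(cost)
    return cols
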