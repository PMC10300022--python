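"""Weighted graph metrics, signed Louvain consensus modularity, and partition
similarity on sparsified state FC matrices.

Path-based metrics (betweenness, efficiencies) and triangle-based metrics
(clustering) run on absolute edge weights rescaled to a maximum of 1, with
lengths L_ij = 1 / w_ij; modularity uses the signed asymmetric quality
function in which positive weights are rewarded fully and negative weights
penalised with a smaller normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from scipy.sparse.csgraph import shortest_path

from .dynamics import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "GraphMetrics",
    "Partition",
    "graph_metrics",
    "modularity_signed",
    "louvain_partition",
    "louvain_consensus",
    "jaccard_partition_similarity",
    "compare_state_metrics",
]

NODAL_METRICS = ("degree", "strength", "betweenness", "clustering", "local_efficiency")


@dataclass
class GraphMetrics:
    """Nodal and global metrics of one (sparsified) weighted graph."""

    degree: np.ndarray  # binary degree
    strength: np.ndarray  # sum of |w|
    betweenness: np.ndarray  # weighted shortest-path betweenness (raw counts)
    clustering: np.ndarray  # Onnela geometric-mean weighted clustering
    local_efficiency: np.ndarray  # efficiency of each node's neighbourhood
    global_efficiency: float
    isolated: np.ndarray  # flags for zero-degree nodes
    labels: list = field(default_factory=list)
    state: int = 0

    def nodal(self, name: str) -> np.ndarray:
        if name not in NODAL_METRICS:
            raise KeyError(name)
        return getattr(self, name)


def _efficiency(W_hat: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs; lengths are
    1 / w on absolute weights <= 1, unreachable pairs contribute 0."""
    n = W_hat.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        L = np.where(W_hat > 0, 1.0 / W_hat, np.inf)
    np.fill_diagonal(L, 0.0)
    D = shortest_path(L, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    return float(inv[off].mean())


def graph_metrics(W: np.ndarray, labels=None, state: int = 0) -> GraphMetrics:
    """Centrality, segregation and integration metrics of a weighted graph.

    ``W`` is a symmetric, zero-diagonal (sparsified) matrix; computations use
    |W| rescaled so the largest weight is 1. Isolated nodes get zero for all
    metrics and are flagged.
    """
    W = np.asarray(W, dtype=float)
    M = W.shape[0]
    if W.ndim != 2 or W.shape[1] != M:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    if np.any(np.diag(W) != 0):
        raise ValueError("W must have a zero diagonal")

    A = np.abs(W)
    wmax = A.max()
    W_hat = A / wmax if wmax > 0 else A

    degree = (W_hat > 0).sum(axis=1).astype(float)
    strength = W_hat.sum(axis=1)
    isolated = degree == 0
    if isolated.any():
        logger.warning("%d isolated node(s); their metrics are 0", isolated.sum())

    G = nx.from_numpy_array(W_hat)
    for _, _, d in G.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    btw_dict = nx.betweenness_centrality(G, weight="length", normalized=False)
    betweenness = np.array([btw_dict[i] for i in range(M)])
    clus_dict = nx.clustering(G, weight="weight")
    clustering = np.array([clus_dict[i] for i in range(M)])

    local_eff = np.zeros(M)
    for i in range(M):
        nbrs = np.flatnonzero(W_hat[i] > 0)
        if nbrs.size >= 2:
            local_eff[i] = _efficiency(W_hat[np.ix_(nbrs, nbrs)])

    return GraphMetrics(
        degree=degree, strength=strength, betweenness=betweenness,
        clustering=clustering, local_efficiency=local_eff,
        global_efficiency=_efficiency(W_hat), isolated=isolated,
        labels=list(labels) if labels is not None else [], state=state,
    )


# ---------------------------------------------------------------------------
# signed Louvain + consensus


@dataclass
class Partition:
    """Node -> module assignment with signed modularity."""

    labels: np.ndarray  # 1-based, contiguous
    Q: float  # signed modularity of this partition on the original graph
    mean_Q: float  # mean Q across the randomized runs (reported value)
    n_modules: int
    co_assignment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
            raise ValueError("module labels must be contiguous from 1")


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Contiguous 1-based labels in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict = {}
    for i, lab in enumerate(labels):
        out[i] = mapping.setdefault(lab, len(mapping) + 1)
    return out


def modularity_signed(W: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Signed modularity Q = Q+/v+ - Q-/(v+ + v-).

    Q_s = sum over within-module pairs of (w_s - gamma * s_i s_j / v_s) for
    each sign s, with v_s the total (ordered-pair) weight of that sign.
    """
    W = np.asarray(W, dtype=float)
    labels = np.asarray(labels)
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    delta = labels[:, None] == labels[None, :]
    q = 0.0
    vp = Wp.sum()
    vn = Wn.sum()
    if vp > 0:
        sp = Wp.sum(axis=1)
        Ep = gamma * np.outer(sp, sp) / vp
        q += ((Wp - Ep) * delta).sum() / vp
    if vn > 0:
        sn = Wn.sum(axis=1)
        En = gamma * np.outer(sn, sn) / vn
        q -= ((Wn - En) * delta).sum() / (vp + vn)
    return float(q)


def _louvain_level(Wp, Wn, vp, vn, gamma, rng):
    """One Louvain level: greedy local moves on the signed gain until stable.

    Self-loops (from aggregation) are constant under moves and ignored.
    """
    n = Wp.shape[0]
    labels = np.arange(n)
    sp = Wp.sum(axis=1)
    sn = Wn.sum(axis=1)
    Sp = sp.copy()  # per-community positive strength sums
    Sn = sn.copy()
    improved_any = False
    for _ in range(100):
        moved = False
        for i in rng.permutation(n):
            a = labels[i]
            Sp[a] -= sp[i]
            Sn[a] -= sn[i]
            labels[i] = -1
            # candidate communities: neighbours' plus the old one
            nbr = np.flatnonzero((Wp[i] > 0) | (Wn[i] > 0))
            cands = set(labels[nbr][labels[nbr] >= 0].tolist())
            cands.add(a)
            best_c, best_gain = a, -np.inf
            for c in sorted(cands):
                members = labels == c
                kp = Wp[i, members].sum()
                kn = Wn[i, members].sum()
                gain = 0.0
                if vp > 0:
                    gain += (kp - gamma * sp[i] * Sp[c] / vp) / vp
                if vn > 0:
                    gain -= (kn - gamma * sn[i] * Sn[c] / vn) / (vp + vn)
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            labels[i] = best_c
            Sp[best_c] += sp[i]
            Sn[best_c] += sn[i]
            if best_c != a:
                moved = True
                improved_any = True
        if not moved:
            break
    return _relabel(labels) - 1, improved_any


def louvain_partition(W: np.ndarray, gamma: float = 1.0,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Single randomized Louvain run on a signed matrix (0-based labels)."""
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    rng = rng or np.random.default_rng()
    n = W.shape[0]
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    np.fill_diagonal(Wp, 0.0)
    np.fill_diagonal(Wn, 0.0)
    vp, vn = Wp.sum(), Wn.sum()
    full = np.arange(n)
    while True:
        labels, improved = _louvain_level(Wp, Wn, vp, vn, gamma, rng)
        full = labels[full]
        k = labels.max() + 1
        if not improved or k == Wp.shape[0]:
            break
        # aggregate communities into super-nodes (self-loops kept: they are
        # constant under later moves)
        C = np.zeros((Wp.shape[0], k))
        C[np.arange(Wp.shape[0]), labels] = 1.0
        Wp = C.T @ Wp @ C
        Wn = C.T @ Wn @ C
    return full


def louvain_consensus(W: np.ndarray, gamma: float = 1.0, n_runs: int = 100,
                      tau: float = 0.5, seed: int | None = None,
                      max_consensus_iter: int = 50) -> Partition:
    """Consensus community detection: repeat randomized Louvain runs, build
    the module co-assignment (agreement) matrix, threshold it at ``tau`` and
    re-cluster until all runs agree.

    ``mean_Q`` is the mean signed modularity across the initial randomized
    runs (the value reported when summarising a state); ``Q`` is the
    consensus partition's own modularity on the original matrix.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    ss = np.random.SeedSequence(seed)

    def run_batch(mat, children):
        parts = [louvain_partition(mat, gamma, np.random.default_rng(c))
                 for c in children]
        agree = np.zeros((n, n))
        for p in parts:
            agree += p[:, None] == p[None, :]
        return parts, agree / len(parts)

    parts, agree = run_batch(W, ss.spawn(n_runs))
    mean_Q = float(np.mean([modularity_signed(W, p, gamma) for p in parts]))

    mat = agree
    for _ in range(max_consensus_iter):
        if all(np.array_equal(_relabel(p), _relabel(parts[0])) for p in parts):
            labels = _relabel(parts[0])
            return Partition(labels=labels,
                             Q=modularity_signed(W, labels, gamma),
                             mean_Q=mean_Q, n_modules=int(labels.max()),
                             co_assignment=agree)
        thr = np.where(mat >= tau, mat, 0.0)
        np.fill_diagonal(thr, 0.0)
        if thr.sum() == 0:  # nothing survives: all singletons
            labels = np.arange(1, n + 1)
            return Partition(labels=labels, Q=modularity_signed(W, labels, gamma),
                             mean_Q=mean_Q, n_modules=n, co_assignment=agree)
        parts, mat = run_batch(thr, ss.spawn(n_runs))
    raise RuntimeError(f"consensus did not converge in {max_consensus_iter} iterations")


def jaccard_partition_similarity(p1, p2) -> float:
    """Jaccard overlap of co-assigned node pairs between two partitions."""
    l1 = np.asarray(p1.labels if isinstance(p1, Partition) else p1)
    l2 = np.asarray(p2.labels if isinstance(p2, Partition) else p2)
    if l1.shape != l2.shape:
        raise ValueError("partitions cover different node sets")
    iu = np.triu_indices(l1.size, k=1)
    e1 = (l1[:, None] == l1[None, :])[iu]
    e2 = (l2[:, None] == l2[None, :])[iu]
    union = (e1 | e2).sum()
    if union == 0:
        logger.warning("both partitions are all singletons; Jaccard defined as 0")
        return 0.0
    return float((e1 & e2).sum() / union)


def _paired_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def compare_state_metrics(metrics: list, alpha: float = 0.01,
                          which=("degree", "betweenness", "clustering",
                                 "local_efficiency")):
    """Pairwise between-state comparison of nodal graph metrics.

    Nodes are the same set in every state, so the tests are paired per node
    (Wilcoxon signed-rank); BH-FDR across the whole metric x state-pair
    family. Returns a pandas DataFrame.
    """
    import pandas as pd

    if len(metrics) < 2:
        raise ValueError("need at least two states")
    n_nodes = metrics[0].degree.size
    if n_nodes < 6:
        logger.warning("fewer than 6 nodes: exact signed-rank p-values infeasible")
    rows = []
    for name in which:
        for a in range(len(metrics)):
            for b in range(a + 1, len(metrics)):
                xa = metrics[a].nodal(name)
                xb = metrics[b].nodal(name)
                stat, p = _paired_signed_rank(xa, xb)
                rows.append({
                    "metric": name,
                    "state_a": metrics[a].state or a + 1,
                    "state_b": metrics[b].state or b + 1,
                    "median_a": float(np.median(xa)),
                    "median_b": float(np.median(xb)),
                    "statistic": stat,
                    "p_raw": p,
                })
    table = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(table["p_raw"].to_numpy(), alpha)
    table["p_fdr"] = p_adj
    table["reject"] = reject
    return table
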