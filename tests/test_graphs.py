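"""Graph metrics against exhaustive-path oracles; signed Louvain against
exhaustive partition search; Jaccard; paired between-state tests."""

import itertools

import numpy as np
import pytest

from dynstates import (compare_state_metrics, graph_metrics,
                       jaccard_partition_similarity, louvain_consensus,
                       modularity_signed)


# ---------------------------------------------------------------------------
# brute-force oracles (exhaustive enumeration; independent of the package)


def brute_shortest(W_hat, s, t):
    """All simple paths s->t; returns (min length, list of optimal paths)."""
    n = W_hat.shape[0]
    best, paths = np.inf, []
    nodes = [v for v in range(n) if v not in (s, t)]
    for r in range(len(nodes) + 1):
        for mid in itertools.permutations(nodes, r):
            seq = (s, *mid, t)
            length = 0.0
            ok = True
            for a, b in zip(seq[:-1], seq[1:]):
                if W_hat[a, b] <= 0:
                    ok = False
                    break
                length += 1.0 / W_hat[a, b]
            if not ok:
                continue
            if length < best - 1e-12:
                best, paths = length, [seq]
            elif abs(length - best) <= 1e-12:
                paths.append(seq)
    return best, paths


def brute_betweenness_and_efficiency(W_hat):
    n = W_hat.shape[0]
    btw = np.zeros(n)
    inv_sum = 0.0
    for s in range(n):
        for t in range(n):
            if s >= t:
                continue
            d, paths = brute_shortest(W_hat, s, t)
            if np.isfinite(d):
                inv_sum += 2.0 / d  # both ordered pairs
                for v in range(n):
                    if v in (s, t):
                        continue
                    frac = sum(1 for p in paths if v in p) / len(paths)
                    btw[v] += frac
    geff = inv_sum / (n * (n - 1))
    return btw, geff


def all_partitions(nodes):
    """Every set partition (restricted-growth enumeration)."""
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for smaller in all_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


# ---------------------------------------------------------------------------


class TestGraphMetrics:
    def test_unit_triangle(self):
        W = np.ones((3, 3)) - np.eye(3)
        m = graph_metrics(W)
        np.testing.assert_allclose(m.clustering, 1.0)
        assert m.global_efficiency == pytest.approx(1.0)
        np.testing.assert_allclose(m.betweenness, 0.0)
        np.testing.assert_allclose(m.degree, 2.0)

    def test_three_node_path(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
        m = graph_metrics(W)
        np.testing.assert_allclose(m.betweenness, [0.0, 1.0, 0.0])
        # pairs: (0,1)=1, (1,2)=1, (0,2)=2 -> (2*1 + 1*0.5)/3
        assert m.global_efficiency == pytest.approx(5 / 6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_small_weighted_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        W = rng.uniform(0.2, 1.0, size=(n, n))
        W = (W + W.T) / 2
        W[rng.random((n, n)) < 0.35] = 0.0  # sparsify asymmetrically...
        W = np.minimum(W, W.T)  # ...then re-symmetrise
        np.fill_diagonal(W, 0.0)
        m = graph_metrics(W)
        W_hat = np.abs(W) / np.abs(W).max()
        btw, geff = brute_betweenness_and_efficiency(W_hat)
        np.testing.assert_allclose(m.betweenness, btw, atol=1e-8)
        assert m.global_efficiency == pytest.approx(geff, abs=1e-10)

    def test_isolated_node_zeroed_and_flagged(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        m = graph_metrics(W)
        assert m.isolated[3]
        assert m.degree[3] == m.strength[3] == m.local_efficiency[3] == 0.0

    def test_efficiency_monotone_under_edge_addition(self):
        W = np.zeros((5, 5))
        for i in range(4):
            W[i, i + 1] = W[i + 1, i] = 1.0
        base = graph_metrics(W).global_efficiency
        W2 = W.copy()
        W2[0, 4] = W2[4, 0] = 1.0
        assert graph_metrics(W2).global_efficiency > base


class TestLouvain:
    def test_two_cliques_match_exhaustive_optimum(self):
        W = np.zeros((8, 8))
        W[:4, :4] = 1.0
        W[4:, 4:] = 1.0
        np.fill_diagonal(W, 0.0)
        best_q, best_part = -np.inf, None
        for part in all_partitions(list(range(8))):
            labels = np.empty(8, dtype=int)
            for i, block in enumerate(part):
                labels[block] = i
            q = modularity_signed(W, labels)
            if q > best_q:
                best_q, best_part = q, labels.copy()
        assert best_q == pytest.approx(0.5)
        res = louvain_consensus(W, n_runs=20, seed=0)
        assert res.Q == pytest.approx(best_q, abs=1e-12)
        # same grouping as the exhaustive optimum
        assert jaccard_partition_similarity(res.labels, best_part + 1) == 1.0

    def test_single_clique_one_module_q_zero(self):
        W = np.ones((5, 5)) - np.eye(5)
        res = louvain_consensus(W, n_runs=10, seed=1)
        assert res.n_modules == 1
        assert res.Q == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        W = rng.uniform(-0.2, 1.0, size=(12, 12))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        r1 = louvain_consensus(W, n_runs=15, seed=42)
        r2 = louvain_consensus(W, n_runs=15, seed=42)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        assert r1.mean_Q == r2.mean_Q

    def test_signed_blocks_with_negative_bridges(self):
        # two positive blocks joined by negative edges: negatives repel
        W = np.zeros((8, 8))
        W[:4, :4] = 0.8
        W[4:, 4:] = 0.8
        W[:4, 4:] = -0.3
        W[4:, :4] = -0.3
        np.fill_diagonal(W, 0.0)
        res = louvain_consensus(W, n_runs=10, seed=2)
        assert res.n_modules == 2
        assert len(set(res.labels[:4])) == 1
        assert len(set(res.labels[4:])) == 1

    def test_consensus_stable_across_seeds_on_separated_blocks(self):
        W = np.zeros((12, 12))
        for a in range(0, 12, 4):
            W[a:a + 4, a:a + 4] = 1.0
        np.fill_diagonal(W, 0.0)
        parts = [louvain_consensus(W, n_runs=10, seed=s).labels for s in range(5)]
        for p in parts[1:]:
            assert jaccard_partition_similarity(parts[0], p) == 1.0


class TestJaccard:
    def test_identical_partitions(self):
        assert jaccard_partition_similarity([1, 1, 2, 2], [2, 2, 1, 1]) == 1.0

    def test_singletons_vs_one_module(self):
        assert jaccard_partition_similarity([1, 2, 3, 4], [1, 1, 1, 1]) == 0.0

    def test_enumerated_example(self):
        # E1 = {(1,2),(3,4)}, E2 = {(1,2),(1,3),(2,3)} -> 1/4
        assert jaccard_partition_similarity([1, 1, 2, 2], [1, 1, 1, 2]) == 0.25

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError):
            jaccard_partition_similarity([1, 2], [1, 2, 3])


class TestCompareStateMetrics:
    def _metrics(self, W, state):
        return graph_metrics(W, state=state)

    def test_identical_states_p_one(self, rng):
        W = rng.uniform(0.1, 1.0, size=(10, 10))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        t = compare_state_metrics([self._metrics(W, 1), self._metrics(W, 2)])
        assert (t["p_raw"] == 1.0).all()
        assert not t["reject"].any()

    def test_node_permutation_invariance(self, rng):
        A = rng.uniform(0.1, 1.0, size=(12, 12))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        B = A * rng.uniform(0.3, 0.9)
        B[0, 1] = B[1, 0] = 0.95
        perm = rng.permutation(12)
        t1 = compare_state_metrics([self._metrics(A, 1), self._metrics(B, 2)])
        t2 = compare_state_metrics([self._metrics(A[np.ix_(perm, perm)], 1),
                                    self._metrics(B[np.ix_(perm, perm)], 2)])
        np.testing.assert_allclose(t1["p_raw"], t2["p_raw"], atol=1e-12)
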