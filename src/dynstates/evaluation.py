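"""Ground-truth evaluation helpers: state matching against a generating
model, decoding accuracy, occupancy recovery, and the discrimination
replicate used to gauge statistical power of the group comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import cohort_dynamics, compare_groups, fractional_occupancy
from .fc import compare_state_edges, sparsify_proportional
from .graphs import compare_state_metrics, graph_metrics
from .hmm import (GaussianHMM, HMMParams, HMMResults, match_states,
                  permute_states, state_correlation_matrix)
from .preprocess import zscore_and_concat
from .simulate import CONTROL, PATIENT, GroundTruth, SimConfig, simulate_cohort

__all__ = ["RecoveryReport", "evaluate_recovery", "fit_cohort",
           "DiscriminationReport", "discrimination_replicate"]


def _truth_params(gt: GroundTruth) -> HMMParams:
    return HMMParams(pi=gt.pi[CONTROL], A=gt.A[CONTROL], mu=gt.mu, Sigma=gt.Sigma)


def fit_cohort(config: SimConfig, n_restarts: int = 2, max_iter: int = 80,
               tol: float = 1e-4, seed: int | None = None):
    """Simulate a cohort, z-score/concatenate and fit a K-state model.

    Returns (subjects, ground truth, concat, results aligned to nothing —
    matching is the caller's job)."""
    subjects, gt = simulate_cohort(config)
    concat = zscore_and_concat(subjects)
    res = GaussianHMM.from_concat(concat, gt.K).fit(
        n_restarts=n_restarts, max_iter=max_iter, tol=tol, seed=seed)
    return subjects, gt, concat, res


@dataclass
class RecoveryReport:
    """How well the fit recovers the generating model."""

    fo_correlation_mean: float  # per-subject corr(decoded FO, true FO)
    fo_correlation_min: float
    frame_accuracy_mean: float  # Viterbi vs true path, after matching
    frame_accuracy_min: float
    transition_max_abs_error: float  # fitted A vs visiting group's chain
    permutation: np.ndarray


def evaluate_recovery(subjects, gt: GroundTruth, res: HMMResults) -> RecoveryReport:
    """Hungarian-match fitted states to the ground truth, then score
    decoding accuracy, per-subject occupancy recovery and the fitted
    transition matrix.

    The fitted (single, group-level) transition matrix is compared row-wise
    against the chain of the group that actually occupies each state:
    healthy-state rows against the control chain, pathological rows against
    the patient chain.
    """
    K = gt.K
    perm = match_states(res.params, _truth_params(gt))
    aligned = permute_states(res.params, perm)
    inv = np.empty(K, dtype=int)
    inv[perm] = np.arange(K)

    acc, fo_corr = [], []
    for sub, path in zip(subjects, res.viterbi_paths()):
        relabeled = inv[path - 1] + 1
        acc.append(float((relabeled == sub.true_path).mean()))
        fo_d = fractional_occupancy(relabeled, K)
        fo_t = fractional_occupancy(sub.true_path, K)
        fo_corr.append(float(np.corrcoef(fo_d, fo_t)[0, 1]))

    A_truth = gt.A[CONTROL].copy()
    patho = [s - 1 for s in gt.pathological_states]
    A_truth[patho] = gt.A[PATIENT][patho]
    a_err = float(np.abs(aligned.A - A_truth).max())

    return RecoveryReport(
        fo_correlation_mean=float(np.mean(fo_corr)),
        fo_correlation_min=float(np.min(fo_corr)),
        frame_accuracy_mean=float(np.mean(acc)),
        frame_accuracy_min=float(np.min(acc)),
        transition_max_abs_error=a_err,
        permutation=perm,
    )


@dataclass
class DiscriminationReport:
    """Rejection outcomes of one discrimination replicate (True = the
    comparison rejected in the planted direction's favour)."""

    fo: dict  # pathological state -> rejected
    edges: dict  # (healthy, pathological) pair -> rejected
    clustering: dict
    local_efficiency: dict


def discrimination_replicate(config: SimConfig, seed: int,
                             alpha_fo: float = 0.01, alpha_edge: float = 0.05,
                             alpha_graph: float = 0.01,
                             sparsity: float = 0.80,
                             n_restarts: int = 2, max_iter: int = 80,
                             tol: float = 1e-4) -> DiscriminationReport:
    """One full pipeline replicate for power estimation: simulate, fit,
    decode, then run the FO group tests, edge-strength comparison and
    segregation (clustering / local efficiency) comparisons between every
    healthy-pathological state pair."""
    from dataclasses import replace

    cfg = replace(config, seed=seed)
    subjects, gt, concat, res = fit_cohort(cfg, n_restarts=n_restarts,
                                           max_iter=max_iter, tol=tol, seed=seed)
    K = gt.K
    perm = match_states(res.params, _truth_params(gt))
    aligned = permute_states(res.params, perm)
    inv = np.empty(K, dtype=int)
    inv[perm] = np.arange(K)
    paths = [inv[p - 1] + 1 for p in res.viterbi_paths()]

    mets = cohort_dynamics(paths, K, cfg.TR, groups=concat.groups)
    table = compare_groups(mets, alpha=alpha_fo).set_index("metric")
    fo = {s: bool(table.loc[f"FO_S{s}", "reject"]) for s in gt.pathological_states}

    states = [sparsify_proportional(state_correlation_matrix(aligned, k),
                                    sparsity, state=k) for k in range(1, K + 1)]
    et = compare_state_edges(states, alpha=alpha_edge).set_index(
        ["state_a", "state_b"])
    gms = [graph_metrics(s.R, state=s.state) for s in states]
    gtab = compare_state_metrics(gms, alpha=alpha_graph).set_index(
        ["metric", "state_a", "state_b"])

    pairs = [(h, p) for h in gt.healthy_states for p in gt.pathological_states]
    edges = {pair: bool(et.loc[pair, "reject"]) for pair in pairs}
    clustering = {pair: bool(gtab.loc[("clustering",) + pair, "reject"])
                  for pair in pairs}
    local_eff = {pair: bool(gtab.loc[("local_efficiency",) + pair, "reject"])
                 for pair in pairs}
    return DiscriminationReport(fo=fo, edges=edges, clustering=clustering,
                                local_efficiency=local_eff)
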