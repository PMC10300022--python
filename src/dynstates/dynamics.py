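"""Temporal state metrics from decoded paths and their group comparison.

Fractional occupancy (fraction of volumes spent in each state), switching
rate (state changes per second), per-subject empirical transition matrices
and maximum-occupancy state assignment, with unpaired rank-sum group tests
under Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DynamicsMetrics",
    "fractional_occupancy",
    "switching_rate",
    "subject_transition_matrix",
    "assign_max_fo_state",
    "rank_sum_test",
    "bh_fdr",
    "compare_groups",
    "cohort_dynamics",
    "pooled_transition_matrix",
]


@dataclass
class DynamicsMetrics:
    """Per-subject temporal metrics."""

    subject_id: str
    group: str
    FO: np.ndarray  # (K,) fractions, sum 1
    SR: float  # Hz
    T_emp: np.ndarray  # (K, K) empirical transitions, zero rows flagged
    unvisited: np.ndarray  # bool mask of never-visited states
    max_fo_state: int  # 1-based


def fractional_occupancy(path: np.ndarray, K: int) -> np.ndarray:
    """FO_k = #(s_t == k) / T for 1-based state labels."""
    path = np.asarray(path)
    if path.size == 0:
        raise ValueError("empty path")
    if path.min() < 1 or path.max() > K:
        raise ValueError(f"state labels outside 1..{K}")
    return np.bincount(path - 1, minlength=K) / path.size


def switching_rate(path: np.ndarray, TR: float) -> float:
    """State changes per second: #(s_t != s_{t-1}) / ((T-1) * TR)."""
    path = np.asarray(path)
    if path.size < 2:
        raise ValueError("need at least two time points")
    if TR <= 0:
        raise ValueError("TR must be positive")
    return float((path[1:] != path[:-1]).sum() / ((path.size - 1) * TR))


def subject_transition_matrix(path: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalised transition counts; never-visited states keep an all-zero
    row and are flagged (so downstream averages can mask them).

    Returns (T_emp, unvisited_mask).
    """
    path = np.asarray(path)
    if path.size < 2:
        raise ValueError("need at least two time points")
    counts = np.zeros((K, K))
    np.add.at(counts, (path[:-1] - 1, path[1:] - 1), 1.0)
    rows = counts.sum(axis=1)
    T_emp = np.divide(counts, rows[:, None], out=np.zeros_like(counts),
                      where=rows[:, None] > 0)
    return T_emp, rows == 0


def assign_max_fo_state(FO: np.ndarray) -> int:
    """1-based argmax of occupancy; ties go to the lower state index."""
    FO = np.asarray(FO, dtype=float)
    best = int(np.argmax(FO))
    if (FO == FO[best]).sum() > 1:
        logger.warning("tied maximum occupancy; assigning the lower state index")
    return best + 1


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test.

    Exact p by enumeration for small samples without ties (n_x + n_y <= 12),
    otherwise the normal approximation with tie and continuity corrections.
    Identical pooled samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject mask, adjusted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    from statsmodels.stats.multitest import multipletests
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def cohort_dynamics(paths: list, K: int, TR: float, subject_ids=None,
                    groups=None) -> list:
    """DynamicsMetrics for every decoded subject path."""
    out = []
    for i, path in enumerate(paths):
        fo = fractional_occupancy(path, K)
        T_emp, unvisited = subject_transition_matrix(path, K)
        out.append(DynamicsMetrics(
            subject_id=subject_ids[i] if subject_ids else f"sub-{i:03d}",
            group=groups[i] if groups else "",
            FO=fo,
            SR=switching_rate(path, TR),
            T_emp=T_emp,
            unvisited=unvisited,
            max_fo_state=assign_max_fo_state(fo),
        ))
    return out


def pooled_transition_matrix(paths: list, K: int, average_subjects: bool = False) -> np.ndarray:
    """Group-level transition matrix: pooled counts (default) or the mean of
    per-subject matrices (unvisited rows masked)."""
    if average_subjects:
        mats, masks = zip(*(subject_transition_matrix(p, K) for p in paths))
        stack = np.stack(mats)
        visited = ~np.stack(masks)
        with np.errstate(invalid="ignore"):
            out = np.where(visited.sum(axis=0)[:, None] > 0,
                           stack.sum(axis=0) / np.maximum(visited.sum(axis=0)[:, None], 1),
                           0.0)
        return out
    counts = np.zeros((K, K))
    for p in paths:
        p = np.asarray(p)
        np.add.at(counts, (p[:-1] - 1, p[1:] - 1), 1.0)
    rows = counts.sum(axis=1)
    return np.divide(counts, rows[:, None], out=np.zeros_like(counts),
                     where=rows[:, None] > 0)


def compare_groups(metrics: list, labels=None, alpha: float = 0.01):
    """Group comparison of FO (per state) and SR.

    One unpaired rank-sum test per state for FO plus one for SR;
    Benjamini-Hochberg correction across the whole family. Returns a pandas
    DataFrame with medians, raw and adjusted p-values and rejection flags.
    """
    import pandas as pd

    if labels is None:
        labels = [m.group for m in metrics]
    labels = np.asarray(labels)
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    g0, g1 = uniq
    idx0 = np.flatnonzero(labels == g0)
    idx1 = np.flatnonzero(labels == g1)
    if idx0.size < 2 or idx1.size < 2:
        raise ValueError("each group needs at least two subjects")

    K = metrics[0].FO.size
    FO = np.stack([m.FO for m in metrics])
    SR = np.array([m.SR for m in metrics])

    rows = []
    for k in range(K):
        stat, p = rank_sum_test(FO[idx0, k], FO[idx1, k])
        rows.append({"metric": f"FO_S{k + 1}", "statistic": stat, "p_raw": p,
                     f"median_{g0}": float(np.median(FO[idx0, k])),
                     f"median_{g1}": float(np.median(FO[idx1, k])),
                     f"mean_{g0}": float(FO[idx0, k].mean()),
                     f"mean_{g1}": float(FO[idx1, k].mean())})
    stat, p = rank_sum_test(SR[idx0], SR[idx1])
    rows.append({"metric": "SR", "statistic": stat, "p_raw": p,
                 f"median_{g0}": float(np.median(SR[idx0])),
                 f"median_{g1}": float(np.median(SR[idx1])),
                 f"mean_{g0}": float(SR[idx0].mean()),
                 f"mean_{g1}": float(SR[idx1].mean())})
    table = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(table["p_raw"].to_numpy(), alpha)
    table["p_fdr"] = p_adj
    table["reject"] = reject
    return table
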