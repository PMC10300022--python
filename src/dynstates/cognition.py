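"""Relating state occupancy to lesions and cognition.

Lesion descriptors (extension, hemisphere, voxelwise frequency maps),
univariate rank-sum screening of cognitive tests between patient subgroups,
collinearity reduction by hierarchical clustering of tests with a silhouette
cut, and stepwise multivariate linear regression of a state's fractional
occupancy on the reduced test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dynamics import rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "zscore_tests",
    "correlate_lesion_fo",
    "lesion_frequency_map",
    "univariate_group_tests",
    "cluster_reduce_features",
    "stepwise_regression",
    "StepwiseResults",
]


def zscore_tests(raw: pd.DataFrame, norms: pd.DataFrame) -> pd.DataFrame:
    """Standardise raw test scores against normative means and SDs.

    ``norms`` is indexed by test name with columns ``mean`` and ``sd``
    (direction conventions — higher is better — are the norms file's
    responsibility). Every test in ``raw`` must have a norm row.
    """
    missing = [t for t in raw.columns if t not in norms.index]
    if missing:
        raise KeyError(f"no normative values for test(s): {missing}")
    sd = norms.loc[list(raw.columns), "sd"]
    if (sd <= 0).any():
        bad = sd.index[sd <= 0].tolist()
        raise ValueError(f"non-positive normative SD for: {bad}")
    mean = norms.loc[list(raw.columns), "mean"]
    return (raw - mean) / sd


def correlate_lesion_fo(extension, fo_state) -> tuple[float, float]:
    """Pearson correlation between lesion extension and occupancy in a state.

    Returns (r, two-sided p from the t-distribution with n - 2 df).
    """
    x = np.asarray(extension, dtype=float)
    y = np.asarray(fo_state, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def lesion_frequency_map(masks: list) -> np.ndarray:
    """Voxelwise lesion frequency: mean of aligned binary masks, in [0, 1]."""
    if not masks:
        raise ValueError("no masks")
    arrs = [np.asarray(m, dtype=float) for m in masks]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("masks are not on the same grid")
    stack = np.stack(arrs)
    if stack.sum() == 0:
        raise ValueError("all masks are empty")
    return stack.mean(axis=0)


def univariate_group_tests(table: pd.DataFrame, subgroup_labels,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-test rank-sum screening between two subgroups (no FDR here: this
    is a screening step, and raw p-values are reported)."""
    labels = np.asarray(subgroup_labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two subgroups, got {uniq}")
    i0 = labels == uniq[0]
    i1 = labels == uniq[1]
    if i0.sum() < 2 or i1.sum() < 2:
        raise ValueError("each subgroup needs at least two subjects")
    rows = []
    for test in table.columns:
        col = table[test].to_numpy(dtype=float)
        if np.all(col == col[0]):
            logger.warning("test %r is constant; p = 1", test)
            stat, p = 0.0, 1.0
        else:
            stat, p = rank_sum_test(col[i0], col[i1])
        rows.append({"test": test, "statistic": stat, "p_raw": p,
                     f"median_{uniq[0]}": float(np.median(col[i0])),
                     f"median_{uniq[1]}": float(np.median(col[i1])),
                     "significant": p < alpha})
    return pd.DataFrame(rows)


def cluster_reduce_features(table: pd.DataFrame, target,
                            method: str = "average") -> list:
    """Collinearity-driven feature reduction.

    Tests are clustered on the distance 1 - |Pearson r| between columns with
    average-linkage (configurable) hierarchical clustering; the number of
    clusters maximises the mean silhouette over k = 2..n_tests-1; each
    cluster contributes the test most correlated (in absolute value) with
    the target occupancy, ties resolved alphabetically. Constant columns are
    set aside (own cluster, never representative).
    """
    from sklearn.metrics import silhouette_score

    target = np.asarray(target, dtype=float)
    if table.shape[1] < 2:
        raise ValueError("need at least two tests")
    if table.shape[0] <= 3:
        raise ValueError("need more than three subjects")

    cols = list(table.columns)
    X = table.to_numpy(dtype=float)
    const = [c for j, c in enumerate(cols) if np.all(X[:, j] == X[0, j])]
    if const:
        logger.warning("constant test column(s) excluded from clustering: %s", const)
    keep = [c for c in cols if c not in const]
    if len(keep) < 2:
        raise ValueError("fewer than two non-constant tests")
    Xk = table[keep].to_numpy(dtype=float)

    corr = np.corrcoef(Xk.T)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method=method)

    n = len(keep)
    best_k, best_sil = None, -np.inf
    for k in range(2, n):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if np.unique(labels).size < 2:
            continue
        sil = silhouette_score(dist, labels, metric="precomputed")
        if sil > best_sil + 1e-12:
            best_sil, best_k = sil, k
    if best_k is None:  # degenerate: fall back to every test its own cluster
        labels = np.arange(1, n + 1)
    else:
        labels = fcluster(Z, t=best_k, criterion="maxclust")

    target_corr = {}
    for j, c in enumerate(keep):
        col = Xk[:, j]
        target_corr[c] = abs(np.corrcoef(col, target)[0, 1]) if col.std() > 0 else 0.0

    selected = []
    for lab in np.unique(labels):
        members = [keep[j] for j in np.flatnonzero(labels == lab)]
        # highest |corr with target| wins; ties resolved alphabetically
        best = sorted(members, key=lambda c: (-target_corr[c], c))[0]
        selected.append(best)
    return sorted(selected, key=cols.index)


@dataclass
class StepwiseResults:
    """Stepwise regression outcome: retained tests, standardised betas, fit."""

    selected: list
    beta: pd.Series  # standardised coefficients
    intercept: float
    r_squared: float  # squared Pearson between fitted values and y
    trace: list = field(default_factory=list)  # (step, action, term, p)
    fitted: np.ndarray | None = None

    def summary(self) -> str:
        lines = ["Stepwise linear regression", "=========================",
                 f"retained terms: {len(self.selected)}",
                 f"R^2 (fit vs observed): {self.r_squared:.3f}", ""]
        for name in self.selected:
            lines.append(f"  beta[{name}] = {self.beta[name]:+.3f}")
        return "\n".join(lines)


def _partial_f_p(y, X_base, x_new):
    """p-value of adding x_new to the model [1, X_base]."""
    n = y.size
    X0 = np.column_stack([np.ones(n)] + ([X_base] if X_base is not None else []))
    X1 = np.column_stack([X0, x_new])
    if np.linalg.matrix_rank(X1) <= np.linalg.matrix_rank(X0):
        return None  # aliased column
    rss0 = _rss(y, X0)
    if rss0 < 1e-12 * max(1.0, float(y @ y)):
        return None  # base model already fits perfectly
    rss1 = _rss(y, X1)
    df2 = n - X1.shape[1]
    if df2 <= 0:
        return None
    f = max(rss0 - rss1, 0.0) / (rss1 / df2) if rss1 > 0 else np.inf
    return float(stats.f.sf(f, 1, df2))


def _rss(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def stepwise_regression(X: pd.DataFrame, y, p_enter: float = 0.05,
                        p_remove: float = 0.10, max_steps: int = 200) -> StepwiseResults:
    """Forward-backward stepwise OLS with partial-F entry/removal tests.

    Predictors are standardised internally (zero mean, unit SD) so the betas
    are comparable across tests; forward steps add the candidate with the
    smallest partial-F p below ``p_enter``, backward steps drop any retained
    term whose p exceeds ``p_remove``; iteration stops at stability (or on an
    add/remove cycle, which is reported). R^2 is the squared Pearson
    correlation between fitted values and the dependent variable.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X and y disagree on sample size")
    cols = list(X.columns)
    Xs = {}
    for c in cols:
        v = X[c].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            logger.warning("dropping constant predictor %r", c)
            continue
        Xs[c] = (v - v.mean()) / sd

    selected: list = []
    trace: list = []
    seen_states = set()
    for step in range(max_steps):
        state = tuple(sorted(selected))
        if state in seen_states and step > 0:
            logger.warning("stepwise selection cycled; stopping at %s", selected)
            trace.append((step, "cycle-stop", None, None))
            break
        seen_states.add(state)

        base = np.column_stack([Xs[c] for c in selected]) if selected else None
        # forward
        best_c, best_p = None, np.inf
        for c in Xs:
            if c in selected:
                continue
            if n <= len(selected) + 2:
                break
            p = _partial_f_p(y, base, Xs[c])
            if p is not None and p < best_p:
                best_p, best_c = p, c
        changed = False
        if best_c is not None and best_p < p_enter:
            selected.append(best_c)
            trace.append((step, "add", best_c, best_p))
            changed = True
        # backward
        removed = True
        while removed and selected:
            removed = False
            worst_c, worst_p = None, -np.inf
            for c in selected:
                others = [d for d in selected if d != c]
                base_o = np.column_stack([Xs[d] for d in others]) if others else None
                p = _partial_f_p(y, base_o, Xs[c])
                if p is not None and p > worst_p:
                    worst_p, worst_c = p, c
            if worst_c is not None and worst_p > p_remove:
                selected.remove(worst_c)
                trace.append((step, "remove", worst_c, worst_p))
                removed = True
                changed = True
        if not changed:
            break

    if selected:
        Xfin = np.column_stack([np.ones(n)] + [Xs[c] for c in selected])
        coef, *_ = np.linalg.lstsq(Xfin, y, rcond=None)
        fitted = Xfin @ coef
        intercept = float(coef[0])
        beta = pd.Series(coef[1:], index=selected)
        if fitted.std() > 0 and y.std() > 0:
            r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
        else:
            r2 = 0.0
    else:
        intercept = float(y.mean())
        fitted = np.full(n, intercept)
        beta = pd.Series(dtype=float)
        r2 = 0.0
    return StepwiseResults(selected=selected, beta=beta, intercept=intercept,
                           r_squared=r2, trace=trace, fitted=fitted)
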