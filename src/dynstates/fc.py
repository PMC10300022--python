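"""State functional-connectivity matrices: proportional sparsification and
between-state edge-strength comparison.

Sparsification is proportional thresholding by edge magnitude (keep the
strongest (1 - sparsity) fraction of upper-triangular edges by |r|, signs
preserved); edge-strength differences between states are tested on the
retained upper-triangular values with rank-sum tests under BH-FDR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import bh_fdr, rank_sum_test

logger = logging.getLogger(__name__)

__all__ = ["StateFC", "sparsify_proportional", "compare_state_edges"]


@dataclass
class StateFC:
    """A (possibly sparsified) M x M state correlation matrix."""

    R: np.ndarray
    mask: np.ndarray  # retained-edge indicator (symmetric, no diagonal)
    density: float  # retained fraction of off-diagonal edges
    state: int = 0  # 1-based state id
    labels: list = field(default_factory=list)  # IC -> RSN labels

    @property
    def M(self) -> int:
        return self.R.shape[0]

    def retained_values(self) -> np.ndarray:
        """Upper-triangular retained edge values."""
        iu = np.triu_indices(self.M, k=1)
        vals = self.R[iu]
        return vals[self.mask[iu]]


def sparsify_proportional(R: np.ndarray, sparsity: float = 0.80, state: int = 0,
                          labels=None) -> StateFC:
    """Keep the strongest (1 - sparsity) fraction of edges by magnitude.

    Edges are the M(M-1)/2 upper-triangular entries; the retained count is
    ceil((1 - sparsity) * E). Ties at the cutoff are resolved by (i, j)
    lexicographic order (noted in the log). Signs of retained edges are
    preserved; the result is mirrored to the lower triangle with a zero
    diagonal.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must be in [0, 1)")
    M = R.shape[0]
    iu, ju = np.triu_indices(M, k=1)
    vals = R[iu, ju]
    E = vals.size
    n_keep = math.ceil((1.0 - sparsity) * E)
    # sort by (-|v|, i, j): magnitude first, lexicographic tie-break
    order = np.lexsort((ju, iu, -np.abs(vals)))
    keep = order[:n_keep]
    if n_keep < E:
        cut = np.abs(vals[order[n_keep - 1]])
        if np.isclose(np.abs(vals[order[n_keep]]), cut):
            logger.info("ties at the sparsification cutoff resolved lexicographically")
    mask = np.zeros((M, M), dtype=bool)
    mask[iu[keep], ju[keep]] = True
    mask |= mask.T
    out = np.where(mask, R, 0.0)
    np.fill_diagonal(out, 0.0)
    return StateFC(R=out, mask=mask, density=n_keep / E if E else 0.0,
                   state=state, labels=list(labels) if labels is not None else [])


def compare_state_edges(states: list, alpha: float = 0.05, use_abs: bool = False):
    """Pairwise rank-sum comparison of retained edge strengths between states.

    Tests run on the retained upper-triangular values (post-sparsification);
    ``use_abs`` switches to absolute values. BH-FDR across all state pairs.
    Returns a pandas DataFrame with per-state medians, raw/adjusted p and
    rejection flags.
    """
    import pandas as pd

    if len(states) < 2:
        raise ValueError("need at least two states")
    M = states[0].M
    if any(s.M != M for s in states):
        raise ValueError("states disagree on node count")
    vals = []
    for s in states:
        v = s.retained_values()
        if v.size == 0:
            raise ValueError(f"state {s.state}: no retained edges")
        vals.append(np.abs(v) if use_abs else v)

    rows = []
    for a in range(len(states)):
        for b in range(a + 1, len(states)):
            stat, p = rank_sum_test(vals[a], vals[b])
            rows.append({
                "state_a": states[a].state or a + 1,
                "state_b": states[b].state or b + 1,
                "median_a": float(np.median(vals[a])),
                "median_b": float(np.median(vals[b])),
                "statistic": stat,
                "p_raw": p,
            })
    table = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(table["p_raw"].to_numpy(), alpha)
    table["p_fdr"] = p_adj
    table["reject"] = reject
    return table
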