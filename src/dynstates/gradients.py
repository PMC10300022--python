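"""Connectivity gradients: Gaussian-kernel affinity + Laplacian eigenmaps,
Procrustes alignment across states, and cosine similarity of principal
gradients.

A gradient is an eigenvector of the normalised graph Laplacian built from an
FC-derived affinity matrix; the first (smallest nonzero eigenvalue) gradient
orders nodes along the principal axis of connectivity variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, orthogonal_procrustes
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GradientSet",
    "compute_gradients",
    "align_gradients",
    "reference_gradient",
    "cosine_similarity",
]


@dataclass
class GradientSet:
    """Gradients of one state: columns ordered by increasing Laplacian
    eigenvalue, trivial (constant) component removed."""

    G: np.ndarray  # (M, g)
    eigenvalues: np.ndarray  # (g,)
    state: int = 0
    aligned: bool = False
    labels: list = field(default_factory=list)

    @property
    def M(self) -> int:
        return self.G.shape[0]

    @property
    def n_gradients(self) -> int:
        return self.G.shape[1]


def _fix_signs(G: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude entry of each column positive."""
    out = G.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def compute_gradients(R: np.ndarray, g: int = 2, row_sparsify: float = 0.5,
                      sigma: float | str = "median", state: int = 0,
                      labels=None) -> GradientSet:
    """Laplacian-eigenmap gradients of a connectivity matrix.

    Steps: (1) per row keep the top (1 - row_sparsify) fraction of entries by
    value, zero the rest; (2) Gaussian-kernel affinity
    W_ij = exp(-d_ij^2 / (2 sigma^2)) on Euclidean distances between the
    processed rows, with sigma the median off-diagonal distance unless given;
    (3) eigendecomposition of the symmetric-normalised Laplacian
    I - D^{-1/2} W D^{-1/2} (spectrally equivalent to the random-walk
    Laplacian); the eigenvectors of the g smallest nonzero eigenvalues are
    returned, orthonormal, signs fixed so each column's largest-magnitude
    entry is positive.
    """
    R = np.asarray(R, dtype=float)
    M = R.shape[0]
    if R.ndim != 2 or R.shape[1] != M:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-9):
        raise ValueError("R must be symmetric")
    if M < g + 2:
        raise ValueError("need at least g + 2 nodes")
    if not 0.0 <= row_sparsify < 1.0:
        raise ValueError("row_sparsify must be in [0, 1)")

    n_keep = max(1, math.ceil((1.0 - row_sparsify) * M))
    rows = np.zeros_like(R)
    for i in range(M):
        top = np.argsort(R[i])[::-1][:n_keep]
        rows[i, top] = R[i, top]

    d = squareform(pdist(rows))
    if sigma == "median":
        off = d[np.triu_indices(M, k=1)]
        sigma_val = float(np.median(off))
        if sigma_val == 0.0:
            sigma_val = 1.0  # all rows identical: affinity degenerates to ones
    else:
        sigma_val = float(sigma)
        if sigma_val <= 0:
            raise ValueError("sigma must be positive")
    W = np.exp(-(d ** 2) / (2.0 * sigma_val ** 2))

    n_comp, comp = connected_components((W > 1e-12).astype(int), directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        raise ValueError(f"affinity graph disconnected: component sizes {sizes.tolist()}")

    deg = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    L_sym = np.eye(M) - W * inv_sqrt[:, None] * inv_sqrt[None, :]
    evals, evecs = eigh((L_sym + L_sym.T) / 2.0)
    nonzero = np.flatnonzero(evals > 1e-10)
    if nonzero.size < g:
        raise ValueError("fewer nonzero Laplacian eigenvalues than requested gradients")
    sel = nonzero[:g]
    return GradientSet(G=_fix_signs(evecs[:, sel]), eigenvalues=evals[sel],
                       state=state, labels=list(labels) if labels is not None else [])


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-norm gradient")
    return float(np.dot(u, v) / (nu * nv))


def align_gradients(sets: list, reference: GradientSet):
    """Orthogonal Procrustes alignment of gradient sets onto a reference.

    Each set's G is rotated/reflected (no scaling, no translation) onto the
    reference G. Returns (aligned sets, S x S matrix of pairwise cosine
    similarities between aligned first gradients).
    """
    for s in sets:
        if s.G.shape != reference.G.shape:
            raise ValueError("gradient set shapes do not match the reference")
    aligned = []
    for s in sets:
        Q, _ = orthogonal_procrustes(s.G, reference.G)
        aligned.append(GradientSet(G=s.G @ Q, eigenvalues=s.eigenvalues.copy(),
                                   state=s.state, aligned=True,
                                   labels=list(s.labels)))
    n = len(aligned)
    sim = np.ones((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            sim[a, b] = sim[b, a] = cosine_similarity(aligned[a].G[:, 0],
                                                      aligned[b].G[:, 0])
    return aligned, sim


def reference_gradient(state_matrices: list, g: int = 2, **kwargs) -> GradientSet:
    """Gradients of the element-wise mean of the state FC matrices."""
    if not state_matrices:
        raise ValueError("need at least one state matrix")
    mats = [np.asarray(m, dtype=float) for m in state_matrices]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("state matrices disagree on shape")
    return compute_gradients(np.mean(mats, axis=0), g=g, **kwargs)
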