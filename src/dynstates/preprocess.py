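"""IC time-course denoising applied before HMM fitting.

The chain is order-fixed: despike -> nuisance regression -> high-pass
(DCT-basis) -> temporal resampling -> per-subject z-scoring and
concatenation. Framewise displacement is computed from 6-column rigid-body
motion parameters for QC-style group comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

__all__ = [
    "ICTimeSeries",
    "ConcatResult",
    "framewise_displacement",
    "despike",
    "nuisance_regress",
    "highpass",
    "resample_to_grid",
    "zscore_and_concat",
    "prep_subject",
]


@dataclass
class ICTimeSeries:
    """One subject's T x M component time-course matrix."""

    series: np.ndarray
    TR: float
    subject_id: str = "sub-000"
    group: str = ""

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[0] < 2:
            raise ValueError("series must be T x M with T >= 2")


@dataclass
class ConcatResult:
    """Concatenated, z-scored cohort matrix with subject row ranges."""

    matrix: np.ndarray  # (N_total, M)
    ranges: list  # list of (start, stop) row slices, one per subject
    subject_ids: list
    groups: list
    TR: float

    @property
    def lengths(self) -> list:
        return [stop - start for start, stop in self.ranges]


def framewise_displacement(mp: np.ndarray, sphere_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style framewise displacement from T x 6 motion parameters.

    Columns 0-2 are translations (mm), columns 3-5 rotations (radians);
    rotations are converted to arc length on a sphere of the given radius.
    The first element is 0 by convention.
    """
    mp = np.asarray(mp, dtype=float)
    if mp.ndim != 2 or mp.shape[1] != 6:
        raise ValueError("motion parameters must be T x 6")
    if mp.shape[0] < 2:
        raise ValueError("need at least two frames")
    if not np.all(np.isfinite(mp)):
        raise ValueError("non-finite motion parameters")
    d = np.diff(mp, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + sphere_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def despike(series: np.ndarray, c1: float = 2.5, c2: float = 4.0, window: int = 15) -> np.ndarray:
    """AFNI-style despiking: squash outliers toward a running-median trend.

    Per channel, residuals r from a running median (window samples,
    nearest-edge padding) are scaled by s = 1.4826 * MAD(r). Samples with
    |r| > c1*s are replaced by
    trend + sign(r) * s * (c1 + (c2 - c1) * tanh((|r|/s - c1)/(c2 - c1)));
    everything else passes through bit-identically. A zero MAD with nonzero
    residuals falls back to the residual SD; all-constant channels pass
    through unchanged.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        return despike(x[:, None], c1, c2, window)[:, 0]
    if x.shape[0] < window:
        raise ValueError(f"need at least {window} samples for the running median")
    out = x.copy()
    trend = ndimage.median_filter(x, size=(window, 1), mode="nearest")
    r = x - trend
    for j in range(x.shape[1]):
        rj = r[:, j]
        s = 1.4826 * np.median(np.abs(rj - np.median(rj)))
        if s == 0.0:
            if np.allclose(rj, 0.0):
                continue
            s = rj.std()
            if s == 0.0:
                continue
        a = np.abs(rj) / s
        hot = a > c1
        if not hot.any():
            continue
        squash = s * (c1 + (c2 - c1) * np.tanh((a[hot] - c1) / (c2 - c1)))
        out[hot, j] = trend[hot, j] + np.sign(rj[hot]) * squash
    return out


def nuisance_regress(series: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualise each channel on the confound columns (plus intercept).

    Rank-deficient designs are handled by least squares on the full design
    (minimum-norm solution), with a logged warning naming the deficiency.
    """
    y = np.asarray(series, dtype=float)
    C = np.asarray(confounds, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != y.shape[0]:
        raise ValueError("confounds and series disagree on T")
    if C.shape[1] >= y.shape[0]:
        raise ValueError("more confounds than time points")
    X = np.column_stack([np.ones(y.shape[0]), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "confound design rank-deficient (rank %d of %d); dependent columns ignored",
            rank, X.shape[1],
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _dct_basis(T: int, TR: float, cutoff_hz: float) -> np.ndarray:
    """SPM-style discrete-cosine drift basis: all components below cutoff."""
    n_basis = int(np.floor(2.0 * T * TR * cutoff_hz))
    t = np.arange(T)
    cols = [np.ones(T)]
    for k in range(1, n_basis + 1):
        cols.append(np.sqrt(2.0 / T) * np.cos(np.pi * k * (2 * t + 1) / (2.0 * T)))
    return np.column_stack(cols)


def highpass(series: np.ndarray, TR: float, cutoff_hz: float = 1.0 / 128.0) -> np.ndarray:
    """High-pass by regressing out a discrete-cosine low-frequency basis.

    Removes the constant and every cosine component with frequency below
    ``cutoff_hz`` (default 1/128 Hz); output channels have zero mean.
    """
    y = np.asarray(series, dtype=float)
    if TR <= 0:
        raise ValueError("TR must be positive")
    if cutoff_hz >= 0.5 / TR:
        raise ValueError("cutoff at or above Nyquist")
    X = _dct_basis(y.shape[0], TR, cutoff_hz)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def resample_to_grid(series: np.ndarray, TR_src: float, TR_tgt: float) -> np.ndarray:
    """Cubic-spline interpolation of each channel onto a target TR grid.

    The target grid spans the source duration; no extrapolation is
    performed (a target grid that would overrun is truncated with a
    warning). With equal TRs the input is returned unchanged.
    """
    y = np.asarray(series, dtype=float)
    if TR_src <= 0 or TR_tgt <= 0:
        raise ValueError("TRs must be positive")
    if TR_src == TR_tgt:
        return y.copy()
    t_src = np.arange(y.shape[0]) * TR_src
    duration = t_src[-1]
    t_tgt = np.arange(0.0, duration + 0.5 * TR_tgt, TR_tgt)
    if t_tgt[-1] > duration + 1e-12:
        warnings.warn("target grid exceeds source duration; truncating")
        t_tgt = t_tgt[t_tgt <= duration + 1e-12]
    return CubicSpline(t_src, y, axis=0)(t_tgt)


def zscore_and_concat(cohort: list, truncate_last: int = 0) -> ConcatResult:
    """Per-subject, per-channel z-scoring followed by temporal concatenation.

    ``truncate_last`` volumes are dropped from the end of each subject's
    series before standardisation (as done to harmonise scan lengths).
    Zero-variance channels raise, naming subject and channel.
    """
    if not cohort:
        raise ValueError("empty cohort")
    M = cohort[0].series.shape[1]
    blocks, ranges, ids, groups = [], [], [], []
    start = 0
    for sub in cohort:
        x = sub.series
        if x.shape[1] != M:
            raise ValueError(f"{sub.subject_id}: component count differs")
        if truncate_last:
            if truncate_last >= x.shape[0] - 1:
                raise ValueError(f"{sub.subject_id}: truncation leaves fewer than 2 rows")
            x = x[: x.shape[0] - truncate_last]
        sd = x.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"{sub.subject_id}: zero-variance channel(s) {bad.tolist()}")
        z = (x - x.mean(axis=0)) / sd
        blocks.append(z)
        ranges.append((start, start + z.shape[0]))
        start += z.shape[0]
        ids.append(sub.subject_id)
        groups.append(getattr(sub, "group", ""))
    return ConcatResult(
        matrix=np.vstack(blocks),
        ranges=ranges,
        subject_ids=ids,
        groups=groups,
        TR=cohort[0].TR,
    )


def prep_subject(
    sub: ICTimeSeries,
    confounds: np.ndarray | None = None,
    motion: np.ndarray | None = None,
    cutoff_hz: float = 1.0 / 128.0,
    TR_target: float | None = None,
    despike_window: int = 15,
) -> ICTimeSeries:
    """Run the fixed denoising chain on one subject.

    Order: despike -> nuisance regression (motion, derivatives, extra
    confounds) -> high-pass -> resample to target TR. z-scoring happens at
    concatenation time.
    """
    x = despike(sub.series, window=despike_window)
    cols = []
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        dmotion = np.vstack([np.zeros((1, motion.shape[1])), np.diff(motion, axis=0)])
        cols += [motion, dmotion]
    if confounds is not None:
        cols.append(np.asarray(confounds, dtype=float))
    if cols:
        x = nuisance_regress(x, np.column_stack(cols))
    x = highpass(x, sub.TR, cutoff_hz)
    TR = sub.TR
    if TR_target is not None and TR_target != sub.TR:
        x = resample_to_grid(x, sub.TR, TR_target)
        TR = TR_target
    return ICTimeSeries(series=x, TR=TR, subject_id=sub.subject_id, group=sub.group)
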