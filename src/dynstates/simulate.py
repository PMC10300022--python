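"""Synthetic two-group cohorts of IC time courses from a ground-truth HMM.

Real resting-state data for this kind of study (tumour patients vs healthy
controls) are rarely shareable, so every downstream stage of the package is
exercised on simulated cohorts with known ground truth: a K-state hidden
Markov chain per subject, multivariate-Gaussian emissions with
block-structured covariances (blocks emulate resting-state networks), two
groups whose transition structure concentrates occupancy on disjoint state
subsets, connectivity attenuation in the "pathological" states, and a
cognitive-score table in which a planted subset of tests is linearly tied to
a state's fractional occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimConfig",
    "CognitiveSimConfig",
    "GroundTruth",
    "SimulatedSubject",
    "LesionMask",
    "make_ground_truth",
    "simulate_subject",
    "simulate_cohort",
    "simulate_cognitive_scores",
    "simulate_lesions",
]

CONTROL = "control"
PATIENT = "patient"
#: internal chain key for the patient subgroup dominated by the first
#: pathological state; their group label remains "patient"
PATIENT_S5DOM = "patient_s5dom"


@dataclass(frozen=True)
class SimConfig:
    """Conditions of the simulated study.

    Defaults mirror the study design the package targets: 33 + 33 subjects,
    45 independent components grouped in 10 blocks (RSN analogues), 730
    retained volumes at TR = 1.26 s, six states of which the last two are
    "pathological". Patient chains are tuned so that the switching rate sits
    near 0.08 Hz and pathological occupancy splits roughly 1:2 between the
    two pathological states, as observed in high-grade glioma cohorts.
    """

    K: int = 6
    M: int = 45
    n_blocks: int = 10
    n_controls: int = 33
    n_patients: int = 33
    T: int = 730
    TR: float = 1.26
    n_pathological: int = 2
    rho_range: tuple[float, float] = (0.40, 0.60)
    #: per-state modulation of the per-block coupling (uniform half-width)
    rho_state_jitter: float = 0.05
    #: background correlation between blocks: constant, or a (lo, hi) range
    #: drawn once per block pair (stable across states)
    cross_rho: float | tuple[float, float] = (0.05, 0.25)
    #: per-state multiplicative scale on off-diagonal correlation
    attenuation: tuple[float, ...] | None = None
    attenuation_pathological: float = 0.5
    #: blocks exempt from attenuation (primary-network analogue): edges with
    #: both endpoints in spared blocks keep full strength, so the weight
    #: ceiling stays comparable across states and the connectivity loss is
    #: structural rather than a uniform rescaling
    n_spared_blocks: int = 2
    mean_scale: float = 0.55
    stay: float = 0.9
    leak: float = 0.01
    #: patient-chain transition rates between the two pathological states
    patho_forward: float = 0.124
    patho_back: float = 0.062
    #: fraction of patients whose chain favours the FIRST pathological state
    #: (forward/back rates swapped), emulating the bimodal stratification of
    #: patient cohorts into state-dominant subgroups
    s5_dominant_frac: float = 0.25
    seed: int = 0

    @property
    def healthy_states(self) -> list[int]:
        return list(range(1, self.K - self.n_pathological + 1))

    @property
    def pathological_states(self) -> list[int]:
        return list(range(self.K - self.n_pathological + 1, self.K + 1))


@dataclass(frozen=True)
class CognitiveSimConfig:
    """Planted cognitive battery: a few tests track occupancy, the rest are
    noisy copies of shared latent factors (to exercise feature clustering)."""

    n_tests: int = 24
    #: test name -> signed weight on the occupancy target
    planted: dict = field(
        default_factory=lambda: {"cog_test_01": 1.0, "cog_test_02": -1.0}
    )
    noise_sd: float = 0.05
    n_latent: int = 7
    latent_noise_sd: float = 0.3

    def test_names(self) -> list[str]:
        return [f"cog_test_{i + 1:02d}" for i in range(self.n_tests)]


@dataclass
class GroundTruth:
    """Parameters of the generating HMM shared by a cohort."""

    K: int
    M: int
    block_assign: np.ndarray  # (M,) block label per component
    pi: dict  # group -> (K,) initial distribution
    A: dict  # group -> (K, K) transition matrix
    mu: np.ndarray  # (K, M)
    Sigma: np.ndarray  # (K, M, M)
    attenuation: np.ndarray  # (K,)
    healthy_states: list
    pathological_states: list
    seed: int

    def validate(self) -> None:
        for g, A in self.A.items():
            if not np.allclose(A.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"transition rows of group {g!r} do not sum to 1")
            if not np.allclose(self.pi[g].sum(), 1.0, atol=1e-12):
                raise ValueError(f"initial distribution of group {g!r} does not sum to 1")
        for k in range(self.K):
            S = self.Sigma[k]
            if not np.allclose(S, S.T, atol=1e-10):
                raise ValueError(f"Sigma[{k}] not symmetric")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError(f"Sigma[{k}] not positive definite")


@dataclass
class SimulatedSubject:
    """One simulated scan: T x M series plus the hidden truth."""

    series: np.ndarray
    true_path: np.ndarray  # 1-based state labels
    group: str
    TR: float
    subject_id: str

    def __post_init__(self) -> None:
        if self.series.shape[0] < 2:
            raise ValueError("need at least two time points")
        if self.true_path.min() < 1:
            raise ValueError("state labels are 1-based")


@dataclass
class LesionMask:
    mask: np.ndarray  # 3-D binary
    extension: int  # voxel count
    hemisphere: str  # left/right by first-axis centroid


def _block_labels(M: int, B: int) -> np.ndarray:
    """Near-equal split of M components into B contiguous blocks."""
    sizes = np.full(B, M // B)
    sizes[: M % B] += 1
    return np.repeat(np.arange(B), sizes)


def _jitter_pd(S: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Add eps*I, doubling eps, until the smallest eigenvalue clears floor."""
    eps = 1e-10
    out = S.copy()
    for _ in range(60):
        if np.linalg.eigvalsh(out).min() > floor:
            return out
        out = S + eps * np.eye(S.shape[0])
        eps *= 2
    raise ValueError("covariance could not be repaired to positive definite")


def make_ground_truth(config: SimConfig) -> GroundTruth:
    """Build the generating HMM for a two-group cohort.

    Covariances are block-structured correlation matrices. Within-block
    coupling is a stable per-block property (drawn once from
    ``config.rho_range``, strongest blocks first so the spared primary-
    network analogues anchor the connectivity hierarchy) modulated per state
    by ``rho_state_jitter``. Blocks sit on a 1-D functional axis
    (primary -> transmodal): cross-block coupling decays with axis distance
    within ``cross_rho``, giving the connectome one dominant slow mode as in
    real FC gradients. In attenuated (pathological) states every edge is
    scaled by the state's attenuation except those with both endpoints in
    spared blocks — a structural, global connectivity loss that survives
    per-matrix weight normalisation downstream. State means are modest
    relative to the unit-variance channels (z-scored-BOLD regime) and carry
    most of the state identifiability, leaving the correlation structure
    free to encode the planted connectivity contrasts.
    """
    K, M, B = config.K, config.M, config.n_blocks
    if B > M:
        raise ValueError("more blocks than components")
    lo, hi = config.rho_range
    if not (-1.0 < lo <= hi < 1.0):
        raise ValueError("within-block correlation must lie in (-1, 1)")
    if config.n_pathological >= K:
        raise ValueError("need at least one healthy state")
    rng = np.random.default_rng(config.seed)

    block = _block_labels(M, B)
    if config.attenuation is not None:
        atten = np.asarray(config.attenuation, dtype=float)
        if atten.shape != (K,):
            raise ValueError("attenuation must have one entry per state")
    else:
        atten = np.ones(K)
        atten[K - config.n_pathological:] = config.attenuation_pathological
    if np.any(atten <= 0) or np.any(atten > 1):
        raise ValueError("attenuation must lie in (0, 1]")

    cross = config.cross_rho
    if np.ndim(cross) == 0:
        cross_lo = cross_hi = float(cross)
    else:
        cross_lo, cross_hi = map(float, cross)
    if not (-1.0 < cross_lo <= cross_hi < 1.0):
        raise ValueError("cross-block correlation must lie in (-1, 1)")
    if not 0 <= config.n_spared_blocks <= B:
        raise ValueError("n_spared_blocks outside 0..n_blocks")
    spared = np.zeros(B, dtype=bool)
    spared[: config.n_spared_blocks] = True

    Sigma = np.empty((K, M, M))
    same_block = block[:, None] == block[None, :]
    # block coupling is a stable network property shared across states,
    # modulated per state; attenuation then yields a consistent contrast
    # strongest internal coupling goes to the spared (primary-network)
    # blocks: their coherence anchors the connectivity hierarchy
    rho_base = np.sort(rng.uniform(lo, hi, size=B))[::-1]
    # blocks sit on a 1-D functional axis (primary -> transmodal): coupling
    # between blocks decays with axis distance, giving the connectome one
    # dominant slow mode, as in real FC gradients; small pair jitter breaks
    # exact degeneracies
    axis = np.arange(B, dtype=float)
    decay = 1.0 - np.abs(axis[:, None] - axis[None, :]) / max(B - 1, 1)
    cross_base = cross_lo + (cross_hi - cross_lo) * decay
    pair_noise = rng.uniform(-0.02, 0.02, size=(B, B))
    cross_base = cross_base + (pair_noise + pair_noise.T) / 2.0
    # attenuation spares only edges with BOTH endpoints in spared blocks
    spared_pair = spared[block][:, None] & spared[block][None, :]
    for k in range(K):
        jit = config.rho_state_jitter
        rho_b = np.clip(rho_base + rng.uniform(-jit, jit, size=B), -0.95, 0.95)
        C = np.where(same_block, rho_b[block][:, None],
                     cross_base[np.ix_(block, block)])
        C = np.where(spared_pair, C, C * atten[k])
        np.fill_diagonal(C, 1.0)
        Sigma[k] = _jitter_pd(C)

    mu = rng.normal(0.0, config.mean_scale, size=(K, M))

    healthy = [s - 1 for s in config.healthy_states]
    patho = [s - 1 for s in config.pathological_states]

    A_ctrl = _group_chain(K, active=healthy, stay=config.stay, leak=config.leak)
    # with no pathological states the two groups share one chain
    A_pat = _patient_chain(config, healthy, patho) if patho else A_ctrl.copy()

    pi_ctrl = np.zeros(K)
    pi_ctrl[healthy] = 1.0 / len(healthy)

    pi_pat = np.zeros(K)
    if len(patho) == 2:
        f, b = config.patho_forward, config.patho_back
        pi_pat[patho[0]] = b / (f + b)
        pi_pat[patho[1]] = f / (f + b)
    elif patho:
        pi_pat[patho] = 1.0 / len(patho)
    else:
        pi_pat = pi_ctrl.copy()

    A_groups = {CONTROL: A_ctrl, PATIENT: A_pat}
    pi_groups = {CONTROL: pi_ctrl, PATIENT: pi_pat}
    if len(patho) == 2 and config.s5_dominant_frac > 0:
        # minority patient subgroup whose chain favours the first
        # pathological state: swap the forward/back rates
        swapped = replace(config, patho_forward=config.patho_back,
                          patho_back=config.patho_forward)
        A_groups[PATIENT_S5DOM] = _patient_chain(swapped, healthy, patho)
        pi_s5 = np.zeros(K)
        pi_s5[patho[0]] = pi_pat[patho[1]]
        pi_s5[patho[1]] = pi_pat[patho[0]]
        pi_groups[PATIENT_S5DOM] = pi_s5

    gt = GroundTruth(
        K=K,
        M=M,
        block_assign=block,
        pi=pi_groups,
        A=A_groups,
        mu=mu,
        Sigma=Sigma,
        attenuation=atten,
        healthy_states=config.healthy_states,
        pathological_states=config.pathological_states,
        seed=config.seed,
    )
    gt.validate()
    return gt


def _group_chain(K: int, active: list, stay: float, leak: float) -> np.ndarray:
    """Sticky chain concentrated on ``active``; other states escape quickly."""
    A = np.zeros((K, K))
    inactive = [s for s in range(K) if s not in active]
    for i in range(K):
        if i in active:
            others = [s for s in active if s != i]
            A[i, i] = stay
            spread = 1.0 - stay - (leak if inactive else 0.0)
            if others:
                A[i, others] = spread / len(others)
            else:
                A[i, i] += spread
            if inactive:
                A[i, inactive] = leak / len(inactive)
        else:
            A[i, i] = 0.2
            A[i, active] = 0.8 / len(active)
    return A


def _patient_chain(config: SimConfig, healthy: list, patho: list) -> np.ndarray:
    """Patient chain: healthy states drain into the pathological subset; for
    two pathological states the forward/back rates set a ~1:2 stationary
    split and a switching rate near the empirical 0.07-0.08 Hz scale."""
    K = config.K
    A = np.zeros((K, K))
    for i in healthy:
        A[i, i] = 0.2
        A[i, patho] = 0.8 / len(patho)
    if len(patho) == 2:
        p5, p6 = patho
        f, b, leak = config.patho_forward, config.patho_back, config.leak
        A[p5, p6] = f
        A[p5, healthy] = leak / len(healthy)
        A[p5, p5] = 1.0 - f - leak
        A[p6, p5] = b
        A[p6, healthy] = leak / len(healthy)
        A[p6, p6] = 1.0 - b - leak
    else:
        for i in patho:
            others = [s for s in patho if s != i]
            A[i, i] = config.stay
            spread = 1.0 - config.stay - config.leak
            if others:
                A[i, others] = spread / len(others)
            else:
                A[i, i] += spread
            A[i, healthy] = config.leak / len(healthy)
    return A


def sample_markov_chain(pi: np.ndarray, A: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
    """Sample a length-T path (1-based labels) from (pi, A)."""
    cum_pi = np.cumsum(pi)
    cum_A = np.cumsum(A, axis=1)
    u = rng.random(T)
    path = np.empty(T, dtype=np.int64)
    s = int(np.searchsorted(cum_pi, u[0] * cum_pi[-1]))
    path[0] = s
    for t in range(1, T):
        s = int(np.searchsorted(cum_A[s], u[t] * cum_A[s, -1]))
        path[t] = s
    return path + 1


def simulate_subject(
    gt: GroundTruth,
    group: str,
    T: int,
    TR: float,
    rng: np.random.Generator,
    subject_id: str = "sub-000",
    chain: str | None = None,
) -> SimulatedSubject:
    """Sample one subject: hidden path from the group's chain (or an
    explicit ``chain`` key, used for within-group heterogeneity), emissions
    from the state's Gaussian."""
    if group not in gt.A:
        raise ValueError(f"unknown group {group!r}; have {sorted(gt.A)}")
    if T < 2:
        raise ValueError("T must be at least 2")
    key = chain if chain is not None else group
    if key not in gt.A:
        raise ValueError(f"unknown chain {key!r}; have {sorted(gt.A)}")
    path = sample_markov_chain(gt.pi[key], gt.A[key], T, rng)
    chol = np.linalg.cholesky(gt.Sigma)
    z = rng.standard_normal((T, gt.M))
    series = gt.mu[path - 1] + np.einsum("tij,tj->ti", chol[path - 1], z)
    return SimulatedSubject(series=series, true_path=path, group=group, TR=TR, subject_id=subject_id)


def simulate_cohort(config: SimConfig) -> tuple[list[SimulatedSubject], GroundTruth]:
    """Simulate the full two-group cohort. Deterministic given ``config.seed``:
    the master seed is fanned out to one child stream per subject."""
    if config.n_controls < 1 or config.n_patients < 1:
        raise ValueError("need at least one subject per group")
    gt = make_ground_truth(config)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_controls + config.n_patients)
    n_s5dom = (round(config.s5_dominant_frac * config.n_patients)
               if PATIENT_S5DOM in gt.A else 0)
    subjects = []
    idx = 0
    for group, n in ((CONTROL, config.n_controls), (PATIENT, config.n_patients)):
        for j in range(n):
            rng = np.random.default_rng(children[idx])
            chain = PATIENT_S5DOM if (group == PATIENT and j < n_s5dom) else None
            subjects.append(
                simulate_subject(
                    gt, group, config.T, config.TR, rng,
                    subject_id=f"sub-{group[:3]}{j + 1:03d}", chain=chain,
                )
            )
            idx += 1
    return subjects, gt


def simulate_cognitive_scores(
    fo_target: np.ndarray,
    config: CognitiveSimConfig,
    rng: np.random.Generator,
):
    """Cognitive battery with planted occupancy predictors.

    Planted columns are ``weight * fo_target + N(0, noise_sd)``; every other
    column is a noisy copy of one of ``n_latent`` shared latent factors, so
    the battery carries the redundant-cluster structure that the feature
    reduction step is meant to collapse.

    Returns a pandas DataFrame (subjects x tests).
    """
    import pandas as pd

    fo_target = np.asarray(fo_target, dtype=float)
    n = fo_target.shape[0]
    names = config.test_names()
    if len(config.planted) > config.n_tests:
        raise ValueError("planted subset larger than the battery")
    unknown = set(config.planted) - set(names)
    if unknown:
        raise ValueError(f"planted names not in battery: {sorted(unknown)}")

    cols = {}
    factors = rng.standard_normal((n, max(config.n_latent, 1)))
    free = [t for t in names if t not in config.planted]
    for j, name in enumerate(names):
        if name in config.planted:
            w = config.planted[name]
            cols[name] = w * fo_target + rng.normal(0.0, config.noise_sd, size=n)
        else:
            fac = factors[:, free.index(name) % config.n_latent]
            cols[name] = fac + rng.normal(0.0, config.latent_noise_sd, size=n)
    return pd.DataFrame(cols, columns=names)


def simulate_lesions(
    n: int,
    rng: np.random.Generator,
    shape: tuple[int, int, int] = (20, 24, 20),
) -> list[LesionMask]:
    """Random ellipsoidal lesion masks on a common grid.

    The first axis is split at its midpoint into left/right hemispheres (the
    convention is recorded by the pipeline's sidecar metadata); the label is
    assigned from the mask centroid.
    """
    if n < 1:
        raise ValueError("need at least one lesion")
    if shape[0] % 2 != 0:
        raise ValueError("first axis must be even for the midpoint hemisphere split")
    grids = np.indices(shape)
    out = []
    for _ in range(n):
        center = np.array([rng.uniform(1, s - 2) for s in shape])
        radii = rng.uniform(1.5, min(shape) / 4.0, size=3)
        d2 = sum(((grids[a] - center[a]) / radii[a]) ** 2 for a in range(3))
        mask = (d2 <= 1.0).astype(np.uint8)
        if mask.sum() == 0:
            raise ValueError("lesion mask is empty")
        centroid0 = np.argwhere(mask)[:, 0].mean()
        hemi = "left" if centroid0 < shape[0] / 2 else "right"
        out.append(LesionMask(mask=mask, extension=int(mask.sum()), hemisphere=hemi))
    return out
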