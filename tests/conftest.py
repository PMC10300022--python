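import numpy as np
import pytest

from dynstates import GaussianHMM, SimConfig, simulate_cohort, zscore_and_concat


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group cohort at reduced scale, shared across tests."""
    cfg = SimConfig(K=4, M=15, n_blocks=5, n_controls=10, n_patients=10,
                    T=300, n_pathological=2, s5_dominant_frac=0.0, seed=202)
    subjects, gt = simulate_cohort(cfg)
    return cfg, subjects, gt


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """One fitted HMM on the shared cohort (reused to keep the suite fast)."""
    cfg, subjects, gt = small_cohort
    concat = zscore_and_concat(subjects)
    res = GaussianHMM(concat.matrix, concat.ranges, cfg.K).fit(
        n_restarts=2, max_iter=150, seed=7)
    return cfg, subjects, gt, concat, res
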