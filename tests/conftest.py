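import numpy as np
import pandas as pd
import pytest

from plexcal import SimulationConfig, generate_experiment


@pytest.fixture(scope="session")
def noiseless_config():
    """All stochastic corruption off: ratios should hit designed values."""
    return SimulationConfig(
        n_proteins=30,
        noise_sd_log2=0.0,
        impurity_spill=0.0,
        mcar_rate=0.0,
        mnar_rate=0.0,
        frac_regulated=0.0,
        batch_offsets_log2=(0.0, 0.0, 0.0, 0.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_experiment(noiseless_config):
    return generate_experiment(noiseless_config)


@pytest.fixture(scope="session")
def small_experiment():
    """Realistic small experiment (noise, batch offsets, missingness)."""
    return generate_experiment(SimulationConfig(n_proteins=60, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Independent step-up oracle: q_(i) = min_{j>=i} min(1, p_(j) m / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    best = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, min(1.0, p[i] * m / rank))
        q[i] = best
    return q
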