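import numpy as np
import pytest

from pace import GridSpec, SimulationConfig, simulate_cohort


@pytest.fixture
def grid8():
    return GridSpec((8, 8))


@pytest.fixture
def grid16():
    return GridSpec((16, 16))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_s2g_cohort():
    """A small labelled S2G cohort shared by fitting tests (16x16, N=120)."""
    cfg = SimulationConfig(grid_shape=(16, 16), n_maps=120, rs_kind="s2g",
                           volume_exponent=0.1, event_rate=0.3)
    return simulate_cohort(cfg, seed=42)
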