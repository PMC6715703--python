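import numpy as np
import pytest

from thermolimits import SyntheticConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated cohort shared across tests."""
    cfg = SyntheticConfig(n_asd=40, n_td=30, seed=123)
    subjects, trials = simulate_study(cfg)
    return cfg, subjects, trials


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
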