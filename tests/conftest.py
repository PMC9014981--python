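import numpy as np
import pytest

from cidyn.synth import SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_session():
    """A compact synthetic session shared by read-only tests."""
    cfg = SimConfig(n_trials=48, n_units=30, seed=7)
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
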