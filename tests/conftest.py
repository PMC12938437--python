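import numpy as np
import pytest

from bistfnet.synthgen import SimulationConfig, make_montage, simulate_session


@pytest.fixture(scope="session")
def small_montages():
    return make_montage(8, 8, seed=7)


@pytest.fixture(scope="session")
def small_session(small_montages):
    """Two-class session, 2 trials/class, default trial structure."""
    cfg = SimulationConfig(n_trials_per_class=2, seed=3, lag_s=5.0, snr_db=20.0)
    return simulate_session(cfg, small_montages), cfg


@pytest.fixture(scope="session")
def std_montages():
    """The full-size layouts: 30 EEG and 36 fNIRS channels."""
    return make_montage(30, 36, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
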