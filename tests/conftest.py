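import numpy as np
import pytest

from cspam import (
    BandSpec,
    SyntheticConfig,
    bandpass_filter_bank,
    simulate_session,
)

#: Small, fast session shared by unit tests: 16 channels at 128 Hz keeps the
#: filter bank (up to 20 Hz) valid while staying cheap.
SMALL = dict(n_trials=90, n_channels=16, sample_rate=128.0, snr=3.0)


@pytest.fixture(scope="session")
def small_session():
    return simulate_session(SyntheticConfig(seed=11, **SMALL))


@pytest.fixture(scope="session")
def small_banded(small_session):
    epochs, _ = small_session
    return bandpass_filter_bank(epochs)


@pytest.fixture(scope="session")
def null_session():
    cfg = SyntheticConfig(seed=12, **{**SMALL, "snr": 0.0})
    return simulate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def single_band():
    return BandSpec(((8.0, 12.0),))
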