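import numpy as np
import pytest

from betachoice.simulate import SimConfig, simulate_subject

#: Small montage subset used throughout the tests: includes the effect
#: channels (FC2, FC4), the SSEP channels (C4, CP4) and distant controls.
TEST_CHANNELS = ("Fz", "FC1", "FC2", "FC4", "Cz", "C4", "CP4", "Pz", "O1", "O2")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """One-block desk-scale subject at a reduced sampling rate."""
    return SimConfig(
        n_blocks=1, trials_per_block=160, fs=256.0, channels=TEST_CHANNELS, seed=7
    )


@pytest.fixture(scope="session")
def small_subject(small_config):
    """A completed (trials, epochs) pair shared by read-only tests."""
    return simulate_subject(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
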