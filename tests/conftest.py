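import numpy as np
import pytest

from cephgrowth import phantom as ph


@pytest.fixture(scope="session")
def spec():
    """Default phantom acquisition regime."""
    return ph.PhantomSpec()


@pytest.fixture(scope="session")
def quiet_spec():
    """Noise-free, jitter-free regime for geometry-level assertions."""
    return ph.PhantomSpec(noise_sd=0.0, jitter_sd=0.0, size_jitter_sd=0.0,
                          texture_amp=0.0, flip_prob=0.0,
                          intensity_gain_range=(1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
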