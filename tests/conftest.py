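import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_bvp():
    """20 s of a 1.2 Hz sinusoid at 256 Hz as a BvpSignal."""
    from ppgtherm.signals import BvpSignal

    t = np.arange(0, 20, 1 / 256)
    return BvpSignal(np.sin(2 * np.pi * 1.2 * t), rate=256.0)
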