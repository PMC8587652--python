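import numpy as np
import pytest
from hypothesis import settings

from kcdetect.core import Signal
from kcdetect.windows import make_window

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def complex_noise(rng):
    def _make(n=64):
        return rng.standard_normal(n) + 1j * rng.standard_normal(n)

    return _make


@pytest.fixture
def small_windows():
    return make_window("hamming", 17), make_window("hamming", 9)  # (g, h)


@pytest.fixture
def tone():
    """On-bin complex tone: (signal, v0, k0, n_freq)."""
    n_freq = 64
    k0 = 20
    v0 = k0 / (2 * n_freq)
    n = np.arange(256)
    return Signal(np.exp(2j * np.pi * v0 * n), fs=1.0), v0, k0, n_freq
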