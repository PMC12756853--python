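import numpy as np
import pytest

from spectralign import AxisHeader, SpectrumGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_axis(n=16, sw=1000.0, obs=100.0, origin_ppm=5.0):
    return AxisHeader(n=n, sw=sw, obs=obs, origin_ppm=origin_ppm)


@pytest.fixture
def small_grid(rng):
    """A 6x8 grid of random intensities with simple headers."""
    axes = [make_axis(n=6), make_axis(n=8, sw=2000.0, origin_ppm=10.0)]
    return SpectrumGrid(rng.normal(size=(6, 8)), axes)


@pytest.fixture
def volume(rng):
    axes = [make_axis(n=4, sw=500.0), make_axis(n=6), make_axis(n=8, sw=2000.0)]
    return SpectrumGrid(rng.normal(size=(4, 6, 8)), axes)
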