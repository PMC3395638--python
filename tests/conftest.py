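import numpy as np
import pytest

from wcms.types import Spectrum, Stage


def gaussian_spectrum(label, centers, heights, width=3.0, grid_step=1.0,
                      lo=2000.0, hi=20000.0, baseline=0.0, stage=Stage.RAW):
    """Sum-of-Gaussians profile on a uniform grid."""
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    y = np.full_like(grid, float(baseline))
    for c, h in zip(centers, heights):
        y += h * np.exp(-0.5 * ((grid - c) / width) ** 2)
    return Spectrum(label, grid, y, stage)


@pytest.fixture
def make_gaussian_spectrum():
    return gaussian_spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
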