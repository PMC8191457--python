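import numpy as np
import pytest

from locrad.preprocessing import MaskedVolume


def make_masked(data, window=(-20.0, 180.0), spacing=(1.0, 1.0, 1.0)):
    """MaskedVolume from an array that may already contain NaN markers."""
    return MaskedVolume(np.asarray(data, dtype=float), spacing, window)


def random_masked(rng, shape=(5, 5, 5), n_levels=4, missing_frac=0.2):
    """Random small volume with integer values 0..n_levels-1 and NaN holes.

    Window (0, n_levels-1) with bin width 1 maps value v to level v+1, so
    the gray-level alphabet is exactly n_levels.
    """
    data = rng.integers(0, n_levels, size=shape).astype(float)
    holes = rng.random(shape) < missing_frac
    data[holes] = np.nan
    if np.isnan(data).all():
        data[0, 0, 0] = 0.0
    return make_masked(data, window=(0.0, float(n_levels - 1)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
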