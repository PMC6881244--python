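import numpy as np
import pytest

from hipporad.io import Mask, Volume


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    data = np.asarray(data, dtype=float)
    affine = np.diag(list(spacing) + [1.0])
    return Volume(data=data, spacing=spacing, affine=affine)


def make_mask(data, spacing=(1.0, 1.0, 1.0), side=None):
    return Mask(data=np.asarray(data), spacing=spacing, side=side)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_level_grid(rng, max_shape=(8, 8, 4), G=8, mask_fraction=0.8):
    """A random quantized grid: levels 1..G with ~20% masked-out voxels."""
    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    levels = rng.integers(1, G + 1, size=shape).astype(np.int32)
    drop = rng.random(shape) > mask_fraction
    levels[drop] = 0
    return levels
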