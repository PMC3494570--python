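import numpy as np
import pytest

from petgtv import BinaryMask, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_mask(arr, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return BinaryMask(np.asarray(arr, dtype=bool), spacing, origin)


def make_grid(arr, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return VoxelGrid(np.asarray(arr, dtype=float), spacing, origin)


@pytest.fixture
def mask_factory():
    return make_mask


@pytest.fixture
def grid_factory():
    return make_grid
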