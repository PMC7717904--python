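import numpy as np
import pytest

from hcrquant.grids import Mask3D, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_grid(rng):
    """Random 8×16×16 stack with anisotropic spacing."""
    data = rng.uniform(0, 100, size=(8, 16, 16)).astype(np.float32)
    return VoxelGrid(data=data, spacing=(2.5, 0.9, 0.9), channel="target")


def make_profile_grid(profile, spacing=(1.0, 1.0, 1.0)):
    """A (1, 1, N) grid whose AP profile equals ``profile`` exactly,
    with an all-true mask."""
    arr = np.asarray(profile, dtype=np.float64)[None, None, :]
    grid = VoxelGrid(data=arr, spacing=spacing, channel="target")
    mask = Mask3D(data=np.ones_like(arr, dtype=bool), spacing=spacing)
    return grid, mask
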