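"""Shared fixtures: small deterministic volumes, masks and phantom configs."""

import numpy as np
import pytest

from periroi.io_volumes import ImageVolume, MaskVolume
from periroi.phantom import PhantomConfig


def sphere_mask(shape, center, radius_vox, spacing=(1.0, 1.0, 1.0)):
    """Digital ball: voxels whose center lies within radius of `center` (index units)."""
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return MaskVolume(data=d2 <= radius_vox**2, spacing=spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    return ImageVolume(data=rng.normal(100.0, 10.0, (16, 16, 16)))


@pytest.fixture
def center_sphere():
    return sphere_mask((16, 16, 16), (8, 8, 8), 4)


@pytest.fixture
def fast_phantom_config():
    """Small, single-center phantom for unit tests (model-free statistics)."""
    return PhantomConfig(grid_shape=(40, 40, 40), n_centers=1)


def random_mask(rng, shape, n_seeds=3, spacing=(1.0, 1.0, 1.0)):
    """A small random blobby mask: a few seed voxels dilated by a random radius."""
    from scipy import ndimage

    data = np.zeros(shape, dtype=bool)
    idx = tuple(rng.integers(1, s - 1, size=n_seeds) for s in shape)
    data[idx] = True
    data = ndimage.binary_dilation(data, iterations=int(rng.integers(0, 3)))
    return MaskVolume(data=data, spacing=spacing)
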