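import numpy as np
import pytest

from ctradiomics.core import ImageVolume, RoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def unit_spacing():
    return (1.0, 1.0, 1.0)


@pytest.fixture
def ct_spacing():
    """The study's voxel geometry: 0.68 x 0.68 x 1.00 mm."""
    return (0.68, 0.68, 1.00)


def make_volume(data, spacing=(1.0, 1.0, 1.0), label=""):
    return ImageVolume(data=np.asarray(data, dtype=float), spacing=spacing,
                       algorithm_label=label)


def make_mask(mask, spacing=(1.0, 1.0, 1.0)):
    return RoiMask(mask=np.asarray(mask, dtype=bool), spacing=spacing)


def digital_ball(radius_voxels, spacing=(1.0, 1.0, 1.0), pad=2):
    """Binary ball of the given radius (voxel units) on an isotropic index grid."""
    n = 2 * radius_voxels + 1 + 2 * pad
    c = (n - 1) / 2.0
    idx = np.indices((n, n, n))
    d2 = sum((idx[i] - c) ** 2 for i in range(3))
    return make_mask(d2 <= radius_voxels**2, spacing=spacing)
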