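import numpy as np
import pytest
from scipy import ndimage

from mrikit import BinaryMask, Geometry, PhantomSpec, make_structural_phantom


@pytest.fixture
def geometry():
    return Geometry(voxel_x=0.1, voxel_y=0.1, slice_thickness=0.5, slice_gap=0.1)


@pytest.fixture
def phantom_noiseless():
    spec = PhantomSpec(shape=(64, 64, 10), noise_sigma=0.0, seed=0)
    return make_structural_phantom(spec)


@pytest.fixture
def dilated_outline(phantom_noiseless):
    """A rough brain outline: ground truth dilated by 3 voxels."""
    _, masks = phantom_noiseless
    return BinaryMask(
        ndimage.binary_dilation(masks["brain"].data, iterations=3),
        parent_id="phantom",
    )


def random_mask(rng, shape):
    return BinaryMask(rng.random(shape) < rng.uniform(0.05, 0.6))


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
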