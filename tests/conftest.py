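import numpy as np
import pytest

from fcdens.volumes import GrayMatterMask, VolumeGrid


@pytest.fixture
def grid3mm():
    return VolumeGrid((8, 8, 8), (3.0, 3.0, 3.0))


@pytest.fixture
def full_mask(grid3mm):
    return GrayMatterMask(grid3mm, np.ones(grid3mm.dims, dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_mask_coords(rng, n_vox, dims=(20, 20, 20), voxel_mm=3.0):
    """Pick n_vox distinct voxels of a grid; return (indices, world coords)."""
    flat = rng.choice(np.prod(dims), size=n_vox, replace=False)
    idx = np.stack(np.unravel_index(flat, dims), axis=1)
    return idx, idx * voxel_mm
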