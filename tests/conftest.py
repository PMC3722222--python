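import numpy as np
import pytest

from ringscape.io_formats import BinaryMask, VolumeGrid
from ringscape.synthetic_data import RingLayout, make_phantom_atlas, phantom_domain


@pytest.fixture
def small_grid():
    return VolumeGrid((8, 8, 4), np.eye(4))


@pytest.fixture(scope="session")
def phantom():
    """Default phantom: 16x16x6 grid, ring in the z 1..4 slab."""
    grid = VolumeGrid((16, 16, 6), np.eye(4))
    layout = RingLayout(z_min=1, z_max=4)
    atlas = make_phantom_atlas(grid, layout, seed=0)
    domain = phantom_domain(grid, layout)
    return grid, layout, atlas, domain


def random_mask(grid, rng, density=0.3):
    return BinaryMask(grid, rng.random(grid.shape) < density)
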