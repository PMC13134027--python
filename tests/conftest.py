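import numpy as np
import pytest

from osteomap.compartments import LayerSpec, compartment_map_for_skull
from osteomap.grids import BinaryMask, VolumeGrid
from osteomap.phantoms import ShellGeometry, SlabGeometry, make_skull, slab_cavity


@pytest.fixture(scope="session")
def shell_grid():
    return VolumeGrid(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def shell_skull(shell_grid):
    c = 15.5
    return make_skull(shell_grid, ShellGeometry((c, c, c), outer_r_mm=13.0, inner_r_mm=10.0))


@pytest.fixture(scope="session")
def shell_cmap(shell_skull):
    return compartment_map_for_skull(shell_skull, LayerSpec(thickness_mm=5.0))


@pytest.fixture(scope="session")
def slab_masks():
    """Half-space skull x<=2, declared cavity x in [3,10] on a 1-mm 12x8x8 grid."""
    grid = VolumeGrid(shape=(12, 8, 8), spacing=(1.0, 1.0, 1.0))
    geom = SlabGeometry(axis=0, bone_range=(0, 2), cavity_range=(3, 10))
    return make_skull(grid, geom), slab_cavity(grid, geom)


def random_mask(grid: VolumeGrid, density: float, seed: int) -> BinaryMask:
    rng = np.random.default_rng(seed)
    return BinaryMask(grid=grid, voxels=rng.random(grid.shape) < density)
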