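import numpy as np
import pytest

from cordlesion.phantoms import PhantomConfig, make_cord_and_atlas
from cordlesion.volumes_io import SoftMask, VoxelGrid


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def cord_and_atlas(phantom_config):
    return make_cord_and_atlas(phantom_config)


@pytest.fixture(scope="session")
def cord(cord_and_atlas):
    return cord_and_atlas[0]


@pytest.fixture(scope="session")
def atlas(cord_and_atlas):
    return cord_and_atlas[1]


@pytest.fixture
def unit_grid():
    return VoxelGrid((10, 10, 10), (1.0, 1.0, 1.0))


def random_soft_mask(grid: VoxelGrid, rng: np.random.Generator, density: float = 0.3) -> SoftMask:
    vals = rng.random(grid.shape) * (rng.random(grid.shape) < density)
    return SoftMask(grid, vals)
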