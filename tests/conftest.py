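import numpy as np
import pytest
import scipy.ndimage as ndi

from optmorph.io_formats import Volume


def build_toy_volume(graded: bool = False) -> Volume:
    """Three-stratum stained toy volume (10**3 voxels).

    10 core voxels at grey 30, exactly 50 shell voxels at grey 90 adjacent
    to the core, remaining tissue at grey 150.  With ``graded=True`` six
    additional rind voxels at grey 45 sit between core and shell so the
    high-expression mask is strictly nested inside the moderate mask.
    """
    grid = np.full((10, 10, 10), 150.0)
    core = np.zeros(grid.shape, dtype=bool)
    core[4:6, 3:8, 5] = True                      # 2 x 5 x 1 = 10 voxels
    dilated = ndi.binary_dilation(core, np.ones((3, 3, 3), bool)) & ~core
    idx = np.argwhere(dilated)
    grid[tuple(idx[:50].T)] = 90.0
    if graded:
        grid[tuple(idx[50:56].T)] = 45.0
    grid[core] = 30.0
    return Volume(grid=grid, spacing=(10.0, 10.0, 10.0))


@pytest.fixture
def toy_volume() -> Volume:
    return build_toy_volume(graded=False)


@pytest.fixture
def graded_toy_volume() -> Volume:
    return build_toy_volume(graded=True)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
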