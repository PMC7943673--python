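import numpy as np
import pytest

from sirtdose import ContourMask, CountVolume, DoseMap, VoxelGrid


@pytest.fixture
def grid16():
    return VoxelGrid((16, 16, 16), (4.42, 4.42, 4.42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_mask(grid: VoxelGrid, sel: np.ndarray, label="mask") -> ContourMask:
    return ContourMask(grid, sel.astype(np.uint8), label=label)


def sphere_mask(grid: VoxelGrid, center_vox, radius_vox, label="sphere") -> ContourMask:
    idx = np.indices(grid.shape, dtype=float)
    d2 = sum((idx[i] - center_vox[i]) ** 2 for i in range(3))
    return make_mask(grid, d2 <= radius_vox**2, label=label)


def uniform_dose(grid: VoxelGrid, value: float) -> DoseMap:
    return DoseMap(grid, np.full(grid.shape, value))


def counts_volume(grid: VoxelGrid, values) -> CountVolume:
    return CountVolume(grid, np.asarray(values, dtype=float))
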