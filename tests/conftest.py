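import numpy as np
import pytest

from anacom.imaging import LesionMask, VolumeGrid


@pytest.fixture
def small_grid() -> VolumeGrid:
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = (-6.0, -6.0, -6.0)
    return VolumeGrid(dims=(6, 6, 6), affine=affine)


def make_mask(grid: VolumeGrid, subject_id: str, voxels) -> LesionMask:
    data = np.zeros(grid.dims, dtype=bool)
    for v in voxels:
        data[tuple(v)] = True
    return LesionMask(subject_id=subject_id, grid=grid, data=data)


def random_masks(grid: VolumeGrid, n: int, rng, p: float = 0.3):
    return [
        LesionMask(subject_id=f"s{i}", grid=grid,
                   data=rng.random(grid.dims) < p)
        for i in range(n)
    ]


@pytest.fixture
def mask_factory():
    return make_mask


@pytest.fixture
def random_mask_factory():
    return random_masks
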