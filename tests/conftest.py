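import numpy as np
import pytest

from mubafire import Mask, VoxelGrid


def ball_mask(grid: VoxelGrid, center=None, radius=None) -> Mask:
    shape = np.array(grid.shape)
    center = np.asarray(center if center is not None else (shape - 1) / 2.0)
    radius = radius if radius is not None else 0.4 * shape.min()
    ii = np.meshgrid(*[np.arange(n, dtype=float) for n in grid.shape], indexing="ij")
    r2 = sum((ii[a] - center[a]) ** 2 for a in range(3))
    return Mask(grid, r2 <= radius**2)


@pytest.fixture
def grid24():
    return VoxelGrid((24, 24, 24))


@pytest.fixture
def sphere_mask(grid24):
    return ball_mask(grid24, radius=9.5)


@pytest.fixture
def ellipsoid_mask(grid24):
    ii = np.meshgrid(*[np.arange(24, dtype=float)] * 3, indexing="ij")
    c = 11.5
    d = ((ii[0] - c) / 10) ** 2 + ((ii[1] - c) / 7) ** 2 + ((ii[2] - c) / 9) ** 2
    return Mask(grid24, d <= 1.0)


@pytest.fixture
def blob_mask(grid24):
    """Brain-like irregular blob: union of offset balls."""
    m = ball_mask(grid24, center=(11, 12, 11), radius=8).values
    m |= ball_mask(grid24, center=(15, 10, 13), radius=6).values
    m |= ball_mask(grid24, center=(8, 14, 12), radius=5).values
    return Mask(grid24, m)


@pytest.fixture
def holed_mask(sphere_mask):
    """Spherical mask with an interior cavity punched out."""
    hole = ball_mask(sphere_mask.grid, center=(14, 11, 12), radius=3).values
    return Mask(sphere_mask.grid, sphere_mask.values & ~hole)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
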