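import numpy as np
import pytest

from tumorseg3d import ImageVolume, LevelSetField, sphere_sdf


@pytest.fixture
def unit_volume():
    """A small constant volume on a unit grid."""
    return ImageVolume(np.full((16, 16, 16), 100.0), (1.0, 1.0, 1.0))


@pytest.fixture
def sphere_field():
    """Exact SDF of a radius-10 sphere on a 40^3 unit grid."""
    return sphere_sdf((40, 40, 40), (1.0, 1.0, 1.0), (19.5, 19.5, 19.5), 10.0)


@pytest.fixture
def blob_field():
    """A smooth non-SDF phi with a blob-shaped interior (for reinit tests)."""
    x, y, z = np.meshgrid(*(np.arange(n, dtype=float) for n in (24, 24, 24)),
                          indexing="ij")
    r = np.sqrt((x - 11.5) ** 2 + 1.3 * (y - 11.5) ** 2 + 0.8 * (z - 11.5) ** 2)
    phi = np.tanh((r - 6.0 + 1.5 * np.sin(0.5 * x)) / 4.0) * 5.0
    return LevelSetField(phi, (1.0, 1.0, 1.0))


def brute_force_signed_distance(phi: np.ndarray, spacing, points_mm: np.ndarray):
    """Exhaustive oracle: signed Euclidean distance from every voxel center to
    a zero-crossing point cloud (O(n*m), test-sized grids only)."""
    sp = np.asarray(spacing)
    shape = phi.shape
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    centers = np.stack([ii * sp[0], jj * sp[1], kk * sp[2]], axis=-1).reshape(-1, 3)
    d = np.sqrt(((centers[:, None, :] - points_mm[None, :, :]) ** 2).sum(-1)).min(1)
    return np.where(phi.reshape(-1) < 0, -d, d).reshape(shape)
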