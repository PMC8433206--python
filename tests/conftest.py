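"""Shared fixtures: small phantoms and digitized solids used across modules."""

import numpy as np
import pytest

from islet3d import PhantomSpec, VoxelGrid, generate_cuboid


def ball_mask(radius_vox: float, pad: int = 2) -> np.ndarray:
    """Digitized solid ball (voxel-centre rule), centred on a voxel centre."""
    n = 2 * int(np.ceil(radius_vox)) + 1 + 2 * pad
    c = (n - 1) / 2
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    return (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= radius_vox**2


def ellipsoid_mask(semi_axes_vox, pad: int = 2) -> np.ndarray:
    """Digitized axis-aligned ellipsoid; semi-axes in voxels, order (z, y, x)."""
    a, b, c = semi_axes_vox
    n = tuple(2 * int(np.ceil(s)) + 1 + 2 * pad for s in (a, b, c))
    ctr = tuple((k - 1) / 2 for k in n)
    zz, yy, xx = np.meshgrid(*[np.arange(k) for k in n], indexing="ij")
    return (
        ((zz - ctr[0]) / a) ** 2 + ((yy - ctr[1]) / b) ** 2 + ((xx - ctr[2]) / c) ** 2
        <= 1.0
    )


@pytest.fixture(scope="session")
def small_phantom():
    """60 well-separated islets in a 128³ cuboid; no vessels/holes."""
    spec = PhantomSpec(
        shape_voxels=(128, 128, 128),
        n_islets=60,
        seed=1,
        vessel_spec=None,
        hole_spec=None,
    )
    signal, anatomy, truth = generate_cuboid(spec)
    return spec, signal, anatomy, truth


@pytest.fixture()
def empty_grid():
    return VoxelGrid(np.zeros((32, 32, 32), dtype=np.float32), 21.0)
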