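"""Per-object 3D morphometry: volume, centroid, axis lengths, sphericity.

Axis lengths are *world-axis-aligned ellipsoid-equivalent lengths*: for a
solid ellipsoid of semi-axis a, the variance of the coordinate of a
uniformly sampled interior point along that axis is a²/5, so the length
along world axis w is reconstructed as 2·√(5·var_w).  The mean 3D diameter
is the average of the x, y and z lengths.  A Sheppard-type correction
(h²/12 per axis, h the voxel size) accounts for the spread of mass within
each voxel, so a single voxel reports an axis length close to the voxel
size rather than zero.

Surface area is measured on a marching-cubes isosurface of the zero-padded
binary mask at level 0.5; sphericity is Wadell's
Ψ = π^(1/3) · (6V)^(2/3) / A (1 for a sphere, smaller for elongated
objects).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import marching_cubes, mesh_surface_area

from .core import IsletRecord, VoxelGrid
from .segment import LabelVolume

__all__ = [
    "object_features",
    "surface_area",
    "surface_area_of_mask",
    "sphericity",
]


def sphericity(volume_um3: float, surface_area_um2: float) -> float:
    """Wadell sphericity Ψ = π^(1/3) (6V)^(2/3) / A."""
    if volume_um3 <= 0 or surface_area_um2 <= 0:
        raise ValueError("volume and surface area must be positive")
    return float(np.pi ** (1 / 3) * (6 * volume_um3) ** (2 / 3) / surface_area_um2)


#: pre-smoothing width (voxels) for surface extraction.  Marching cubes on
#: a raw binary mask tracks the voxel staircase and overestimates the area
#: of smooth solids by a persistent ~8%; a light Gaussian anti-aliasing
#: before extracting the 0.5 isosurface recovers sphere areas to well
#: within the discretization error.  Objects too small to survive the
#: smoothing (peak below the iso-level) fall back to the raw mask.
_SURFACE_SMOOTH_SIGMA = 0.8


def surface_area_of_mask(mask: np.ndarray, voxel_size_um: float) -> float:
    """Marching-cubes surface area (µm²) of a binary mask.

    The mask is zero-padded so objects touching the border still produce a
    closed surface, lightly smoothed (see ``_SURFACE_SMOOTH_SIGMA``), and
    triangulated at level 0.5.  In the coarse limit (an object of a few
    voxels) the isosurface is much smaller than the blocky voxel surface:
    a single voxel yields the dual octahedron with area √3·h².
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no surface")
    padded = np.pad(mask, 2).astype(np.float32)
    if _SURFACE_SMOOTH_SIGMA > 0:
        smoothed = ndi.gaussian_filter(padded, _SURFACE_SMOOTH_SIGMA)
        if smoothed.max() > 0.5:
            padded = smoothed
    h = float(voxel_size_um)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=(h, h, h))
    return float(mesh_surface_area(verts, faces))


def surface_area(labels: LabelVolume, islet_id: int) -> float:
    """Surface area (µm²) of one labelled object."""
    sl = ndi.find_objects((labels.labels == islet_id).astype(np.int8))
    if not sl or sl[0] is None:
        raise ValueError(f"label {islet_id} not present")
    mask = labels.labels[sl[0]] == islet_id
    return surface_area_of_mask(mask, labels.voxel_size_um)


def object_features(
    labels: LabelVolume,
    grid: VoxelGrid | None = None,
    cuboid_id: str = "",
) -> list[IsletRecord]:
    """Morphometry for every labelled object.

    ``grid`` is only used for metadata consistency checks; all geometric
    features derive from the label lattice and its voxel size.  Empty label
    ids (possible after external edits) are skipped with a warning.
    """
    if grid is not None and grid.shape != labels.shape:
        raise ValueError("labels are not aligned to the grid")
    h = labels.voxel_size_um
    voxel_vol = h**3
    lab = labels.labels
    records: list[IsletRecord] = []
    slices = ndi.find_objects(lab)
    for islet_id, sl in enumerate(slices, start=1):
        if sl is None:
            warnings.warn(f"label {islet_id} is empty; skipped", stacklevel=2)
            continue
        mask = lab[sl] == islet_id
        n = int(mask.sum())
        zz, yy, xx = np.nonzero(mask)
        # voxel centres in local physical coordinates (x, y, z µm)
        xs = (xx + sl[2].start + 0.5) * h
        ys = (yy + sl[1].start + 0.5) * h
        zs = (zz + sl[0].start + 0.5) * h
        centroid = (float(xs.mean()), float(ys.mean()), float(zs.mean()))
        # ellipsoid-equivalent axis lengths with intra-voxel variance term
        axes = tuple(
            float(2.0 * np.sqrt(5.0 * (np.var(c) + h**2 / 12.0))) for c in (xs, ys, zs)
        )
        volume = n * voxel_vol
        area = surface_area_of_mask(mask, h)
        records.append(
            IsletRecord(
                islet_id=islet_id,
                cuboid_id=cuboid_id,
                centroid_local_um=centroid,
                voxel_count=n,
                volume_um3=volume,
                axis_length_um=axes,
                mean_diameter_um=float(np.mean(axes)),
                surface_area_um2=area,
                sphericity=sphericity(volume, area),
                bbox_min_vox=(int(zz.min() + sl[0].start),
                              int(yy.min() + sl[1].start),
                              int(xx.min() + sl[2].start)),
                bbox_max_vox=(int(zz.max() + sl[0].start),
                              int(yy.max() + sl[1].start),
                              int(xx.max() + sl[2].start)),
            )
        )
    return records
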