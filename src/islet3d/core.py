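"""Core containers shared by every pipeline stage.

Conventions used throughout the package:

* Arrays are indexed ``(z, y, x)`` (the natural order of a TIFF stack of
  z-pages).
* All *physical* coordinates are ``(x, y, z)`` in micrometres, measured
  from the cuboid (or organ) corner.  A voxel with index ``(iz, iy, ix)``
  has its centre at ``origin + (ix + 0.5, iy + 0.5, iz + 0.5) * voxel_size``.
* Voxels are isotropic, as produced by optical projection tomography.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "CuboidMeta",
    "IsletRecord",
    "ClusterRecord",
]


@dataclass
class VoxelGrid:
    """One channel of one tissue cuboid: a 3D scalar lattice with physical scale.

    Parameters
    ----------
    data
        ``(nz, ny, nx)`` array of intensities (any float/int dtype).
    voxel_size_um
        Isotropic voxel edge length in micrometres.
    origin_um
        Physical position ``(x, y, z)`` of the cuboid corner in the organ
        frame, micrometres.  ``(0, 0, 0)`` for a stand-alone cuboid.
    """

    data: np.ndarray
    voxel_size_um: float
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        self.origin_um = tuple(float(v) for v in self.origin_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.voxel_size_um) ** 3

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """New grid sharing this grid's scale/origin metadata."""
        return VoxelGrid(data, self.voxel_size_um, self.origin_um)

    def index_to_um(self, indices_zyx: np.ndarray) -> np.ndarray:
        """Voxel indices ``(iz, iy, ix)`` -> physical voxel centres ``(x, y, z)`` µm."""
        idx = np.atleast_2d(np.asarray(indices_zyx, dtype=float))
        xyz = (idx[:, ::-1] + 0.5) * self.voxel_size_um + np.asarray(self.origin_um)
        return xyz

    def um_to_index(self, xyz_um: np.ndarray) -> np.ndarray:
        """Physical points ``(x, y, z)`` µm -> fractional voxel indices ``(iz, iy, ix)``."""
        xyz = np.atleast_2d(np.asarray(xyz_um, dtype=float))
        idx = (xyz - np.asarray(self.origin_um)) / self.voxel_size_um - 0.5
        return idx[:, ::-1]


@dataclass
class CuboidMeta:
    """Identity and placement of one tissue cuboid within the organ slicing grid.

    ``origin_um`` must equal ``grid_ijk * grid_pitch_um`` (elementwise, within
    one voxel): the slicing matrix cuts on a regular grid and placement is
    metadata-driven, not registration-driven.
    """

    cuboid_id: str
    grid_ijk: tuple[int, int, int]  # (i, j, k) along (x, y, z)
    origin_um: tuple[float, float, float]  # (x, y, z)
    shape_voxels: tuple[int, int, int]  # (nz, ny, nx)
    voxel_size_um: float
    grid_pitch_um: tuple[float, float, float] = (5500.0, 3300.0, 5500.0)

    def __post_init__(self) -> None:
        self.grid_ijk = tuple(int(v) for v in self.grid_ijk)
        self.origin_um = tuple(float(v) for v in self.origin_um)
        self.shape_voxels = tuple(int(v) for v in self.shape_voxels)
        if any(n <= 0 for n in self.shape_voxels):
            raise ValueError("shape_voxels must be positive")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size (x, y, z) of the cuboid in µm."""
        nz, ny, nx = self.shape_voxels
        return (nx * self.voxel_size_um, ny * self.voxel_size_um, nz * self.voxel_size_um)

    def to_dict(self) -> dict:
        return {
            "cuboid_id": self.cuboid_id,
            "grid_ijk": list(self.grid_ijk),
            "origin_um": list(self.origin_um),
            "shape_voxels": list(self.shape_voxels),
            "voxel_size_um": self.voxel_size_um,
            "grid_pitch_um": list(self.grid_pitch_um),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CuboidMeta":
        return cls(
            cuboid_id=d["cuboid_id"],
            grid_ijk=tuple(d["grid_ijk"]),
            origin_um=tuple(d["origin_um"]),
            shape_voxels=tuple(d["shape_voxels"]),
            voxel_size_um=d["voxel_size_um"],
            grid_pitch_um=tuple(d.get("grid_pitch_um", (5500.0, 3300.0, 5500.0))),
        )


@dataclass
class IsletRecord:
    """One segmented islet with its 3D morphometry.

    Lengths are µm, volumes µm³, areas µm².  ``axis_length_um`` are
    world-axis-aligned ellipsoid-equivalent lengths; ``mean_diameter_um`` is
    their average — the mean 3D diameter used to size islets.
    Sphericity is Wadell's Ψ = π^(1/3) (6V)^(2/3) / A, 1 for a sphere.
    """

    islet_id: int
    cuboid_id: str
    centroid_local_um: tuple[float, float, float]
    voxel_count: int
    volume_um3: float
    axis_length_um: tuple[float, float, float]
    mean_diameter_um: float
    surface_area_um2: float
    sphericity: float
    centroid_global_um: Optional[tuple[float, float, float]] = None
    hemorrhage_volume_um3: float = 0.0
    cluster_id: Optional[int] = None
    size_category: Optional[int] = None
    # local voxel-index bounding box (z, y, x), inclusive; used for
    # boundary-object merging when stitching
    bbox_min_vox: Optional[tuple[int, int, int]] = None
    bbox_max_vox: Optional[tuple[int, int, int]] = None

    def to_flat_dict(self) -> dict:
        d = {
            "islet_id": self.islet_id,
            "cuboid_id": self.cuboid_id,
            "x_um": self.centroid_local_um[0],
            "y_um": self.centroid_local_um[1],
            "z_um": self.centroid_local_um[2],
            "voxel_count": self.voxel_count,
            "volume_um3": self.volume_um3,
            "axis_x_um": self.axis_length_um[0],
            "axis_y_um": self.axis_length_um[1],
            "axis_z_um": self.axis_length_um[2],
            "mean_diameter_um": self.mean_diameter_um,
            "surface_area_um2": self.surface_area_um2,
            "sphericity": self.sphericity,
            "hemorrhage_volume_um3": self.hemorrhage_volume_um3,
            "cluster_id": self.cluster_id,
            "size_category": self.size_category,
        }
        if self.centroid_global_um is not None:
            d["gx_um"], d["gy_um"], d["gz_um"] = self.centroid_global_um
        if self.bbox_min_vox is not None:
            d["bbox_zmin"], d["bbox_ymin"], d["bbox_xmin"] = self.bbox_min_vox
            d["bbox_zmax"], d["bbox_ymax"], d["bbox_xmax"] = self.bbox_max_vox
        return d


@dataclass
class ClusterRecord:
    """One single-linkage spatial cluster of islets.

    ``cls`` is "HIDR" (high islet density region) when the member count
    strictly exceeds the configured threshold, else "LIDR".
    """

    cluster_id: int
    member_ids: list[int]
    count: int
    cls: str  # "HIDR" | "LIDR"
    centroid_um: tuple[float, float, float]
    bbox_min_um: tuple[float, float, float]
    bbox_max_um: tuple[float, float, float]
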