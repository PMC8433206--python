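"""Synthetic tissue-cuboid phantoms with exact ground truth.

Real organ-scale datasets of antibody-labelled pancreas are not publicly
deposited, so every downstream stage of this package is exercised against
phantoms generated here: ellipsoidal bright islets on a textured
autofluorescence (AF) background, tube-shaped hyper-AF vessels, hypointense
holes (lumens, fat), bright red-blood-cell (RBC) blobs inside islets,
spatial islet clusters near the tissue periphery, and multi-cuboid
partitions of a single organ.

Geometry is rasterized with a *voxel-centre-in-solid* rule: a voxel belongs
to an object iff its centre lies inside the analytic solid.  This is the
simplest rule with a provable volume bound — for convex solids the voxel
count times the voxel volume converges to the analytic volume as the solid
grows relative to the voxel.

Two channels are emulated, mirroring a near-infrared OPT scan of an
insulin-immunolabelled cuboid:

``signal``
    dim tissue background + bright islets (+ noise); holes are darker than
    background.
``anatomy``
    textured tissue AF + bright vessel walls + bright RBC blobs inside
    islets (+ noise); holes are darker than background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial.transform import Rotation

from .core import CuboidMeta, VoxelGrid

__all__ = [
    "PhantomSpec",
    "ClusterSpec",
    "VesselSpec",
    "HoleSpec",
    "OrganSpec",
    "PlantedObject",
    "GroundTruth",
    "PhantomPlacementError",
    "render_ellipsoid",
    "generate_cuboid",
    "generate_organ",
]

_MAX_PLACEMENT_RETRIES = 10_000
_CHUNK_VOXELS = 4_000_000  # rasterization slab size cap


class PhantomPlacementError(RuntimeError):
    """Raised when an object cannot be placed without overlap."""


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------


@dataclass
class ClusterSpec:
    """Planted islet clusters (emulating high islet density regions).

    Each member islet is placed within ``cluster_radius_um`` of an already
    placed member, so the planted cluster is a single connected component
    under single-linkage at any cutoff ≥ cluster_radius_um.

    Cluster members draw their diameters from ``diameter_dist`` (median µm,
    geometric SD), smaller by default than scattered islets: two islets can
    only sit with centres ≤ cluster_radius_um apart without overlapping
    when their radii sum to less than that distance, so dense regions are
    necessarily regions of small-to-medium islets.
    """

    n_clusters: int = 1
    islets_per_cluster: int = 120
    cluster_radius_um: float = 250.0
    peripheral: bool = True
    diameter_dist: tuple[float, float] = (75.0, 1.2)


@dataclass
class VesselSpec:
    """Hyper-AF tubes (vessel/duct walls) in the anatomy channel."""

    n_tubes: int = 2
    radius_um: float = 60.0
    wall_intensity: float = 0.8


@dataclass
class HoleSpec:
    """Hypointense regions: spherical (fat) and tubular (lumen) holes."""

    n_spherical: int = 2
    n_tubular: int = 1
    sphere_diameter_um: tuple[float, float] = (150.0, 300.0)
    tube_radius_um: tuple[float, float] = (40.0, 70.0)


@dataclass
class PhantomSpec:
    """Full description of one synthetic cuboid.

    Defaults mirror the imaging conditions the pipeline targets: 21 µm
    isotropic voxels and islets whose mean 3D diameter is log-normally
    distributed around a 110 µm median — the average human islet diameter
    the pipeline itself is parameterized with.  ``diameter_dist`` is
    (median µm, geometric SD); diameters below ``min_diameter_um``
    (3 voxels by default, the scale below which an object is not reliably
    represented on the lattice) are resampled.
    """

    shape_voxels: tuple[int, int, int] = (128, 128, 128)  # (nz, ny, nx)
    voxel_size_um: float = 21.0
    n_islets: int = 50
    diameter_dist: tuple[float, float] = (110.0, 1.5)
    min_diameter_um: float = 63.0
    anisotropy_max: float = 1.5
    cluster_spec: Optional[ClusterSpec] = None
    vessel_spec: Optional[VesselSpec] = None
    hole_spec: Optional[HoleSpec] = None
    hemorrhage_fraction: float = 0.0
    background_level: float = 0.3  # anatomy tissue AF
    signal_background: float = 0.08  # unlabelled tissue in the signal channel
    islet_intensity: float = 1.0
    rbc_intensity: float = 0.9
    hole_intensity: float = 0.02
    texture_amplitude: float = 0.15
    noise_sd: float = 0.02
    placement_gap_um: float = 42.0  # min free gap between object surfaces (2 voxels)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.shape_voxels):
            raise ValueError("shape_voxels must be positive")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if self.n_islets < 0:
            raise ValueError("n_islets must be non-negative")
        if self.diameter_dist[0] <= 0 or self.diameter_dist[1] < 1:
            raise ValueError("diameter_dist must be (median>0, geometric sd>=1)")
        if self.anisotropy_max < 1:
            raise ValueError("anisotropy_max must be >= 1")
        if not 0 <= self.hemorrhage_fraction <= 1:
            raise ValueError("hemorrhage_fraction must be in [0, 1]")

    @property
    def extent_um(self) -> np.ndarray:
        """(x, y, z) physical size of the cuboid."""
        nz, ny, nx = self.shape_voxels
        return np.array([nx, ny, nz], dtype=float) * self.voxel_size_um


@dataclass
class OrganSpec:
    """A multi-cuboid 'organ': an ellipsoidal tissue body cut on a regular grid.

    The organ is generated as one contiguous volume and partitioned into
    ``grid_shape`` cuboids of ``cuboid_shape_voxels`` each, emulating the
    slicing-matrix workflow in which cm³ cuboids carry recorded grid
    coordinates for later re-assembly.  Grid pitch therefore equals the
    cuboid physical extent and is by construction a multiple of the voxel
    size.
    """

    grid_shape: tuple[int, int, int] = (2, 2, 2)  # cuboids along (x, y, z)
    cuboid_shape_voxels: tuple[int, int, int] = (64, 64, 64)  # (nz, ny, nx)
    voxel_size_um: float = 21.0
    n_islets: int = 100
    diameter_dist: tuple[float, float] = (110.0, 1.5)
    min_diameter_um: float = 63.0
    anisotropy_max: float = 1.5
    cluster_spec: Optional[ClusterSpec] = None
    vessel_spec: Optional[VesselSpec] = None
    hole_spec: Optional[HoleSpec] = None
    hemorrhage_fraction: float = 0.0
    organ_fill: float = 0.95  # organ ellipsoid semi-axes / half-domain
    background_level: float = 0.3
    signal_background: float = 0.08
    islet_intensity: float = 1.0
    rbc_intensity: float = 0.9
    hole_intensity: float = 0.02
    texture_amplitude: float = 0.15
    noise_sd: float = 0.02
    placement_gap_um: float = 42.0
    seed: int = 0

    @property
    def full_shape_voxels(self) -> tuple[int, int, int]:
        gz = self.grid_shape[2] * self.cuboid_shape_voxels[0]
        gy = self.grid_shape[1] * self.cuboid_shape_voxels[1]
        gx = self.grid_shape[0] * self.cuboid_shape_voxels[2]
        return (gz, gy, gx)


# --------------------------------------------------------------------------
# planted objects
# --------------------------------------------------------------------------

_TUBE_KINDS = frozenset({"vessel", "hole_tube"})


@dataclass
class PlantedObject:
    """One analytic solid planted in a phantom.

    ``kind`` is one of ``islet | vessel | hole_sphere | hole_tube | rbc_blob``.
    Ellipsoids use ``semi_axes_um`` directly; tubes are finite cylinders with
    ``semi_axes_um = (r, r, L/2)``.  ``rotation`` columns are the object's
    principal axes in the world (x, y, z) frame.
    """

    obj_id: int
    kind: str
    center_um: np.ndarray
    semi_axes_um: np.ndarray
    rotation: np.ndarray
    intensity: float
    analytic_volume_um3: float
    voxel_count: int = 0
    truncated: bool = False
    cluster_id: Optional[int] = None
    parent_islet: Optional[int] = None

    def contains(self, pts_xyz: np.ndarray) -> np.ndarray:
        """Voxel-centre-in-solid test for an (n, 3) array of points (µm)."""
        u = (pts_xyz - self.center_um) @ self.rotation  # object frame
        a, b, c = self.semi_axes_um
        if self.kind in _TUBE_KINDS:
            return (np.abs(u[:, 2]) <= c) & (u[:, 0] ** 2 / a**2 + u[:, 1] ** 2 / b**2 <= 1.0)
        return (u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2 + (u[:, 2] / c) ** 2 <= 1.0

    def bbox_half_extent_um(self) -> np.ndarray:
        """Axis-aligned half extents of the solid's bounding box, per world axis."""
        R = self.rotation
        a, b, c = self.semi_axes_um
        if self.kind in _TUBE_KINDS:
            axis = R[:, 2]
            r = max(a, b)
            return np.abs(axis) * c + r * np.sqrt(np.clip(1.0 - axis**2, 0.0, 1.0)) + r * 1e-9
        return np.sqrt((R * np.array([a, b, c])) ** 2 @ np.ones(3))

    def axis_lengths_um(self) -> np.ndarray:
        """World-axis ellipsoid-equivalent lengths (x, y, z), µm.

        For a solid ellipsoid the coordinate variance along world axis w is
        Σ_j R²_wj a_j² / 5, so the equivalent length is 2·√(Σ_j R²_wj a_j²)
        — the same definition the morphometry stage measures, making truth
        and measurement directly comparable for rotated objects.
        """
        return 2.0 * np.sqrt((self.rotation**2) @ (self.semi_axes_um**2))

    @property
    def mean_diameter_um(self) -> float:
        """Mean 3D diameter: average of the x, y, z axis lengths."""
        return float(self.axis_lengths_um().mean())

    @property
    def bounding_radius_um(self) -> float:
        a, b, c = self.semi_axes_um
        if self.kind in _TUBE_KINDS:
            return float(np.hypot(max(a, b), c))
        return float(max(a, b, c))


@dataclass
class GroundTruth:
    """Catalog of every planted object in one phantom (or organ)."""

    objects: list[PlantedObject] = field(default_factory=list)
    voxel_size_um: float = 21.0
    shape_voxels: tuple[int, int, int] = (0, 0, 0)

    def __len__(self) -> int:
        return len(self.objects)

    def of_kind(self, kind: str) -> list[PlantedObject]:
        return [o for o in self.objects if o.kind == kind]

    @property
    def islets(self) -> list[PlantedObject]:
        return self.of_kind("islet")

    def islet_centers_um(self) -> np.ndarray:
        islets = self.islets
        if not islets:
            return np.empty((0, 3))
        return np.array([o.center_um for o in islets])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for o in self.objects:
            rows.append(
                {
                    "obj_id": o.obj_id,
                    "kind": o.kind,
                    "x_um": o.center_um[0],
                    "y_um": o.center_um[1],
                    "z_um": o.center_um[2],
                    "semi_a_um": o.semi_axes_um[0],
                    "semi_b_um": o.semi_axes_um[1],
                    "semi_c_um": o.semi_axes_um[2],
                    "analytic_volume_um3": o.analytic_volume_um3,
                    "voxel_count": o.voxel_count,
                    "truncated": o.truncated,
                    "cluster_id": o.cluster_id,
                    "parent_islet": o.parent_islet,
                    **{f"R{i}{j}": o.rotation[i, j] for i in range(3) for j in range(3)},
                }
            )
        cols = [
            "obj_id", "kind", "x_um", "y_um", "z_um",
            "semi_a_um", "semi_b_um", "semi_c_um",
            "analytic_volume_um3", "voxel_count", "truncated",
            "cluster_id", "parent_islet",
        ] + [f"R{i}{j}" for i in range(3) for j in range(3)]
        return pd.DataFrame(rows, columns=cols)


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------


def _voxel_index_box(obj: PlantedObject, shape: tuple[int, int, int], voxel: float,
                     origin_um: np.ndarray) -> Optional[tuple[slice, slice, slice]]:
    """Voxel-index bounding box (z, y, x slices) of the object inside the grid."""
    half = obj.bbox_half_extent_um()
    lo_um = obj.center_um - half - origin_um
    hi_um = obj.center_um + half - origin_um
    lo = np.floor(lo_um / voxel - 0.5).astype(int)  # (x, y, z) voxel indices
    hi = np.ceil(hi_um / voxel + 0.5).astype(int)
    nz, ny, nx = shape
    lims = np.array([nx, ny, nz])
    lo = np.clip(lo, 0, lims)
    hi = np.clip(hi, 0, lims)
    if np.any(hi <= lo):
        return None
    return (slice(lo[2], hi[2]), slice(lo[1], hi[1]), slice(lo[0], hi[0]))


def _iter_slabs(box: tuple[slice, slice, slice]):
    """Split a z/y/x index box into z-slabs of bounded voxel count."""
    zs, ys, xs = box
    per_slice = max(1, (ys.stop - ys.start) * (xs.stop - xs.start))
    step = max(1, _CHUNK_VOXELS // per_slice)
    for z0 in range(zs.start, zs.stop, step):
        yield (slice(z0, min(z0 + step, zs.stop)), ys, xs)


def _rasterize(obj: PlantedObject, data: np.ndarray, voxel: float,
               origin_um: np.ndarray, mode: str = "max") -> int:
    """Paint the object into ``data``; returns the number of voxels inside.

    ``mode='max'`` combines with existing values by maximum (emissive
    objects); ``mode='set'`` overwrites (carving holes).
    """
    box = _voxel_index_box(obj, data.shape, voxel, origin_um)
    if box is None:
        return 0
    count = 0
    for slab in _iter_slabs(box):
        zs, ys, xs = slab
        zz, yy, xx = np.meshgrid(
            np.arange(zs.start, zs.stop),
            np.arange(ys.start, ys.stop),
            np.arange(xs.start, xs.stop),
            indexing="ij",
        )
        pts = np.stack(
            [
                (xx.ravel() + 0.5) * voxel + origin_um[0],
                (yy.ravel() + 0.5) * voxel + origin_um[1],
                (zz.ravel() + 0.5) * voxel + origin_um[2],
            ],
            axis=1,
        )
        inside = obj.contains(pts).reshape(zz.shape)
        n = int(inside.sum())
        if n:
            sub = data[slab]
            if mode == "max":
                sub[inside] = np.maximum(sub[inside], obj.intensity)
            else:
                sub[inside] = obj.intensity
            count += n
    return count


def _count_in_box(obj: PlantedObject, box: tuple[slice, slice, slice],
                  voxel: float, origin_um: np.ndarray) -> int:
    """Count voxels of ``obj`` whose centres fall inside a voxel-index box."""
    own = _voxel_index_box(obj, (box[0].stop, box[1].stop, box[2].stop), voxel, origin_um)
    if own is None:
        return 0
    inter = tuple(
        slice(max(a.start, b.start), min(a.stop, b.stop)) for a, b in zip(own, box)
    )
    if any(s.stop <= s.start for s in inter):
        return 0
    count = 0
    for slab in _iter_slabs(inter):
        zs, ys, xs = slab
        zz, yy, xx = np.meshgrid(
            np.arange(zs.start, zs.stop),
            np.arange(ys.start, ys.stop),
            np.arange(xs.start, xs.stop),
            indexing="ij",
        )
        pts = np.stack(
            [
                (xx.ravel() + 0.5) * voxel + origin_um[0],
                (yy.ravel() + 0.5) * voxel + origin_um[1],
                (zz.ravel() + 0.5) * voxel + origin_um[2],
            ],
            axis=1,
        )
        count += int(obj.contains(pts).sum())
    return count


def render_ellipsoid(
    grid: VoxelGrid,
    center_um,
    semi_axes_um,
    orientation: Optional[np.ndarray] = None,
    intensity: float = 1.0,
) -> VoxelGrid:
    """Rasterize an ellipsoid into ``grid`` (in place), combining by maximum.

    A voxel is set iff its centre lies inside the ellipsoid.  An ellipsoid
    entirely outside the grid triggers a warning and leaves the grid
    untouched.  Returns ``grid`` for chaining.
    """
    semi = np.asarray(semi_axes_um, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("semi-axes must be positive")
    if not np.isfinite(intensity):
        raise ValueError("intensity must be finite")
    R = np.eye(3) if orientation is None else np.asarray(orientation, dtype=float)
    obj = PlantedObject(
        obj_id=-1,
        kind="islet",
        center_um=np.asarray(center_um, dtype=float),
        semi_axes_um=semi,
        rotation=R,
        intensity=float(intensity),
        analytic_volume_um3=float(4.0 / 3.0 * np.pi * semi.prod()),
    )
    n = _rasterize(obj, grid.data, grid.voxel_size_um, np.asarray(grid.origin_um))
    if n == 0:
        box = _voxel_index_box(obj, grid.shape, grid.voxel_size_um, np.asarray(grid.origin_um))
        if box is None:
            warnings.warn("ellipsoid lies entirely outside the grid; nothing rendered",
                          stacklevel=2)
    return grid


# --------------------------------------------------------------------------
# placement
# --------------------------------------------------------------------------


def _sample_islet_geometry(rng: np.random.Generator, diameter_dist, min_diameter_um,
                           anisotropy_max) -> tuple[np.ndarray, np.ndarray]:
    """Semi-axes (µm) and rotation for one islet."""
    median, gsd = diameter_dist
    for _ in range(1000):
        d = float(rng.lognormal(np.log(median), np.log(gsd)))
        if d >= min_diameter_um:
            break
    else:  # pragma: no cover - degenerate distributions only
        d = min_diameter_um
    ratios = rng.uniform(1.0, anisotropy_max, size=3)
    semi = ratios / ratios.mean() * (d / 2.0)
    R = Rotation.random(rng=rng).as_matrix()
    return semi, R


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-12), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


class _Placer:
    """Rejection-sampling placement of non-overlapping solids.

    Overlap is forbidden pairwise via bounding radii plus a free gap, which
    is conservative but guarantees a ≥ gap separation between surfaces —
    the property the segmentation tests rely on.
    """

    def __init__(self, extent_um: np.ndarray, gap_um: float,
                 organ_center: Optional[np.ndarray] = None,
                 organ_semi: Optional[np.ndarray] = None):
        self.extent = extent_um
        self.gap = gap_um
        self.centers: list[np.ndarray] = []
        self.radii: list[float] = []
        self.segments: list[tuple[np.ndarray, np.ndarray, float]] = []
        self.organ_center = organ_center
        self.organ_semi = organ_semi

    def _inside_domain(self, center: np.ndarray, r: float) -> bool:
        if np.any(center - r < 0) or np.any(center + r > self.extent):
            return False
        if self.organ_center is not None:
            u = (center - self.organ_center) / self.organ_semi
            margin = r / float(self.organ_semi.min())
            return float(np.linalg.norm(u)) <= max(1.0 - margin, 0.0)
        return True

    def _clear(self, center: np.ndarray, r: float) -> bool:
        for c, cr in zip(self.centers, self.radii):
            if np.linalg.norm(center - c) < r + cr + self.gap:
                return False
        for a, b, tr in self.segments:
            if _point_segment_distance(center, a, b) < r + tr + self.gap:
                return False
        return True

    def commit(self, center: np.ndarray, r: float) -> None:
        self.centers.append(center)
        self.radii.append(r)

    def commit_segment(self, a: np.ndarray, b: np.ndarray, r: float) -> None:
        self.segments.append((a, b, r))

    def place_ball(self, rng: np.random.Generator, r: float, kind: str,
                   near: Optional[np.ndarray] = None, near_max: float = 0.0,
                   min_norm_radius: float = 0.0) -> np.ndarray:
        """Find a centre for a solid of bounding radius ``r``.

        ``near`` restricts the centre to within ``near_max`` µm of a point
        (cluster growth); ``min_norm_radius`` restricts it to the outer
        shell of the organ ellipsoid (peripheral placement).
        """
        for _ in range(_MAX_PLACEMENT_RETRIES):
            if near is not None:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                dist = rng.uniform(0.0, near_max)
                center = near + direction * dist
            else:
                center = rng.uniform(0, 1, size=3) * self.extent
            if not self._inside_domain(center, r):
                continue
            if min_norm_radius > 0 and self.organ_center is not None:
                u = (center - self.organ_center) / self.organ_semi
                if np.linalg.norm(u) < min_norm_radius:
                    continue
            if self._clear(center, r):
                return center
        raise PhantomPlacementError(
            f"could not place object of kind '{kind}' (r={r:.1f} µm) "
            f"after {_MAX_PLACEMENT_RETRIES} attempts"
        )


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def _tube_rotation(direction: np.ndarray) -> np.ndarray:
    """Rotation whose third column is the (unit) tube axis."""
    d = direction / np.linalg.norm(direction)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return np.column_stack([u, v, d])


def _plant_objects(spec, extent_um: np.ndarray, rng: np.random.Generator,
                   organ_center=None, organ_semi=None) -> list[PlantedObject]:
    """Sample all object geometries (no rasterization yet)."""
    placer = _Placer(extent_um, spec.placement_gap_um, organ_center, organ_semi)
    objects: list[PlantedObject] = []
    next_id = 0

    def add(kind, center, semi, R, intensity, volume, cluster_id=None, parent=None):
        nonlocal next_id
        objects.append(
            PlantedObject(
                obj_id=next_id, kind=kind, center_um=np.asarray(center, float),
                semi_axes_um=np.asarray(semi, float), rotation=np.asarray(R, float),
                intensity=float(intensity), analytic_volume_um3=float(volume),
                cluster_id=cluster_id, parent_islet=parent,
            )
        )
        next_id += 1
        return objects[-1]

    # vessels and hole-tubes first: long objects are the hardest to place
    if spec.vessel_spec is not None and spec.vessel_spec.n_tubes > 0:
        vs = spec.vessel_spec
        for _ in range(vs.n_tubes):
            _add_tube(placer, rng, extent_um, vs.radius_um, "vessel",
                      add, vs.wall_intensity)
    if spec.hole_spec is not None:
        hs = spec.hole_spec
        for _ in range(hs.n_tubular):
            r = rng.uniform(*hs.tube_radius_um)
            _add_tube(placer, rng, extent_um, r, "hole_tube", add, spec.hole_intensity)
        for _ in range(hs.n_spherical):
            d = rng.uniform(*hs.sphere_diameter_um)
            center = placer.place_ball(rng, d / 2, "hole_sphere")
            placer.commit(center, d / 2)
            add("hole_sphere", center, (d / 2,) * 3, np.eye(3), spec.hole_intensity,
                4 / 3 * np.pi * (d / 2) ** 3)

    # clustered islets
    cluster_islets: list[PlantedObject] = []
    if spec.cluster_spec is not None and spec.cluster_spec.n_clusters > 0:
        cs = spec.cluster_spec
        for cid in range(cs.n_clusters):
            members: list[np.ndarray] = []
            for m in range(cs.islets_per_cluster):
                semi, R = _sample_islet_geometry(
                    rng, cs.diameter_dist, spec.min_diameter_um, spec.anisotropy_max)
                r = float(semi.max())
                if m == 0:
                    min_nr = 0.8 if (cs.peripheral and organ_center is not None) else 0.0
                    center = placer.place_ball(rng, r, "islet (cluster seed)",
                                               min_norm_radius=min_nr)
                else:
                    anchor = members[int(rng.integers(len(members)))]
                    center = placer.place_ball(rng, r, "islet (cluster member)",
                                               near=anchor, near_max=cs.cluster_radius_um)
                placer.commit(center, r)
                members.append(center)
                obj = add("islet", center, semi, R, spec.islet_intensity,
                          4 / 3 * np.pi * semi.prod(), cluster_id=cid)
                cluster_islets.append(obj)

    # scattered islets
    n_scattered = spec.n_islets - len(cluster_islets)
    for _ in range(max(0, n_scattered)):
        semi, R = _sample_islet_geometry(
            rng, spec.diameter_dist, spec.min_diameter_um, spec.anisotropy_max)
        r = float(semi.max())
        center = placer.place_ball(rng, r, "islet")
        placer.commit(center, r)
        add("islet", center, semi, R, spec.islet_intensity, 4 / 3 * np.pi * semi.prod())

    # RBC blobs inside a fraction of islets
    if spec.hemorrhage_fraction > 0:
        islets = [o for o in objects if o.kind == "islet"]
        n_hem = int(round(spec.hemorrhage_fraction * len(islets)))
        chosen = rng.choice(len(islets), size=n_hem, replace=False) if n_hem else []
        for i in np.sort(np.asarray(chosen, dtype=int)):
            host = islets[int(i)]
            semi = host.semi_axes_um * 0.35
            offset = (rng.uniform(-0.2, 0.2, size=3)) * host.semi_axes_um.min()
            add("rbc_blob", host.center_um + offset, semi, host.rotation,
                spec.rbc_intensity, 4 / 3 * np.pi * semi.prod(),
                parent=host.obj_id)
    return objects


def _add_tube(placer: _Placer, rng: np.random.Generator, extent_um: np.ndarray,
              radius: float, kind: str, add, intensity: float) -> None:
    for _ in range(_MAX_PLACEMENT_RETRIES):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        mid = rng.uniform(0.25, 0.75, size=3) * extent_um
        half_len = rng.uniform(0.25, 0.45) * float(extent_um.min())
        a, b = mid - direction * half_len, mid + direction * half_len
        if np.any(a - radius < 0) or np.any(a + radius > extent_um):
            continue
        if np.any(b - radius < 0) or np.any(b + radius > extent_um):
            continue
        ok = True
        for c, cr in zip(placer.centers, placer.radii):
            if _point_segment_distance(c, a, b) < cr + radius + placer.gap:
                ok = False
                break
        if ok:
            placer.commit_segment(a, b, radius)
            R = _tube_rotation(direction)
            L = 2 * half_len
            add(kind, mid, (radius, radius, half_len), R, intensity,
                np.pi * radius**2 * L)
            return
    raise PhantomPlacementError(
        f"could not place object of kind '{kind}' after {_MAX_PLACEMENT_RETRIES} attempts")


def _render_channels(objects: list[PlantedObject], shape, voxel: float,
                     spec, rng: np.random.Generator,
                     organ_center=None, organ_semi=None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize all objects into signal and anatomy channels."""
    origin = np.zeros(3)
    signal = np.full(shape, spec.signal_background, dtype=np.float32)
    anatomy = np.full(shape, spec.background_level, dtype=np.float32)

    if spec.texture_amplitude > 0:
        texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, size=shape), sigma=1.5)
        sd = texture.std()
        if sd > 0:
            anatomy *= 1.0 + spec.texture_amplitude * (texture / sd).astype(np.float32)

    if organ_center is not None:
        zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        pts_x = (xx + 0.5) * voxel
        pts_y = (yy + 0.5) * voxel
        pts_z = (zz + 0.5) * voxel
        u = (
            ((pts_x - organ_center[0]) / organ_semi[0]) ** 2
            + ((pts_y - organ_center[1]) / organ_semi[1]) ** 2
            + ((pts_z - organ_center[2]) / organ_semi[2]) ** 2
        )
        outside = u > 1.0
        anatomy[outside] = 0.0
        signal[outside] = 0.0
        del zz, yy, xx, pts_x, pts_y, pts_z, u

    # emissive objects (max-combine), then carve holes (overwrite)
    for o in objects:
        if o.kind == "islet":
            o.voxel_count = _rasterize(o, signal, voxel, origin, mode="max")
        elif o.kind == "vessel":
            o.voxel_count = _rasterize(o, anatomy, voxel, origin, mode="max")
        elif o.kind == "rbc_blob":
            o.voxel_count = _rasterize(o, anatomy, voxel, origin, mode="max")
    for o in objects:
        if o.kind in ("hole_sphere", "hole_tube"):
            o.voxel_count = _rasterize(o, anatomy, voxel, origin, mode="set")
            _rasterize(o, signal, voxel, origin, mode="set")

    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
        anatomy = anatomy + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
    return np.clip(signal, 0, None), np.clip(anatomy, 0, None)


def generate_cuboid(spec: PhantomSpec) -> tuple[VoxelGrid, VoxelGrid, GroundTruth]:
    """Generate one synthetic cuboid: (signal, anatomy, ground truth).

    Deterministic: the same ``spec.seed`` yields bit-identical volumes and
    truth.  Raises :class:`PhantomPlacementError` when a requested object
    count cannot be placed without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    extent = spec.extent_um
    objects = _plant_objects(spec, extent, rng)
    signal, anatomy = _render_channels(objects, spec.shape_voxels,
                                       spec.voxel_size_um, spec, rng)
    truth = GroundTruth(objects=objects, voxel_size_um=spec.voxel_size_um,
                        shape_voxels=tuple(spec.shape_voxels))
    return (
        VoxelGrid(signal, spec.voxel_size_um),
        VoxelGrid(anatomy, spec.voxel_size_um),
        truth,
    )


def generate_organ(spec: OrganSpec) -> tuple[list[tuple[VoxelGrid, VoxelGrid, CuboidMeta]], GroundTruth]:
    """Generate a multi-cuboid organ and cut it on the slicing grid.

    The organ (an ellipsoid of tissue inscribed in the full grid) is
    rendered once as a contiguous volume and then partitioned, so the
    per-cuboid arrays are exact sub-blocks of the organ arrays: stitching
    them back (see :mod:`islet3d.stitch`) reproduces the organ volume
    bit-identically.  Each cuboid's truth lists the global objects whose
    rasterization intersects it; objects whose voxels span a cut carry
    ``truncated=True`` in every part.
    """
    rng = np.random.default_rng(spec.seed)
    full_shape = spec.full_shape_voxels
    voxel = spec.voxel_size_um
    nz, ny, nx = full_shape
    extent = np.array([nx, ny, nz], dtype=float) * voxel
    organ_center = extent / 2.0
    organ_semi = extent / 2.0 * spec.organ_fill

    objects = _plant_objects(spec, extent, rng, organ_center, organ_semi)
    signal, anatomy = _render_channels(objects, full_shape, voxel, spec, rng,
                                       organ_center, organ_semi)
    global_truth = GroundTruth(objects=objects, voxel_size_um=voxel,
                               shape_voxels=full_shape)

    cz, cy, cx = spec.cuboid_shape_voxels
    gx, gy, gz = spec.grid_shape
    pitch = (cx * voxel, cy * voxel, cz * voxel)
    cuboids = []
    for k in range(gz):
        for j in range(gy):
            for i in range(gx):
                box = (slice(k * cz, (k + 1) * cz),
                       slice(j * cy, (j + 1) * cy),
                       slice(i * cx, (i + 1) * cx))
                origin = (i * pitch[0], j * pitch[1], k * pitch[2])
                meta = CuboidMeta(
                    cuboid_id=f"c{i}{j}{k}",
                    grid_ijk=(i, j, k),
                    origin_um=origin,
                    shape_voxels=(cz, cy, cx),
                    voxel_size_um=voxel,
                    grid_pitch_um=pitch,
                )
                sig = VoxelGrid(signal[box].copy(), voxel, origin)
                ana = VoxelGrid(anatomy[box].copy(), voxel, origin)
                cuboids.append((sig, ana, meta))
    return cuboids, global_truth


def cuboid_truth(global_truth: GroundTruth, meta: CuboidMeta) -> GroundTruth:
    """Restrict organ-level truth to one cuboid.

    An object belongs to the cuboid iff at least one of its voxels (by the
    voxel-centre rule) lies inside; ``truncated`` marks parts whose
    in-cuboid voxel count is below the object's total.  ``voxel_count`` in
    the returned objects is the in-cuboid count; centres stay global.
    """
    voxel = meta.voxel_size_um
    ox, oy, oz = meta.origin_um
    i0, j0, k0 = int(round(ox / voxel)), int(round(oy / voxel)), int(round(oz / voxel))
    cz, cy, cx = meta.shape_voxels
    box = (slice(k0, k0 + cz), slice(j0, j0 + cy), slice(i0, i0 + cx))
    out: list[PlantedObject] = []
    for o in global_truth.objects:
        n = _count_in_box(o, box, voxel, np.zeros(3))
        if n == 0:
            continue
        part = PlantedObject(
            obj_id=o.obj_id, kind=o.kind, center_um=o.center_um.copy(),
            semi_axes_um=o.semi_axes_um.copy(), rotation=o.rotation.copy(),
            intensity=o.intensity, analytic_volume_um3=o.analytic_volume_um3,
            voxel_count=n, truncated=(n < o.voxel_count),
            cluster_id=o.cluster_id, parent_islet=o.parent_islet,
        )
        out.append(part)
    return GroundTruth(objects=out, voxel_size_um=voxel,
                       shape_voxels=tuple(meta.shape_voxels))
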