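"""Re-assembly of per-cuboid catalogs and volumes into the organ frame.

Cuboids are cut on a regular slicing grid with recorded (i, j, k) grid
coordinates, so placement is pure metadata arithmetic: a point at local
position ``p`` in cuboid ``c`` sits at ``p + origin(c)`` in the organ
frame.  No image registration is performed (the grid is assumed to cut
ideally — true for phantoms, an approximation for real tissue).

``merge_catalogs`` concatenates per-cuboid islet catalogs with globally
unique ids.  Optionally (off by default, matching a workflow in which
boundary objects were counted per cuboid), objects in adjacent cuboids
whose bounding boxes touch the shared cut face and whose centroids are
laterally within a tolerance are merged: volumes summed, centroid
volume-weighted.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .core import CuboidMeta, IsletRecord, VoxelGrid

__all__ = ["to_global", "merge_catalogs", "assemble_volume"]

_AXIS_OF_DIM = {0: "x", 1: "y", 2: "z"}


def to_global(records: Sequence[IsletRecord], meta: CuboidMeta) -> list[IsletRecord]:
    """Attach global centroids: global = local + cuboid origin (exactly invertible)."""
    origin = np.asarray(meta.origin_um)
    out = []
    for r in records:
        if r.cuboid_id and r.cuboid_id != meta.cuboid_id:
            raise ValueError(
                f"record belongs to cuboid '{r.cuboid_id}', not '{meta.cuboid_id}'")
        g = tuple(np.asarray(r.centroid_local_um) + origin)
        out.append(replace(r, cuboid_id=meta.cuboid_id, centroid_global_um=g))
    return out


def _touches_face(rec: IsletRecord, meta: CuboidMeta, dim: int, side: int,
                  tol_vox: int = 1) -> bool:
    """Does the record's bounding box reach the cuboid face on world axis ``dim``?

    ``side`` +1 means the high face, -1 the low face.  ``dim`` indexes
    (x, y, z); bounding boxes are stored (z, y, x).
    """
    if rec.bbox_min_vox is None:
        return False
    zyx_dim = 2 - dim
    n = meta.shape_voxels[zyx_dim]
    if side > 0:
        return rec.bbox_max_vox[zyx_dim] >= n - 1 - tol_vox + 1
    return rec.bbox_min_vox[zyx_dim] <= tol_vox - 1


def merge_catalogs(
    catalogs: Sequence[Sequence[IsletRecord]],
    metas: Sequence[CuboidMeta],
    merge_boundary: bool = False,
    lateral_tol_um: float = 55.0,
) -> list[IsletRecord]:
    """Concatenate per-cuboid catalogs into one organ catalog.

    Records receive globally unique ``islet_id`` values and global
    centroids.  With ``merge_boundary``, objects cut by the slicing grid
    are re-joined: candidates are pairs in grid-adjacent cuboids that both
    touch the shared face (bounding box within one voxel of it) and whose
    global centroids are within ``lateral_tol_um`` in the face plane.
    Merged volumes are summed and centroids volume-weighted; sphericity and
    axis lengths of merged objects are kept from the larger part (a merged
    surface is not re-triangulated).
    """
    ids = [m.cuboid_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cuboid ids")
    if len(catalogs) != len(metas):
        raise ValueError("one catalog per meta required")
    vs = {m.voxel_size_um for m in metas}
    if len(vs) > 1:
        raise ValueError("voxel sizes differ across cuboids")

    flat: list[tuple[IsletRecord, CuboidMeta]] = []
    for cat, meta in zip(catalogs, metas):
        for r in to_global(cat, meta):
            flat.append((r, meta))
    for new_id, (r, _) in enumerate(flat, start=1):
        r.islet_id = new_id
    if not merge_boundary:
        return [r for r, _ in flat]

    # union-find over boundary-touching pairs in grid-adjacent cuboids
    parent = list(range(len(flat)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    meta_by_ijk = {tuple(m.grid_ijk): m for m in metas}
    by_cuboid: dict[str, list[int]] = {}
    for idx, (r, m) in enumerate(flat):
        by_cuboid.setdefault(m.cuboid_id, []).append(idx)

    for m in metas:
        for dim in range(3):
            nb_ijk = list(m.grid_ijk)
            nb_ijk[dim] += 1
            nb = meta_by_ijk.get(tuple(nb_ijk))
            if nb is None:
                continue
            lateral = [d for d in range(3) if d != dim]
            for ia in by_cuboid.get(m.cuboid_id, []):
                ra = flat[ia][0]
                if not _touches_face(ra, m, dim, +1):
                    continue
                for ib in by_cuboid.get(nb.cuboid_id, []):
                    rb = flat[ib][0]
                    if not _touches_face(rb, nb, dim, -1):
                        continue
                    ga = np.asarray(ra.centroid_global_um)
                    gb = np.asarray(rb.centroid_global_um)
                    if np.hypot(*(ga[lateral] - gb[lateral])) <= lateral_tol_um:
                        ri, rj = find(ia), find(ib)
                        if ri != rj:
                            parent[rj] = ri

    groups: dict[int, list[IsletRecord]] = {}
    for idx, (r, _) in enumerate(flat):
        groups.setdefault(find(idx), []).append(r)
    merged: list[IsletRecord] = []
    for new_id, root in enumerate(sorted(groups), start=1):
        parts = groups[root]
        if len(parts) == 1:
            parts[0].islet_id = new_id
            merged.append(parts[0])
            continue
        parts.sort(key=lambda r: -r.volume_um3)
        total_vol = sum(p.volume_um3 for p in parts)
        w = np.array([p.volume_um3 for p in parts]) / total_vol
        g = tuple((np.array([p.centroid_global_um for p in parts]) * w[:, None]).sum(axis=0))
        rep = replace(
            parts[0],
            islet_id=new_id,
            centroid_global_um=g,
            voxel_count=sum(p.voxel_count for p in parts),
            volume_um3=total_vol,
            hemorrhage_volume_um3=sum(p.hemorrhage_volume_um3 for p in parts),
        )
        merged.append(rep)
    return merged


def assemble_volume(
    cuboids: Sequence[VoxelGrid],
    metas: Sequence[CuboidMeta],
    fill_value: float = 0.0,
) -> VoxelGrid:
    """Paste per-cuboid volumes at their grid offsets into one organ volume.

    Placements must be voxel-aligned and non-overlapping (cuboids are
    non-overlapping by construction of the slicing grid); unfilled space
    is ``fill_value``.  Overlap or misalignment raises with the offending
    cuboid named.
    """
    if len(cuboids) != len(metas):
        raise ValueError("one grid per meta required")
    if not cuboids:
        raise ValueError("nothing to assemble")
    vs = {m.voxel_size_um for m in metas}
    if len(vs) > 1:
        raise ValueError("voxel sizes differ across cuboids")
    voxel = metas[0].voxel_size_um

    starts = []
    for g, m in zip(cuboids, metas):
        if g.shape != tuple(m.shape_voxels):
            raise ValueError(f"cuboid '{m.cuboid_id}': data shape {g.shape} "
                             f"does not match meta {m.shape_voxels}")
        off = np.asarray(m.origin_um) / voxel  # (x, y, z) voxels
        if not np.allclose(off, np.round(off), atol=1e-6):
            raise ValueError(f"cuboid '{m.cuboid_id}' origin is not voxel-aligned")
        starts.append(np.round(off).astype(int)[::-1])  # (z, y, x)

    shapes = np.array([g.shape for g in cuboids])
    stops = np.array(starts) + shapes
    if np.any(np.array(starts) < 0):
        bad = metas[int(np.argmin(np.array(starts).min(axis=1)))].cuboid_id
        raise ValueError(f"cuboid '{bad}' extends outside the organ frame")
    full_shape = tuple(stops.max(axis=0))
    out = np.full(full_shape, fill_value, dtype=cuboids[0].data.dtype)
    filled = np.zeros(full_shape, dtype=bool)
    for g, m, a, b in zip(cuboids, metas, starts, stops):
        box = tuple(slice(int(lo), int(hi)) for lo, hi in zip(a, b))
        if filled[box].any():
            raise ValueError(f"cuboid '{m.cuboid_id}' overlaps a previously placed cuboid")
        out[box] = g.data
        filled[box] = True
    return VoxelGrid(out, voxel, (0.0, 0.0, 0.0))
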