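"""Reading and writing the package's on-disk formats.

Volumes are multi-page TIFF stacks (one page per z-slice) with the voxel
size stored ImageJ-style (µm spacing + x/y resolution), cuboid placement
metadata is JSON, and object catalogs / ground truth are CSV.  See
``docs/catalog_schema.md`` for column names and units.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import CuboidMeta, IsletRecord, VoxelGrid

__all__ = [
    "write_volume",
    "read_volume",
    "write_meta",
    "read_meta",
    "write_catalog",
    "read_catalog",
]


def write_volume(path, grid: VoxelGrid) -> None:
    """Write a volume as an ImageJ-compatible multi-page TIFF (z pages)."""
    h = grid.voxel_size_um
    data = np.asarray(grid.data)
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / h, 1.0 / h),
        metadata={
            "spacing": h,
            "unit": "um",
            "origin_um": list(grid.origin_um),
        },
    )


def read_volume(path, voxel_size_um: float | None = None) -> VoxelGrid:
    """Read a TIFF stack; voxel size from ImageJ metadata unless overridden."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        origin = (0.0, 0.0, 0.0)
        if voxel_size_um is None:
            meta = tif.imagej_metadata or {}
            spacing = meta.get("spacing")
            if spacing is None:
                raise ValueError(
                    f"{path}: no voxel size in metadata; pass voxel_size_um")
            voxel_size_um = float(spacing)
            if "origin_um" in meta:
                origin = tuple(json.loads(meta["origin_um"])
                               if isinstance(meta["origin_um"], str)
                               else meta["origin_um"])
    if data.ndim == 2:
        data = data[None]
    return VoxelGrid(data, voxel_size_um, origin)


def write_meta(path, meta: CuboidMeta) -> None:
    Path(path).write_text(json.dumps(meta.to_dict(), indent=2))


def read_meta(path) -> CuboidMeta:
    return CuboidMeta.from_dict(json.loads(Path(path).read_text()))


def write_catalog(path, records: Sequence[IsletRecord]) -> None:
    """One CSV row per islet; see docs/catalog_schema.md for units."""
    pd.DataFrame([r.to_flat_dict() for r in records]).to_csv(path, index=False)


def read_catalog(path) -> list[IsletRecord]:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        def opt(name):
            return None if name not in row or pd.isna(row[name]) else row[name]

        rec = IsletRecord(
            islet_id=int(row.islet_id),
            cuboid_id="" if pd.isna(row.cuboid_id) else str(row.cuboid_id),
            centroid_local_um=(row.x_um, row.y_um, row.z_um),
            voxel_count=int(row.voxel_count),
            volume_um3=float(row.volume_um3),
            axis_length_um=(row.axis_x_um, row.axis_y_um, row.axis_z_um),
            mean_diameter_um=float(row.mean_diameter_um),
            surface_area_um2=float(row.surface_area_um2),
            sphericity=float(row.sphericity),
            hemorrhage_volume_um3=float(row.get("hemorrhage_volume_um3", 0.0)),
            cluster_id=None if opt("cluster_id") is None else int(row.cluster_id),
            size_category=None if opt("size_category") is None else int(row.size_category),
        )
        if opt("gx_um") is not None:
            rec.centroid_global_um = (row.gx_um, row.gy_um, row.gz_um)
        if opt("bbox_zmin") is not None:
            rec.bbox_min_vox = (int(row.bbox_zmin), int(row.bbox_ymin), int(row.bbox_xmin))
            rec.bbox_max_vox = (int(row.bbox_zmax), int(row.bbox_ymax), int(row.bbox_xmax))
        records.append(rec)
    return records
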