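# On-disk schema

## Islet catalog CSV (`io.write_catalog` / `io.read_catalog`)

One row per segmented islet.

| column | unit | meaning |
|---|---|---|
| `islet_id` | — | label id, contiguous from 1 within a cuboid; globally unique after stitching |
| `cuboid_id` | — | id of the source cuboid |
| `x_um`, `y_um`, `z_um` | µm | centroid in the local cuboid frame (origin at cuboid corner) |
| `gx_um`, `gy_um`, `gz_um` | µm | centroid in the organ frame (present after stitching) |
| `voxel_count` | voxels | number of voxels of the object |
| `volume_um3` | µm³ | `voxel_count × voxel_size³` |
| `axis_x_um`, `axis_y_um`, `axis_z_um` | µm | world-axis ellipsoid-equivalent lengths, 2·√(5·variance) |
| `mean_diameter_um` | µm | mean 3D diameter = mean of the three axis lengths |
| `surface_area_um2` | µm² | marching-cubes isosurface area |
| `sphericity` | — | Wadell Ψ = π^(1/3)·(6V)^(2/3)/A; 1 for a sphere |
| `hemorrhage_volume_um3` | µm³ | intra-islet red-blood-cell AF volume |
| `cluster_id` | — | single-linkage cluster id (empty if clustering not run) |
| `size_category` | — | 0-based size-bin index (empty if unbinned: zero or overflow) |
| `bbox_zmin` … `bbox_xmax` | voxels | local voxel-index bounding box (inclusive), used for boundary merging |

## Cuboid metadata JSON (`io.write_meta` / `io.read_meta`)

```json
{
  "cuboid_id": "c010",
  "grid_ijk": [0, 1, 0],
  "origin_um": [0.0, 3300.0, 0.0],
  "shape_voxels": [64, 64, 64],
  "voxel_size_um": 21.0,
  "grid_pitch_um": [5500.0, 3300.0, 1344.0]
}
```

* `grid_ijk` — slicing-grid coordinates along (x, y, z).
* `origin_um` — physical offset (x, y, z) of the cuboid corner in the
  organ frame; equals `grid_ijk ⊙ grid_pitch_um`.
* `shape_voxels` — array shape (nz, ny, nx).

## Volumes (TIFF)

Multi-page TIFF, one page per z-slice, ImageJ-style metadata carrying the
voxel spacing in µm (`spacing`) and the cuboid origin (`origin_um`).
Label volumes are written as 16-bit (or 32-bit when > 65 535 labels) with
0 = background; masks as 8-bit 0/1.

## Ground truth CSV (phantom)

One row per planted object: `obj_id`, `kind`
(`islet | vessel | hole_sphere | hole_tube | rbc_blob`), centre
`x_um, y_um, z_um`, `semi_a_um, semi_b_um, semi_c_um` (for tubes:
radius, radius, half-length), rotation matrix entries `R00`–`R22`
(columns = object axes in world frame), `analytic_volume_um3`,
`voxel_count` (rasterized), `truncated` (object crosses a cuboid cut),
`cluster_id` (planted cluster), `parent_islet` (for RBC blobs).

## Density report CSV (`DensityReport.to_csv`)

Two stacked tables: a one-row header (`region_id`, `normalization`
(`outline | tissue`), `reference_volume_mm3`, `total_islet_volume_um3`,
`islet_count`, `volume_density` (dimensionless), `count_per_mm3`),
followed by one row per size category plus an `overflow` row:
`category`, `volume_sum_um3`, `count`, `volume_density`, `count_per_mm3`.
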