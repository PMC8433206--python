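"""Phantom generator: rasterization rule, determinism, clusters, organ cuts."""

import numpy as np
import pytest

from islet3d import (
    CuboidMeta,
    OrganSpec,
    PhantomSpec,
    VoxelGrid,
    generate_cuboid,
    generate_organ,
    render_ellipsoid,
)
from islet3d.phantom import (
    ClusterSpec,
    GroundTruth,
    PhantomPlacementError,
    PlantedObject,
    cuboid_truth,
)


def _grid(n=96, h=21.0):
    return VoxelGrid(np.zeros((n, n, n), dtype=np.float32), h)


class TestRenderEllipsoid:
    def test_sphere_volume_matches_analytic(self):
        # a 110 µm radius sphere (~5.2 voxels) digitizes to within 5% of
        # 4/3 π r³; at 55 µm (~2.6 voxels) digitization noise grows to ~10%
        g = _grid(24)
        render_ellipsoid(g, center_um=(250.5, 250.5, 250.5), semi_axes_um=(110,) * 3)
        vol = np.count_nonzero(g.data) * 21.0**3
        assert vol == pytest.approx(4 / 3 * np.pi * 110**3, rel=0.05)
        g2 = _grid(16)
        render_ellipsoid(g2, center_um=(178.5, 178.5, 178.5), semi_axes_um=(55,) * 3)
        vol2 = np.count_nonzero(g2.data) * 21.0**3
        assert vol2 == pytest.approx(4 / 3 * np.pi * 55**3, rel=0.15)

    def test_subvoxel_ellipsoid_renders_nothing(self):
        # smaller than half a voxel, centred between voxel centres: no centre inside
        g = _grid(8)
        render_ellipsoid(g, center_um=(42, 42, 42), semi_axes_um=(5, 5, 5))
        assert not g.data.any()

    def test_max_combine_is_idempotent(self):
        g = _grid(16)
        render_ellipsoid(g, (168, 168, 168), (60, 50, 40), intensity=0.7)
        snapshot = g.data.copy()
        render_ellipsoid(g, (168, 168, 168), (60, 50, 40), intensity=0.7)
        np.testing.assert_array_equal(g.data, snapshot)

    def test_entirely_outside_warns_and_is_noop(self):
        g = _grid(8)
        with pytest.warns(UserWarning):
            render_ellipsoid(g, (10_000, 10_000, 10_000), (50, 50, 50))
        assert not g.data.any()

    def test_rejects_nonpositive_semi_axes(self):
        with pytest.raises(ValueError):
            render_ellipsoid(_grid(8), (84, 84, 84), (0, 50, 50))


class TestGenerateCuboid:
    def test_empty_spec_gives_background_only(self):
        spec = PhantomSpec(shape_voxels=(32, 32, 32), n_islets=0, noise_sd=0.01,
                           vessel_spec=None, hole_spec=None, seed=5)
        sig, ana, truth = generate_cuboid(spec)
        assert len(truth) == 0
        # background + noise only: nothing anywhere near islet intensity
        assert sig.data.max() < spec.signal_background + 8 * spec.noise_sd

    def test_same_seed_is_bit_identical(self):
        spec = PhantomSpec(shape_voxels=(48, 48, 48), n_islets=10, seed=3,
                           hemorrhage_fraction=0.2)
        s1, a1, t1 = generate_cuboid(spec)
        s2, a2, t2 = generate_cuboid(spec)
        np.testing.assert_array_equal(s1.data, s2.data)
        np.testing.assert_array_equal(a1.data, a2.data)
        assert t1.to_dataframe().equals(t2.to_dataframe())

    def test_rasterized_volume_tracks_analytic(self, small_phantom):
        # >= 100-voxel objects: count x voxel volume within 15% of analytic
        _, _, _, truth = small_phantom
        for o in truth.islets:
            if o.voxel_count >= 100:
                assert o.voxel_count * 21.0**3 == pytest.approx(
                    o.analytic_volume_um3, rel=0.15)

    def test_planted_cluster_is_single_linkage_connected(self):
        spec = PhantomSpec(
            shape_voxels=(160, 160, 160), n_islets=120, seed=11,
            diameter_dist=(75.0, 1.15), anisotropy_max=1.1,
            cluster_spec=ClusterSpec(n_clusters=1, islets_per_cluster=120,
                                     cluster_radius_um=250.0, peripheral=False),
            vessel_spec=None, hole_spec=None,
        )
        _, _, truth = generate_cuboid(spec)
        pts = truth.islet_centers_um()
        assert len(pts) == 120
        # brute-force union-find on pairwise distances at 300 µm
        parent = list(range(len(pts)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.linalg.norm(pts[i] - pts[j]) <= 300.0:
                    parent[find(j)] = find(i)
        assert len({find(i) for i in range(len(pts))}) == 1

    def test_unplaceable_spec_raises_with_kind(self):
        spec = PhantomSpec(shape_voxels=(24, 24, 24), n_islets=500, seed=0,
                           vessel_spec=None, hole_spec=None)
        with pytest.raises(PhantomPlacementError, match="islet"):
            generate_cuboid(spec)

    def test_hemorrhage_blobs_have_parents(self):
        spec = PhantomSpec(shape_voxels=(64, 64, 64), n_islets=10, seed=4,
                           hemorrhage_fraction=0.5, vessel_spec=None, hole_spec=None)
        _, _, truth = generate_cuboid(spec)
        blobs = truth.of_kind("rbc_blob")
        assert len(blobs) == 5
        islet_ids = {o.obj_id for o in truth.islets}
        assert all(b.parent_islet in islet_ids for b in blobs)


class TestGenerateOrgan:
    def test_single_cell_grid_is_one_cuboid(self):
        spec = OrganSpec(grid_shape=(1, 1, 1), cuboid_shape_voxels=(48, 48, 48),
                         n_islets=12, seed=2)
        cuboids, truth = generate_organ(spec)
        assert len(cuboids) == 1
        sig, ana, meta = cuboids[0]
        assert sig.shape == (48, 48, 48)
        assert meta.origin_um == (0.0, 0.0, 0.0)
        assert len(truth) == 12

    def test_cuboid_partition_conserves_objects_and_voxels(self):
        spec = OrganSpec(grid_shape=(2, 2, 2), cuboid_shape_voxels=(48, 48, 48),
                         n_islets=40, seed=9)
        cuboids, truth = generate_organ(spec)
        assert len(cuboids) == 8
        parts = [cuboid_truth(truth, meta) for _, _, meta in cuboids]
        # every global object appears in >= 1 cuboid; per-part voxel counts
        # sum to the global count (conservation across cuts)
        seen = {}
        for p in parts:
            for o in p.objects:
                seen[o.obj_id] = seen.get(o.obj_id, 0) + o.voxel_count
        for o in truth.objects:
            assert seen.get(o.obj_id, 0) == o.voxel_count
        # deduplicated count equals the global count
        assert len(seen) == len(truth)
        # truncated objects appear in >= 2 cuboids
        for p in parts:
            for o in p.objects:
                if o.truncated:
                    n_parts = sum(
                        any(q.obj_id == o.obj_id for q in p2.objects) for p2 in parts)
                    assert n_parts >= 2

    def test_object_centred_on_cut_plane_is_truncated_in_two_cuboids(self):
        # handcrafted truth: one sphere centred exactly on the x cut plane
        voxel = 21.0
        meta_lo = CuboidMeta("a", (0, 0, 0), (0, 0, 0), (32, 32, 32), voxel,
                             (672.0, 672.0, 672.0))
        meta_hi = CuboidMeta("b", (1, 0, 0), (672.0, 0, 0), (32, 32, 32), voxel,
                             (672.0, 672.0, 672.0))
        sphere = PlantedObject(
            obj_id=0, kind="islet",
            center_um=np.array([672.0, 336.0, 336.0]),
            semi_axes_um=np.array([100.0, 100.0, 100.0]),
            rotation=np.eye(3), intensity=1.0,
            analytic_volume_um3=4 / 3 * np.pi * 100**3,
        )
        # independent full rasterization count over the joined 64x32x32 domain
        zz, yy, xx = np.meshgrid(np.arange(32), np.arange(32), np.arange(64),
                                 indexing="ij")
        centres = np.stack([(xx + 0.5) * voxel, (yy + 0.5) * voxel,
                            (zz + 0.5) * voxel], axis=-1)
        inside = np.linalg.norm(centres - sphere.center_um, axis=-1) <= 100.0
        sphere.voxel_count = int(inside.sum())
        truth = GroundTruth([sphere], voxel, (32, 32, 64))
        part_lo = cuboid_truth(truth, meta_lo)
        part_hi = cuboid_truth(truth, meta_hi)
        assert len(part_lo) == 1 and len(part_hi) == 1
        assert part_lo.objects[0].truncated and part_hi.objects[0].truncated
        # the two halves together cover the full rasterization exactly
        full = part_lo.objects[0].voxel_count + part_hi.objects[0].voxel_count
        assert full == sphere.voxel_count

    def test_meta_offsets_are_grid_multiples(self):
        spec = OrganSpec(grid_shape=(2, 1, 2), cuboid_shape_voxels=(32, 32, 32),
                         n_islets=5, seed=1)
        cuboids, _ = generate_organ(spec)
        for _, _, meta in cuboids:
            for d in range(3):
                assert meta.origin_um[d] == meta.grid_ijk[d] * meta.grid_pitch_um[d]
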