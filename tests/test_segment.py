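"""Segmentation: watershed splitting, spot detection, masks, hemorrhage."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from islet3d import (
    PhantomSpec,
    SegmentConfig,
    VoxelGrid,
    baseline_subtract,
    detect_spots,
    generate_cuboid,
    hemorrhage_segment,
    hypointense_regions,
    outline_mask,
    render_ellipsoid,
    rescale_minmax,
    segment_islets,
    tissue_mask,
)
from islet3d.phantom import HoleSpec
from islet3d.segment import LabelVolume

H = 21.0


def _grid(n=64):
    return VoxelGrid(np.zeros((n, n, n), dtype=np.float32), H)


class TestBaselineSubtract:
    def test_percentile_zero_leaves_nonnegative_input(self):
        rng = np.random.default_rng(0)
        g = VoxelGrid(rng.uniform(0, 1, (4, 4, 4)), H)
        out = baseline_subtract(g, 0.0)
        np.testing.assert_allclose(out.data, g.data - g.data.min(), atol=1e-6)

    def test_constant_volume_becomes_zero(self):
        out = baseline_subtract(VoxelGrid(np.full((3, 3, 3), 5.0), H), 50.0)
        assert not out.data.any()

    def test_median_never_increases(self):
        rng = np.random.default_rng(1)
        g = VoxelGrid(rng.uniform(0, 10, (8, 8, 8)), H)
        out = baseline_subtract(g, 30.0)
        assert np.median(out.data) <= np.median(g.data)

    def test_invalid_percentile_raises(self):
        with pytest.raises(ValueError):
            baseline_subtract(_grid(4), 100.0)


class TestSegmentIslets:
    def test_two_separated_spheres_give_two_labels(self):
        # d = 110 µm spheres, centres 300 µm apart: separate objects
        g = _grid(48)
        render_ellipsoid(g, (325.5, 504, 504), (55, 55, 55))
        render_ellipsoid(g, (625.5, 504, 504), (55, 55, 55))
        labels = segment_islets(g, SegmentConfig(threshold_mode=0.5))
        assert labels.n_labels == 2
        counts = np.bincount(labels.labels.ravel())[1:]
        expected = 4 / 3 * np.pi * 55**3 / H**3
        for c in counts:
            assert c == pytest.approx(expected, rel=0.10)

    def test_overlapping_spheres_are_split(self):
        # centres 110 µm apart: fused solid is split into 2, total volume
        # matches a brute-force union count
        g = _grid(48)
        c1, c2 = (399.0, 504, 504), (509.0, 504, 504)
        render_ellipsoid(g, c1, (55, 55, 55))
        render_ellipsoid(g, c2, (55, 55, 55))
        union_count = int(np.count_nonzero(g.data))
        labels = segment_islets(g, SegmentConfig(threshold_mode=0.5))
        assert labels.n_labels == 2
        assert int(np.count_nonzero(labels.labels)) == union_count

    @pytest.mark.parametrize("n_voxels,survives", [(4, False), (5, True)])
    def test_minimum_object_filter(self, n_voxels, survives):
        g = _grid(16)
        flat = np.ravel_multi_index(
            ([8, 8, 8, 8, 9][:n_voxels], [8, 8, 9, 9, 8][:n_voxels],
             [8, 9, 8, 9, 8][:n_voxels]), g.shape)
        g.data.flat[flat] = 1.0
        labels = segment_islets(g, SegmentConfig(threshold_mode=0.5))
        assert (labels.n_labels == 1) is survives

    def test_empty_foreground_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty foreground"):
            labels = segment_islets(_grid(8), SegmentConfig(threshold_mode=0.5))
        assert labels.n_labels == 0

    def test_phantom_count_recovered_exactly(self, small_phantom):
        _, signal, _, truth = small_phantom
        labels = segment_islets(baseline_subtract(signal, 20.0))
        assert labels.n_labels == len(truth.islets)


class TestDetectSpots:
    def test_ideal_blob_quality_tracks_contrast(self):
        # Gaussian blob of the expected diameter, contrast 2: one spot,
        # quality ~ 2, centroid within one voxel of the centre
        n, d, contrast = 41, 110.0, 2.0
        s_vox = d / (2 * np.sqrt(3)) / H
        c = (n - 1) / 2
        zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        r2 = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2
        g = VoxelGrid(contrast * np.exp(-r2 / (2 * s_vox**2)), H)
        spots = detect_spots(g, SegmentConfig(spot_quality_min=1.0))
        assert len(spots) == 1
        assert spots[0].quality == pytest.approx(contrast, rel=0.10)
        centre = (c + 0.5) * H
        assert np.allclose(spots[0].centroid_um, (centre,) * 3, atol=H)

    def test_empty_volume_yields_no_spots(self):
        assert detect_spots(_grid(32)) == []

    def test_spot_count_matches_label_count_on_phantom(self, small_phantom):
        _, signal, _, truth = small_phantom
        labels = segment_islets(baseline_subtract(signal, 20.0))
        spots = detect_spots(rescale_minmax(signal))
        assert abs(len(spots) - labels.n_labels) / labels.n_labels <= 0.05


class TestMasks:
    def test_uniform_block_is_all_tissue(self):
        g = VoxelGrid(np.full((32, 32, 32), 0.5, dtype=np.float32), H)
        mask = tissue_mask(g, SegmentConfig(threshold_mode=0.25))
        assert mask.all()

    def test_dark_hole_excluded_from_tissue_then_closed_into_outline(self):
        g = VoxelGrid(np.full((48, 48, 48), 0.5, dtype=np.float32), H)
        zz, yy, xx = np.meshgrid(*[np.arange(48)] * 3, indexing="ij")
        hole = (zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2 <= 6**2
        g.data[hole] = 0.0
        cfg = SegmentConfig(threshold_mode=0.25)
        tis = tissue_mask(g, cfg)
        assert not tis[24, 24, 24]
        out = outline_mask(tis, cfg)
        assert out[24, 24, 24]  # internal hole closed
        assert (out | tis).sum() == out.sum()  # outline ⊇ tissue

    def test_outline_is_superset_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            tis = ndi.binary_dilation(
                rng.uniform(size=(24, 24, 24)) > 0.995,
                iterations=int(rng.integers(1, 4)))
            out = outline_mask(tis, SegmentConfig(outline_closing_radius_vox=3))
            assert not (tis & ~out).any()

    def test_tissue_volume_tracks_phantom(self):
        spec = PhantomSpec(shape_voxels=(64, 64, 64), n_islets=0, seed=6,
                           vessel_spec=None,
                           hole_spec=HoleSpec(n_spherical=1, n_tubular=0,
                                              sphere_diameter_um=(250, 300)))
        _, ana, truth = generate_cuboid(spec)
        tis = tissue_mask(ana, SegmentConfig(threshold_mode=0.15))
        hole_vox = sum(o.voxel_count for o in truth.of_kind("hole_sphere"))
        planted = 64**3 - hole_vox
        assert tis.sum() == pytest.approx(planted, rel=0.05)


class TestHypointense:
    def test_constructed_sphere_and_tube_are_classified(self):
        # a spherical hole (fat deposit) and a 16:1 tubular lumen carved
        # from a solid block classify by sphericity
        n = 96
        outline = np.ones((n, n, n), dtype=bool)
        zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        tube = ((yy - 70) ** 2 + (xx - 70) ** 2 <= 2.5**2) & (np.abs(zz - 48) <= 40)
        ball = (zz - 30) ** 2 + (yy - 25) ** 2 + (xx - 25) ** 2 <= 5**2
        tissue = outline & ~tube & ~ball
        labels, classes = hypointense_regions(outline, tissue, SegmentConfig(), H)
        assert labels.n_labels == 2
        by_size = np.argsort(np.bincount(labels.labels.ravel())[1:]) + 1
        assert classes[int(by_size[-1])] == "tubular"  # the larger region
        assert classes[int(by_size[0])] == "spherical"

    def test_phantom_hole_recovered_as_spherical(self):
        spec = PhantomSpec(shape_voxels=(64, 64, 64), n_islets=0, seed=8,
                           vessel_spec=None, texture_amplitude=0.05,
                           hole_spec=HoleSpec(n_spherical=1, n_tubular=0,
                                              sphere_diameter_um=(200, 220)))
        _, ana, truth = generate_cuboid(spec)
        cfg = SegmentConfig(threshold_mode=0.15, min_voxels=10)
        tis = tissue_mask(ana, cfg)
        out = outline_mask(tis, cfg)
        labels, classes = hypointense_regions(out, tis, cfg, spec.voxel_size_um)
        counts = np.bincount(labels.labels.ravel())[1:]
        largest = int(np.argmax(counts)) + 1
        assert classes[largest] == "spherical"
        assert counts[largest - 1] == pytest.approx(
            truth.of_kind("hole_sphere")[0].voxel_count, rel=0.15)

    def test_identical_masks_give_no_regions(self):
        m = np.zeros((16, 16, 16), dtype=bool)
        m[4:12, 4:12, 4:12] = True
        labels, classes = hypointense_regions(m, m, SegmentConfig(), H)
        assert labels.n_labels == 0 and classes == {}

    def test_tissue_outside_outline_raises(self):
        out = np.zeros((8, 8, 8), dtype=bool)
        tis = np.ones((8, 8, 8), dtype=bool)
        with pytest.raises(ValueError):
            hypointense_regions(out, tis, SegmentConfig(), H)

    def test_set_identity_tissue_union_hypo_equals_outline(self):
        rng = np.random.default_rng(9)
        cfg = SegmentConfig(min_voxels=1, outline_closing_radius_vox=3)
        for _ in range(5):
            tis = ndi.binary_dilation(rng.uniform(size=(20, 20, 20)) > 0.99,
                                      iterations=2)
            out = outline_mask(tis, cfg)
            labels, _ = hypointense_regions(out, tis, cfg, H)
            hypo = labels.labels > 0
            assert np.array_equal(hypo | tis, out)
            assert not (hypo & tis).any()


class TestHemorrhage:
    @pytest.fixture(scope="module")
    @staticmethod
    def hemorrhage_phantom():
        spec = PhantomSpec(shape_voxels=(64, 64, 64), n_islets=8, seed=10,
                           hemorrhage_fraction=0.25, vessel_spec=None,
                           hole_spec=None)
        sig, ana, truth = generate_cuboid(spec)
        labels = segment_islets(baseline_subtract(sig, 20.0))
        return sig, ana, truth, labels

    def test_blob_volume_recovered_in_host_islet_only(self, hemorrhage_phantom):
        sig, ana, truth, labels = hemorrhage_phantom
        hem = hemorrhage_segment(ana, labels, SegmentConfig(), threshold=0.6)
        blobs = truth.of_kind("rbc_blob")
        assert blobs
        hosts = {b.parent_islet for b in blobs}
        # total hemorrhage matches the planted blob rasterization within 15%
        planted = sum(b.voxel_count for b in blobs) * 21.0**3
        assert sum(hem.values()) == pytest.approx(planted, rel=0.15)
        # islets without a blob report zero
        host_centers = np.array(
            [next(o for o in truth.islets if o.obj_id == h).center_um for h in hosts])
        for k, v in hem.items():
            rec_mask = labels.labels == k
            zz, yy, xx = np.nonzero(rec_mask)
            c = np.array([(xx.mean() + 0.5) * 21, (yy.mean() + 0.5) * 21,
                          (zz.mean() + 0.5) * 21])
            is_host = np.any(np.linalg.norm(host_centers - c, axis=1) < 110)
            if not is_host:
                assert v == 0.0

    def test_signal_outside_islets_is_ignored(self):
        ana = _grid(32)
        ana.data[4:8, 4:8, 4:8] = 1.0  # bright blob in a corner
        labels = LabelVolume(np.zeros((32, 32, 32), dtype=np.int32), H)
        labels.labels[20:26, 20:26, 20:26] = 1
        hem = hemorrhage_segment(ana, labels, threshold=0.5)
        assert hem == {1: 0.0}

    def test_shape_mismatch_raises(self):
        labels = LabelVolume(np.zeros((8, 8, 8), dtype=np.int32), H)
        with pytest.raises(ValueError, match="mismatch"):
            hemorrhage_segment(_grid(16), labels)
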