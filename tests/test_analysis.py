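"""MTR maps, scar metrics, AHA statistics, vessel sharpness, CNR."""

import numpy as np
import pytest

from mtprep.analysis import (
    AHALabels,
    MetricError,
    MTRMap,
    aha16_labels,
    cnr,
    contrast_ratio,
    dice,
    false_positive_percent,
    mtr_map,
    overlap_percent,
    reformat_short_axis,
    scar_threshold_segmentation,
    segment_stats,
    smooth_map,
    vessel_sharpness,
)


def flat_map(values, valid=None):
    values = np.asarray(values, dtype=float)
    valid = np.ones(values.shape, bool) if valid is None else valid
    return MTRMap(values, valid)


class TestMTRMap:
    def test_equal_volumes_zero_everywhere(self, rng):
        ref = np.abs(rng.standard_normal((8, 8, 4))) + 1.0
        m = mtr_map(ref, ref)
        assert np.all(m.valid)
        assert np.allclose(m.values, 0.0)

    def test_scaled_volume_constant_mtr(self, rng):
        ref = np.abs(rng.standard_normal((8, 8, 4))) + 1.0
        m = mtr_map(0.6 * ref, ref)
        assert np.allclose(m.values[m.valid], 40.0)

    def test_floor_excludes_low_reference_voxels(self):
        ref = np.ones((4, 4, 2))
        ref[0, 0, 0] = 0.01  # below 5 % of robust max
        m = mtr_map(ref * 0.5, ref)
        assert not m.valid[0, 0, 0]
        assert m.valid.sum() == ref.size - 1

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mtr_map(np.ones((4, 4, 2)), np.ones((4, 4, 3)))


class TestSmoothing:
    def test_constant_map_unchanged(self):
        m = flat_map(np.full((10, 10, 3), 37.0))
        out = smooth_map(m)
        assert np.allclose(out.values, 37.0)

    def test_impulse_centre_matches_truncated_gaussian_oracle(self):
        vals = np.zeros((11, 11, 1))
        vals[5, 5, 0] = 1.0
        out = smooth_map(flat_map(vals), kernel=5, sigma=3.0)
        ax = np.arange(-2, 3, dtype=float)
        g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * 9.0))
        oracle = (g / g.sum())[2, 2]
        assert out.values[5, 5, 0] == pytest.approx(oracle, rel=1e-12)

    def test_valid_renormalization_preserves_constants_at_edges(self):
        valid = np.zeros((10, 10, 1), bool)
        valid[:5] = True
        m = MTRMap(np.where(valid, 25.0, 0.0), valid)
        out = smooth_map(m)
        assert np.allclose(out.values[valid], 25.0)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            smooth_map(flat_map(np.zeros((4, 4, 1))), kernel=4)


class TestScarThreshold:
    def test_gaussian_tail_fraction(self, rng):
        # homogeneous normal map: expected scar fraction is the one-sided
        # 2-sigma tail, ~2.3 % (binomial tolerance at n = 1e5)
        n = 100_000
        vals = rng.normal(25.0, 2.0, size=(n, 1, 1))
        myo = np.ones((n, 1, 1), bool)
        scar, thr = scar_threshold_segmentation(flat_map(vals), myo, myo)
        frac = scar.mean()
        assert frac == pytest.approx(0.02275, abs=0.002)

    def test_lowered_sector_fully_selected(self, rng):
        # remote 25.1 +/- 1.7 against a sector lowered by ~8 points
        vals = rng.normal(25.1, 1.7, size=(40, 40, 1))
        myo = np.ones(vals.shape, bool)
        remote = myo.copy()
        remote[:10] = False
        vals[:10] = rng.normal(16.8, 1.9, size=(10, 40, 1))
        scar, thr = scar_threshold_segmentation(flat_map(vals), myo, remote)
        assert scar[:10].mean() > 0.95
        assert thr == pytest.approx(25.1 - 2 * 1.7, abs=0.5)

    def test_zero_variance_remote_uniform_map_empty_scar(self):
        vals = np.full((6, 6, 1), 30.0)
        myo = np.ones(vals.shape, bool)
        scar, _ = scar_threshold_segmentation(flat_map(vals), myo, myo)
        assert not scar.any()

    def test_shift_invariance(self, rng):
        vals = rng.normal(25.0, 2.0, size=(20, 20, 2))
        myo = np.ones(vals.shape, bool)
        remote = myo.copy()
        remote[:5] = False
        s1, _ = scar_threshold_segmentation(flat_map(vals), myo, remote)
        s2, _ = scar_threshold_segmentation(flat_map(vals + 11.0), myo, remote)
        assert np.array_equal(s1, s2)

    def test_empty_remote_rejected(self):
        with pytest.raises(MetricError):
            scar_threshold_segmentation(
                flat_map(np.zeros((4, 4, 1))),
                np.ones((4, 4, 1), bool),
                np.zeros((4, 4, 1), bool),
            )


class TestOverlapMetrics:
    def setup_method(self):
        self.a = np.zeros((10, 10, 1), bool)
        self.a[:4] = True

    def test_identical_masks_full_overlap(self):
        assert overlap_percent(self.a, self.a) == 100.0

    def test_disjoint_masks_zero_overlap(self):
        b = ~self.a
        assert overlap_percent(b, self.a) == 0.0

    def test_half_coverage(self):
        half = self.a.copy()
        half[2:] = False
        assert overlap_percent(half, self.a) == 50.0

    def test_false_positive_default_and_literal(self):
        remote = ~self.a
        none_in_remote = self.a
        assert false_positive_percent(none_in_remote, remote) == 0.0
        assert false_positive_percent(none_in_remote, remote, literal=True) == 100.0
        all_in_remote = remote
        assert false_positive_percent(all_in_remote, remote) == 100.0
        ten = np.zeros_like(remote)
        ten_idx = np.argwhere(remote)[: remote.sum() // 10]
        ten[tuple(ten_idx.T)] = True
        assert false_positive_percent(ten, remote) == pytest.approx(10.0)

    def test_overlap_monotone_under_enlargement(self, rng):
        lge = rng.random((10, 10, 2)) > 0.5
        small = rng.random((10, 10, 2)) > 0.8
        large = small | (rng.random((10, 10, 2)) > 0.8)
        assert overlap_percent(large, lge) >= overlap_percent(small, lge)

    def test_bounds(self, rng):
        a = rng.random((8, 8, 2)) > 0.5
        b = rng.random((8, 8, 2)) > 0.5
        if b.any():
            assert 0.0 <= overlap_percent(a, b) <= 100.0
            assert 0.0 <= false_positive_percent(a, b) <= 100.0

    def test_empty_reference_rejected(self):
        with pytest.raises(MetricError):
            overlap_percent(self.a, np.zeros_like(self.a))


class TestReformat:
    def test_identity_geometry(self, rng):
        vol = rng.standard_normal((8, 8, 4))
        out, valid = reformat_short_axis(vol, np.eye(3), (0, 0, 0), vol.shape)
        assert np.allclose(out, vol)
        assert valid.all()

    def test_quarter_turn_permutes_axes(self, rng):
        vol = rng.standard_normal((8, 8, 4))
        # output axis 0 walks along input axis 1
        axes = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        out, _ = reformat_short_axis(vol, axes, (0, 0, 0), (8, 8, 4))
        assert np.allclose(out, np.swapaxes(vol, 0, 1))

    def test_rotated_smooth_field_matches_analytic(self):
        n = 32
        x, y, z = np.meshgrid(*(np.arange(n, dtype=float),) * 2, np.arange(4.0),
                              indexing="ij")
        f = lambda X, Y, Z: np.sin(0.2 * X) * np.cos(0.15 * Y) + 0.1 * Z
        vol = f(x, y, z)
        th = np.radians(30.0)
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        origin = np.array([16.0, 16.0, 0.0]) - R @ np.array([8.0, 8.0, 0.0])
        out, valid = reformat_short_axis(vol, R, origin, (16, 16, 4))
        jj = np.indices((16, 16, 4), dtype=float).reshape(3, -1)
        coords = origin.reshape(3, 1) + R @ jj
        analytic = f(*coords).reshape(16, 16, 4)
        rng_range = vol.max() - vol.min()
        assert np.abs((out - analytic)[valid]).max() < 0.02 * rng_range

    def test_singular_axes_rejected(self):
        with pytest.raises(ValueError):
            reformat_short_axis(np.zeros((4, 4, 2)), np.zeros((3, 3)), (0, 0, 0),
                                (4, 4, 2))


def annulus_slabs(n=48, r_in=10, r_out=18, nz=6):
    x, y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    c = (n - 1) / 2.0
    r2 = (x - c) ** 2 + (y - c) ** 2
    ring = (r2 >= r_in**2) & (r2 <= r_out**2)
    vol = np.repeat(ring[:, :, None], nz, axis=2)
    zidx = np.arange(nz)[None, None, :]
    return {
        "basal": vol & (zidx < 2),
        "mid": vol & (zidx >= 2) & (zidx < 4),
        "apical": vol & (zidx >= 4),
    }, (c, c)


class TestAHA16:
    def test_labels_partition_myocardium(self):
        slabs, c = annulus_slabs()
        labels = aha16_labels(slabs, c, (c[0] + 20, c[1]))
        total = sum(s.sum() for s in slabs.values())
        assert (labels.labels > 0).sum() == total
        assert set(np.unique(labels.labels)) == set(range(17))

    def test_symmetric_annulus_balanced_sectors(self):
        slabs, c = annulus_slabs()
        labels = aha16_labels(slabs, c, (c[0] + 20, c[1]))
        counts = [(labels.labels == s).sum() for s in range(1, 7)]
        assert max(counts) - min(counts) <= 0.03 * np.mean(counts) + 1

    def test_rotating_rv_insertion_permutes_basal_labels(self):
        slabs, c = annulus_slabs()
        l0 = aha16_labels(slabs, c, (c[0] + 20, c[1])).labels
        # +60 deg (counterclockwise in the index plane)
        rv = (c[0] + 20 * np.cos(np.radians(60)), c[1] + 20 * np.sin(np.radians(60)))
        l1 = aha16_labels(slabs, c, rv).labels
        basal = (l0 >= 1) & (l0 <= 6)
        assert np.array_equal(l1[basal], (l0[basal] - 1 - 1) % 6 + 1)

    def test_centre_outside_mask_rejected(self):
        slabs, c = annulus_slabs()
        with pytest.raises(ValueError):
            aha16_labels(slabs, (200.0, 200.0), (220.0, 200.0))


class TestSegmentStats:
    def test_constant_map_zero_spatial_variation(self):
        slabs, c = annulus_slabs()
        labels = aha16_labels(slabs, c, (c[0] + 20, c[1]))
        m = flat_map(np.full(labels.labels.shape, 40.0))
        stats = segment_stats(m, labels)
        assert np.allclose(stats.per_segment["spatial_variation"], 0.0)
        assert stats.global_mean == pytest.approx(40.0)

    def test_two_segment_intersegment_variation(self):
        labels = AHALabels(np.zeros((10, 10, 1), np.int8), 0.0)
        labels.labels[:5] = 1
        labels.labels[5:] = 2
        vals = np.where(labels.labels == 1, 30.0, 50.0)
        stats = segment_stats(flat_map(vals), labels)
        expected = 100.0 * np.std([30.0, 50.0], ddof=1) / 40.0
        assert stats.intersegment_variation == pytest.approx(expected)

    def test_gaussian_map_recovers_spatial_variation(self, rng):
        # mu 37, sigma 5.8 -> spatial variation ~15.7 %
        labels = AHALabels(np.zeros((100, 100, 1), np.int8), 0.0)
        labels.labels[:] = 1
        vals = rng.normal(37.0, 5.8, size=labels.labels.shape)
        stats = segment_stats(flat_map(vals), labels)
        assert stats.per_segment.loc[1, "spatial_variation"] == pytest.approx(
            100.0 * 5.8 / 37.0, abs=0.5
        )

    def test_spatial_variation_scale_invariant_and_sd_linear(self, rng):
        labels = AHALabels(np.ones((40, 40, 1), np.int8), 0.0)
        base = rng.normal(40.0, 4.0, size=labels.labels.shape)
        sv1 = segment_stats(flat_map(base), labels).per_segment.loc[1,
                                                                    "spatial_variation"]
        sv_scaled = segment_stats(flat_map(base * 3.0), labels).per_segment.loc[
            1, "spatial_variation"]
        assert sv_scaled == pytest.approx(sv1, rel=1e-9)
        doubled = base.mean() + 2.0 * (base - base.mean())  # same mean, 2x SD
        sv2 = segment_stats(flat_map(doubled), labels).per_segment.loc[
            1, "spatial_variation"]
        assert sv2 == pytest.approx(2.0 * sv1, rel=1e-9)


class TestContrastAndCNR:
    def test_contrast_ratio_cases(self):
        vals = np.zeros((10, 10, 1))
        myo = np.zeros(vals.shape, bool)
        blood = np.zeros(vals.shape, bool)
        myo[:5], blood[5:] = True, True
        vals[myo], vals[blood] = 37.5, 15.0
        m = flat_map(vals)
        assert contrast_ratio(m, myo, blood) == pytest.approx(2.5)
        m3 = flat_map(vals * 3.0)
        assert contrast_ratio(m3, myo, blood) == pytest.approx(2.5)

    def test_cnr_arithmetic_and_scale_invariance(self, rng):
        img = np.zeros((12, 12, 1))
        blood = np.zeros(img.shape, bool)
        myo = np.zeros(img.shape, bool)
        lungs = np.zeros(img.shape, bool)
        blood[:4], myo[4:8], lungs[8:] = True, True, True
        img[blood], img[myo] = 10.0, 4.0
        img[lungs] = rng.normal(0, 0.75, size=lungs.sum())
        sd = img[lungs].std(ddof=1)
        assert cnr(img, blood, myo, lungs) == pytest.approx(6.0 / sd)
        assert cnr(2 * img, blood, myo, lungs) == pytest.approx(
            cnr(img, blood, myo, lungs)
        )
        img[blood] = 4.0
        assert cnr(img, blood, myo, lungs) == pytest.approx(0.0, abs=1e-12)


class TestVesselSharpness:
    def _slab_image(self):
        img = np.zeros((24, 24, 8))
        img[10:15, :, :] = 1.0  # step-edge tube along y/z
        cl = np.array([[12.0, 12.0, z] for z in range(1, 7)])
        return img, cl

    def test_ideal_step_edge_is_100(self):
        img, cl = self._slab_image()
        assert vessel_sharpness(img, cl, vessel_diameter=3.0) == pytest.approx(
            100.0, rel=1e-9
        )

    def test_blur_strictly_reduces_sharpness(self):
        from scipy.ndimage import gaussian_filter

        img, cl = self._slab_image()
        blurred = gaussian_filter(img, 1.5)
        assert vessel_sharpness(blurred, cl) < vessel_sharpness(img, cl)

    def test_intensity_scale_invariance(self):
        img, cl = self._slab_image()
        assert vessel_sharpness(3.0 * img, cl) == pytest.approx(
            vessel_sharpness(img, cl), rel=1e-12
        )

    def test_nonpositive_centre_rejected(self):
        img, cl = self._slab_image()
        with pytest.raises(MetricError):
            vessel_sharpness(-img, cl)


def test_dice_of_identical_and_disjoint():
    a = np.zeros((6, 6, 1), bool)
    a[:3] = True
    assert dice(a, a) == 1.0
    assert dice(a, ~a) == 0.0
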