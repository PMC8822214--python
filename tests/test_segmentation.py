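import numpy as np
import pytest

from rbcarea.imaging import GrayImage, HSVImage
from rbcarea.segmentation import (
    CellContour,
    ConfigurationError,
    ContourStatus,
    DegenerateThresholdError,
    compute_s_mean,
    edge_refine,
    extract_outer_contours,
    flag_pending,
    otsu_segment,
    polygon_area,
    select_effective_contours,
    summarize_contours,
)

from conftest import candidate, disk_mask, make_contour


def hsv_from_saturation(sat):
    return HSVImage(hue=np.zeros_like(sat), saturation=sat, value=np.ones_like(sat))


def brute_force_otsu(values, n_bins=256):
    """Exhaustive between-class-variance scan over candidate thresholds."""
    lo, hi = values.min(), values.max()
    best_t, best_var = None, -1.0
    for t in np.linspace(lo, hi, n_bins, endpoint=False)[1:]:
        lower, upper = values[values <= t], values[values > t]
        if len(lower) == 0 or len(upper) == 0:
            continue
        w0, w1 = len(lower) / len(values), len(upper) / len(values)
        var = w0 * w1 * (lower.mean() - upper.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestOtsu:
    def test_bimodal_disks_segmented_exactly(self):
        sat = np.full((128, 128), 0.05)
        disks = disk_mask((128, 128), (40, 40), 15) | disk_mask((128, 128), (90, 90), 12)
        sat[disks] = 0.6
        mask = otsu_segment(hsv_from_saturation(sat))
        np.testing.assert_array_equal(mask, disks)

    def test_constant_saturation_raises_naming_channel(self):
        sat = np.full((64, 64), 0.05)
        with pytest.raises(DegenerateThresholdError, match="saturation"):
            otsu_segment(hsv_from_saturation(sat))

    def test_threshold_between_two_mass_points(self):
        # 50% at 0.1, 50% at 0.9: any variance-maximizing threshold separates them
        sat = np.where(np.arange(64 * 64).reshape(64, 64) % 2 == 0, 0.1, 0.9)
        mask = otsu_segment(hsv_from_saturation(sat))
        np.testing.assert_array_equal(mask, sat > 0.5)
        # and the exhaustive scan agrees the split lands strictly between
        t = brute_force_otsu(sat.ravel())
        assert 0.1 < t < 0.9


class TestEdgeRefine:
    def _disk_scene(self, radius=20, dilate=0):
        from scipy.ndimage import binary_dilation

        gray_arr = np.full((128, 128), 230.0)
        true = disk_mask((128, 128), (64, 64), radius)
        gray_arr[true] = 120.0
        mask = binary_dilation(true, iterations=dilate) if dilate else true
        return mask, GrayImage(gray_arr), true

    def test_aligned_mask_is_fixed_point(self):
        mask, gray, _ = self._disk_scene()
        out = edge_refine(mask, gray)
        np.testing.assert_array_equal(out, mask)

    def test_dilated_mask_snaps_within_one_pixel(self):
        from scipy.ndimage import binary_dilation

        mask, gray, true = self._disk_scene(dilate=2)
        out = edge_refine(mask, gray)
        # every remaining foreground pixel within 1 px (8-connected) of the disk
        one_px_band = binary_dilation(true, structure=np.ones((3, 3), bool))
        assert not (out & ~one_px_band).any()
        assert (out & true).sum() >= 0.95 * true.sum()

    def test_empty_mask_passes_through(self):
        gray = GrayImage(np.full((64, 64), 128.0))
        out = edge_refine(np.zeros((64, 64), bool), gray)
        assert not out.any()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            edge_refine(np.zeros((64, 64), bool), GrayImage(np.zeros((64, 65))))

    def test_foreground_change_capped_at_20_percent(self):
        # featureless gray image: without the cap the whole mask could erode
        rng = np.random.default_rng(0)
        mask = disk_mask((128, 128), (64, 64), 30)
        gray = GrayImage(rng.normal(128, 2, (128, 128)))
        out = edge_refine(mask, gray)
        assert abs(int(out.sum()) - int(mask.sum())) <= 0.2 * mask.sum()


class TestExtractContours:
    def test_single_disk_area_within_5_percent(self):
        mask = disk_mask((64, 64), (32, 32), 10.5)
        cts = extract_outer_contours(mask, 0.1)
        assert len(cts) == 1
        assert cts[0].area_px == pytest.approx(np.pi * 10.5**2, rel=0.05)
        # shoelace agrees with the rasterized pixel count too
        assert cts[0].area_px == pytest.approx(mask.sum(), rel=0.05)

    def test_two_disjoint_disks_give_two_contours(self):
        mask = disk_mask((128, 128), (30, 30), 10) | disk_mask((128, 128), (90, 90), 12)
        assert len(extract_outer_contours(mask, 0.1)) == 2

    def test_annulus_yields_outer_area_only(self):
        outer = disk_mask((96, 96), (48, 48), 20)
        inner = disk_mask((96, 96), (48, 48), 8)
        cts = extract_outer_contours(outer & ~inner, 0.1)
        assert len(cts) == 1
        # area equals the filled outer disk, not the ring
        assert cts[0].area_px == pytest.approx(outer.sum(), rel=0.05)

    def test_empty_mask_gives_empty_list(self):
        assert extract_outer_contours(np.zeros((64, 64), bool), 0.1) == []

    @pytest.mark.parametrize("radius", [8, 12, 20, 31])
    def test_shoelace_matches_pixel_fill_for_disks(self, radius):
        mask = disk_mask((128, 128), (64, 64), radius)
        (ct,) = extract_outer_contours(mask, 0.1)
        assert ct.area_px == pytest.approx(mask.sum(), rel=0.05)

    def test_scaling_equivariance_of_calibration(self):
        mask = disk_mask((64, 64), (32, 32), 12)
        (base,) = extract_outer_contours(mask, 0.1)
        (scaled,) = extract_outer_contours(mask, 0.3)
        assert scaled.area_um2 == pytest.approx(9 * base.area_um2, rel=1e-9)
        assert scaled.area_px == base.area_px


class TestPendingPartition:
    def test_threshold_window(self):
        cts = [candidate(0.2), candidate(5.0), candidate(40.0)]
        for ct in cts:
            ct.status = None
        parts = flag_pending(cts)
        assert [c.area_um2 for c in parts["rejected"]] == [0.2]
        assert [c.area_um2 for c in parts["pending"]] == [5.0]
        assert [c.area_um2 for c in parts["candidate"]] == [40.0]
        assert parts["rejected"][0].status is ContourStatus.REJECTED
        assert parts["pending"][0].status is ContourStatus.PENDING

    def test_empty_input(self):
        parts = flag_pending([])
        assert parts == {"rejected": [], "pending": [], "candidate": []}

    def test_ceiling_value_is_candidate(self):
        ct = candidate(10.0)
        ct.status = None
        parts = flag_pending([ct])
        assert parts["candidate"] == [ct]

    def test_inverted_window_rejected(self):
        with pytest.raises(ConfigurationError):
            flag_pending([], noise_floor_um2=10, pending_ceiling_um2=0.5)


class TestSMean:
    def test_arithmetic(self):
        assert compute_s_mean([candidate(40), candidate(50), candidate(60)]) == pytest.approx(50)
        assert compute_s_mean([candidate(44)]) == pytest.approx(44)

    def test_matches_independent_summation(self):
        rng = np.random.default_rng(2)
        areas = rng.uniform(20, 80, 100)
        cts = [candidate(a) for a in areas]
        total = 0.0
        for a in areas:
            total += a
        assert compute_s_mean(cts) == pytest.approx(total / 100, abs=1e-9)

    def test_empty_field_raises(self):
        with pytest.raises(ValueError, match="empty"):
            compute_s_mean([])


class TestEffectiveSelection:
    def test_window_and_merge_rule(self):
        cts = [candidate(20, 0.95), candidate(60, 0.95), candidate(300, 0.95)]
        effective = select_effective_contours(cts, s_mean_um2=50)
        assert [c.status for c in cts] == [
            ContourStatus.EFFECTIVE,  # 0.3*50 = 15 < 20 < 250
            ContourStatus.EFFECTIVE,
            ContourStatus.MERGED,  # 300 >= 5*50
        ]
        assert len(effective) == 2

    def test_dumbbell_rejected_by_convexity(self):
        # two 20x20 squares joined by a thin 2 px bridge: deeply non-convex
        pts = np.array(
            [
                [0, 0], [0, 20], [9, 20], [9, 50], [0, 50], [0, 70],
                [20, 70], [20, 50], [11, 50], [11, 20], [20, 20], [20, 0],
            ],
            float,
        )
        from scipy.spatial import ConvexHull

        area = polygon_area(pts)
        conv = area / ConvexHull(pts).volume
        assert conv < 0.9  # oracle: the bridge shape is non-convex
        ct = CellContour(points=pts, area_px=area, area_um2=area * 0.01, convexity_ratio=conv)
        ct.status = ContourStatus.CANDIDATE
        select_effective_contours([ct], s_mean_um2=ct.area_um2)
        assert ct.status is ContourStatus.REJECTED

    def test_lower_bound_is_open(self):
        ct = candidate(15.0, 0.95)
        select_effective_contours([ct], s_mean_um2=50)  # a*S_mean = 15 exactly
        assert ct.status is ContourStatus.REJECTED

    @pytest.mark.parametrize("a, b", [(1.0, 5.0), (0.3, 1.0), (1.5, 0.5)])
    def test_bad_window_parameters(self, a, b):
        with pytest.raises(ConfigurationError):
            select_effective_contours([], s_mean_um2=50, a=a, b=b)

    def test_partition_completeness(self):
        rng = np.random.default_rng(3)
        cts = [candidate(a, c) for a, c in zip(rng.uniform(0.1, 400, 50), rng.uniform(0.5, 1.0, 50))]
        for ct in cts:
            ct.status = None
        parts = flag_pending(cts)
        s_mean = compute_s_mean(parts["candidate"])
        select_effective_contours(parts["candidate"], s_mean)
        assert all(
            ct.status in (ContourStatus.PENDING, ContourStatus.EFFECTIVE,
                          ContourStatus.MERGED, ContourStatus.REJECTED)
            for ct in cts
        )
        summ = summarize_contours(cts, s_mean)
        assert summ.n_total == summ.n_pending + summ.n_effective + summ.n_merged + summ.n_rejected

    def test_selection_invariant_under_calibration_rescale(self):
        rng = np.random.default_rng(4)
        areas = rng.uniform(11, 400, 30)
        k2 = 2.0**2  # doubled microns_per_pixel quadruples every area
        base = [candidate(a, 0.95) for a in areas]
        scaled = [candidate(a * k2, 0.95) for a in areas]
        s1 = compute_s_mean(base)
        s2 = compute_s_mean(scaled)
        assert s2 == pytest.approx(k2 * s1, rel=1e-9)
        select_effective_contours(base, s1)
        select_effective_contours(scaled, s2)
        assert [c.status for c in base] == [c.status for c in scaled]
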