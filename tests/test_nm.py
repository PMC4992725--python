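"""NM measurement chain: ROI statistics, thresholding, SN segmentation,
LC localization, CNRs, normalization, asymmetry and repeat averaging."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nigrascan.nm import (
    ImageVolume,
    NmPipelineError,
    RegionStats,
    RoiSpec,
    asymmetry_index,
    average_repeats,
    binary_map,
    cnr_lc,
    cnr_sn,
    jitter_roi,
    lc_intensity,
    locate_lc,
    measure_lc,
    measure_sn,
    percent_cnr,
    region_stats,
    segment_sn,
)
from nigrascan.phantom import LABEL_CODES, default_nm_spec, make_nm_phantom, nm_layout


def _flat_volume(value=0.0, shape=(16, 16, 3), spacing=(0.5, 0.5, 3.0)):
    return ImageVolume(np.full(shape, float(value)), spacing)


class TestRegionStats:
    def test_constant_region(self):
        vol = _flat_volume(7.5)
        roi = RoiSpec("circle", 1, center=(8.0, 8.0), diameter_mm=4.0)
        st_ = region_stats(vol, roi)
        assert (st_.mean, st_.sd) == (7.5, 0.0)

    def test_population_sd(self):
        vol = _flat_volume()
        vol.data[0, 0:3, 0] = [98, 100, 102]
        mask = np.zeros((16, 16), dtype=bool)
        mask[0, 0:3] = True
        st_ = region_stats(vol, RoiSpec("mask", 0, mask=mask))
        assert st_.mean == 100.0
        assert st_.sd == pytest.approx(1.633, abs=5e-4)  # sqrt(8/3), population
        assert st_.n == 3

    def test_circle_voxel_centre_convention(self):
        # 4 mm diameter at 0.5 mm voxels -> radius 4 voxels -> 49 lattice points
        vol = _flat_volume()
        roi = RoiSpec("circle", 0, center=(8.0, 8.0), diameter_mm=4.0)
        assert region_stats(vol, roi).n == 49

    def test_circle_must_fit_inside_grid(self):
        vol = _flat_volume()
        with pytest.raises(NmPipelineError, match="beyond the grid"):
            region_stats(vol, RoiSpec("circle", 0, center=(1.0, 8.0), diameter_mm=4.0))

    def test_noisy_background_recovered_within_sampling_error(self, rng):
        data = rng.normal(100.0, 10.0, (32, 32, 3))
        vol = ImageVolume(data, (0.5, 0.5, 3.0))
        st_ = region_stats(vol, RoiSpec("circle", 1, center=(16.0, 16.0), diameter_mm=4.0))
        assert st_.n >= 49
        assert st_.mean == pytest.approx(100.0, abs=6.0)
        assert st_.sd == pytest.approx(10.0, abs=4.0)


class TestBinaryMap:
    def test_strict_inequality_at_threshold(self):
        vol = _flat_volume(0.0, shape=(8, 8, 1))
        vol.data[1, 1, 0] = 130.0
        vol.data[1, 2, 0] = 130.1
        bg = RegionStats(mean=100.0, sd=10.0, n=50)
        m = binary_map(vol, bg, 0, "left")
        assert not m[1, 1] and m[1, 2]

    def test_high_contrast_sn_fully_above_threshold(self, exact_phantom):
        ph, layout = exact_phantom
        bg = RegionStats(mean=100.0, sd=10.0, n=48)
        m = binary_map(ph.vol, bg, 3, "left", layout.search_mask)
        truth = ph.mask("SN_left")[:, :, 3]
        assert np.all(m[truth])  # CNR 4.28 > 3 forces inclusion

    def test_false_positive_rate_matches_gaussian_tail(self, rng):
        data = rng.normal(100.0, 10.0, (200, 200, 1))
        vol = ImageVolume(data, (0.5, 0.5, 3.0))
        bg = RegionStats(mean=100.0, sd=10.0, n=10**6)
        frac = binary_map(vol, bg, 0, "left").sum() / (100 * 200)
        assert 0.0005 < frac < 0.0025  # P(Z > 3) = 0.00135

    def test_volume_monotone_in_threshold_multiplier(self, noisy_phantom):
        ph, layout = noisy_phantom
        bg = {s: None for s in layout.sn_slices}
        for mult_lo, mult_hi in [(3.0, 4.0), (4.0, 5.0)]:
            lo = measure_sn(ph.vol, layout.bg_rois, layout.search_mask, multiplier=mult_lo)
            hi = measure_sn(ph.vol, layout.bg_rois, layout.search_mask, multiplier=mult_hi)
            for side in ("left", "right"):
                assert hi[side].volume_mm3 <= lo[side].volume_mm3


class TestSegmentSn:
    def test_single_voxel_volume(self):
        vol = _flat_volume(0.0, shape=(8, 8, 1))
        mask = np.zeros((8, 8), dtype=bool)
        mask[2, 2] = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # <4 signal slices
            sn = segment_sn(vol, {0: mask}, "left")
        assert sn.volume_mm3 == pytest.approx(0.75)

    def test_largest_component_retained(self):
        vol = _flat_volume(0.0, shape=(16, 16, 1))
        mask = np.zeros((16, 16), dtype=bool)
        mask[1:6, 1:9] = True          # 40 voxels
        mask[10:13, 12] = True         # 3 voxels, separate
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sn = segment_sn(vol, {0: mask}, "left")
        assert int(sn.mask.sum()) == 40

    def test_missing_side_flagged_not_raised(self):
        vol = _flat_volume(0.0, shape=(8, 8, 2))
        empty = np.zeros((8, 8), dtype=bool)
        sn = segment_sn(vol, {0: empty, 1: empty}, "right")
        assert sn.missing and sn.volume_mm3 == 0.0

    def test_noiseless_phantom_volume_recovered_within_one_voxel(self, exact_phantom):
        ph, layout = exact_phantom
        sn = measure_sn(ph.vol, layout.bg_rois, layout.search_mask)
        for side in ("left", "right"):
            assert abs(sn[side].volume_mm3 - 236.0) <= 0.75
            assert sn[side].slices == [2, 3, 4, 5]


class TestCnrSn:
    def test_construction_value_recovered_exactly(self, exact_phantom):
        ph, layout = exact_phantom
        sn = measure_sn(ph.vol, layout.bg_rois, layout.search_mask)
        assert sn["left"].cnr == pytest.approx(4.28, abs=1e-9)
        assert all(c == pytest.approx(4.28, abs=1e-9)
                   for c in sn["left"].cnr_per_slice.values())

    def test_zero_contrast_gives_zero(self):
        vol = _flat_volume(100.0, shape=(8, 8, 1))
        mask3d = np.zeros((8, 8, 1), dtype=bool)
        mask3d[2, 2, 0] = True
        from nigrascan.nm import SnMeasurement
        sn = SnMeasurement("left", mask3d, [0], 0.75, {}, 0.0)
        out = cnr_sn(vol, sn, {0: RegionStats(100.0, 10.0, 50)})
        assert out.cnr == 0.0

    def test_degenerate_background_raises(self):
        vol = _flat_volume(100.0, shape=(8, 8, 1))
        mask3d = np.ones((8, 8, 1), dtype=bool)
        from nigrascan.nm import SnMeasurement
        sn = SnMeasurement("left", mask3d, [0], 1.0, {}, 0.0)
        with pytest.raises(NmPipelineError, match="SD_CC"):
            cnr_sn(vol, sn, {0: RegionStats(100.0, 0.0, 50)})

    def test_affine_intensity_invariance(self, noisy_phantom):
        ph, layout = noisy_phantom
        base = measure_sn(ph.vol, layout.bg_rois, layout.search_mask)
        a, b = 3.7, 250.0
        scaled = ImageVolume(a * ph.vol.data + b, ph.vol.spacing)
        out = measure_sn(scaled, layout.bg_rois, layout.search_mask)
        for side in ("left", "right"):
            assert out[side].cnr == pytest.approx(base[side].cnr, rel=1e-9)
            assert out[side].volume_mm3 == base[side].volume_mm3


class TestLocateLc:
    def test_phantom_lc_found_on_every_slice(self, exact_phantom):
        ph, layout = exact_phantom
        ventricle = ph.labels == LABEL_CODES["fourth_ventricle"]
        for s in layout.lc_slices:
            for side in ("left", "right"):
                pt = locate_lc(ph.vol, ventricle, s, side)
                assert ph.mask(f"LC_{side}")[pt[0], pt[1], s]

    def test_tie_break_smallest_row_then_column(self):
        vol = _flat_volume(0.0, shape=(16, 16, 1))
        ventricle = np.zeros((16, 16), dtype=bool)
        ventricle[6:10, 8:12] = True
        vol.data[4, 9, 0] = 50.0   # two equal maxima in the band
        vol.data[5, 9, 0] = 50.0
        assert locate_lc(vol, ventricle, 0, "left") == (4, 9)

    def test_empty_band_raises(self):
        vol = _flat_volume(0.0, shape=(16, 16, 1))
        ventricle = np.zeros((16, 16), dtype=bool)
        ventricle[0:3, 0:16] = True  # band exists only on the left side rows
        with pytest.raises(NmPipelineError, match="empty LC search band"):
            locate_lc(vol, ventricle, 0, "right")

    def test_argmax_uniform_over_band_under_pure_noise(self):
        # the located maximum of iid noise should be uniform over the band
        ventricle = np.zeros((16, 16), dtype=bool)
        ventricle[6:10, 6:10] = True
        rng = np.random.default_rng(123)
        counts: dict[tuple[int, int], int] = {}
        n_draws = 2000
        for _ in range(n_draws):
            vol = ImageVolume(rng.normal(size=(16, 16, 1)), (0.5, 0.5, 3.0))
            pt = locate_lc(vol, ventricle, 0, "left")
            counts[pt] = counts.get(pt, 0) + 1
        from scipy.stats import chisquare
        n_cells = 2 * 8 + 2 * 4  # left-side band voxels (Chebyshev radius 2)
        observed = np.zeros(n_cells)
        observed[: len(counts)] = sorted(counts.values(), reverse=True)
        _, p = chisquare(observed, np.full(n_cells, n_draws / n_cells))
        assert p > 0.01


class TestCnrLc:
    def test_construction_value_recovered_exactly(self, exact_phantom):
        ph, layout = exact_phantom
        ventricle = ph.labels == LABEL_CODES["fourth_ventricle"]
        lc = measure_lc(ph.vol, ventricle, list(layout.lc_slices), layout.teg_rois)
        for side in ("left", "right"):
            assert lc[side].cnr == pytest.approx(3.54, abs=1e-9)

    def test_zero_contrast_gives_zero(self):
        vol = _flat_volume(100.0, shape=(16, 16, 1))
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:8, 4:10] = True
        vol.data[2, 2, 0] = 100.0
        roi = RoiSpec("mask", 0, mask=mask)
        vol.data[5, 5, 0] = 101.0  # nonzero SD in the reference
        lc = cnr_lc(vol, {0: (2, 2)}, {0: roi})
        st_ = region_stats(vol, roi)
        assert lc.cnr == pytest.approx((100.0 - st_.mean) / st_.sd)

    def test_edge_lc_uses_available_neighbours_with_warning(self):
        vol = _flat_volume(0.0, shape=(8, 8, 1))
        vol.data[0, 0, 0] = 10.0
        with pytest.warns(UserWarning, match="grid edge"):
            mn = lc_intensity(vol, 0, (0, 0))
        assert mn == pytest.approx(10.0 / 3.0)  # 3 of 5 voxels available

    def test_affine_intensity_invariance(self, noisy_phantom):
        ph, layout = noisy_phantom
        ventricle = ph.labels == LABEL_CODES["fourth_ventricle"]
        base = measure_lc(ph.vol, ventricle, list(layout.lc_slices), layout.teg_rois)
        scaled = ImageVolume(2.5 * ph.vol.data + 40.0, ph.vol.spacing)
        out = measure_lc(scaled, ventricle, list(layout.lc_slices), layout.teg_rois)
        for side in ("left", "right"):
            assert out[side].cnr == pytest.approx(base[side].cnr, rel=1e-9)


class TestNormalizationAndAsymmetry:
    def test_percent_cnr(self):
        assert percent_cnr(4.89, 4.89) == 100.0
        assert percent_cnr(3.54, 4.89) == pytest.approx(72.39, abs=0.01)
        with pytest.raises(NmPipelineError):
            percent_cnr(1.0, 0.0)

    def test_asymmetry_index_values(self):
        assert asymmetry_index(1.0, 1.0) == 0.0
        assert asymmetry_index(2.06, 1.60) == pytest.approx(25.14, abs=0.01)
        assert asymmetry_index(1.0, 0.0) == 200.0

    @given(st.floats(0.01, 1e4), st.floats(0.01, 1e4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_asymmetry_bounded_and_symmetric(self, a, b):
        ai = asymmetry_index(a, b)
        assert 0.0 <= ai <= 200.0
        assert ai == asymmetry_index(b, a)


class TestRepeats:
    def test_mean_and_sample_sd(self):
        reps = [{"v": x} for x in (4.0, 4.2, 4.4, 4.6)]
        mean, sd = average_repeats(reps)
        assert mean["v"] == pytest.approx(4.3)
        assert sd["v"] == pytest.approx(0.258, abs=5e-4)

    def test_identical_repeats_zero_sd(self):
        mean, sd = average_repeats([{"v": 1.5}] * 4)
        assert (mean["v"], sd["v"]) == (1.5, 0.0)

    def test_jitter_keeps_circle_size(self, rng):
        roi = RoiSpec("circle", 2, center=(18.0, 10.0), diameter_mm=4.0)
        j = jitter_roi(roi, rng)
        assert j.diameter_mm == 4.0
        assert abs(j.center[0] - 18.0) <= 1 and abs(j.center[1] - 10.0) <= 1

    def test_repeat_sd_small_on_phantom(self, noisy_phantom):
        from nigrascan.io import measure_nm_subject
        ph, layout = noisy_phantom
        ventricle = ph.labels == LABEL_CODES["fourth_ventricle"]
        res = measure_nm_subject(ph.vol, layout, ventricle, n_repeats=4, seed=1)
        for key in ("cnr_sn_left", "cnr_sn_right"):
            assert res["sd"][key] < 0.05 * abs(res["mean"][key])
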