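"""Threshold-isocontour measurement: maxima, ROIs, background, L/B_m."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rcpvc import datasets, isocontour as iso, phantom as ph
from tests.conftest import BACKGROUND as B, center_seed_voxel


def _flat_volume(value=B, shape=(9, 15, 15)):
    return ph.VolumeImage(np.full(shape, value), ph.DEFAULT_VOXEL_SIZE_MM)


class TestFindLesionMax:
    def test_single_hot_voxel_found(self):
        vol = _flat_volume()
        vol.values[4, 7, 8] = 10 * B
        loc, val = iso.find_lesion_max(vol, (4, 7, 7), search_radius_mm=10)
        assert loc == (4, 7, 8)
        assert val == 10 * B

    def test_equal_maxima_break_to_lowest_index(self):
        vol = _flat_volume()
        vol.values[4, 7, 6] = 10 * B
        vol.values[4, 7, 9] = 10 * B
        loc, _ = iso.find_lesion_max(vol, (4, 7, 7), search_radius_mm=15)
        assert loc == (4, 7, 6)

    def test_blurred_sphere_max_near_center(self, noiseless_sphere_volume):
        vol, spec = noiseless_sphere_volume
        seed = center_seed_voxel(spec)
        loc, _ = iso.find_lesion_max(vol, seed, search_radius_mm=17.0)
        assert np.all(np.abs(np.asarray(loc) - seed) <= 1)

    def test_bad_inputs(self):
        vol = _flat_volume()
        with pytest.raises(ValueError):
            iso.find_lesion_max(vol, (50, 0, 0), 10)
        with pytest.raises(ValueError):
            iso.find_lesion_max(vol, (4, 7, 7), -1)


class TestIsocontourROI:
    def test_mask_nesting_across_thresholds(self, noiseless_sphere_volume):
        vol, spec = noiseless_sphere_volume
        loc, _ = iso.find_lesion_max(vol, center_seed_voxel(spec), 17.0)
        masks = {
            t: iso.isocontour_roi(vol, loc, t).mask for t in (0.5, 0.6, 0.7, 0.8)
        }
        for lo, hi in [(0.5, 0.6), (0.6, 0.7), (0.7, 0.8)]:
            assert np.all(masks[hi] <= masks[lo])  # higher threshold is subset

    def test_d_thr_nonincreasing_in_threshold(self, noiseless_sphere_volume):
        vol, spec = noiseless_sphere_volume
        loc, _ = iso.find_lesion_max(vol, center_seed_voxel(spec), 17.0)
        ds = [
            iso.measure_lesion(vol, iso.isocontour_roi(vol, loc, t)).d_thr_mm
            for t in (0.5, 0.6, 0.7, 0.8)
        ]
        assert np.all(np.diff(ds) <= 0)

    def test_threshold_out_of_range_rejected(self, noiseless_sphere_volume):
        vol, spec = noiseless_sphere_volume
        loc, _ = iso.find_lesion_max(vol, center_seed_voxel(spec), 17.0)
        for bad in (0.0, 1.0, -0.2, 1.4):
            with pytest.raises(ValueError):
                iso.isocontour_roi(vol, loc, bad)

    def test_3d_variant_contains_2d_footprint(self, noiseless_sphere_volume):
        vol, spec = noiseless_sphere_volume
        loc, _ = iso.find_lesion_max(vol, center_seed_voxel(spec), 17.0)
        roi2d = iso.isocontour_roi(vol, loc, 0.6, upsample=1, axial_refine=False)
        mask3d = iso.isocontour_roi_3d(vol, loc, 0.6)
        assert np.all(roi2d.mask <= mask3d[loc[0]])


class TestMeasureLesion:
    def test_single_native_voxel_circle_equivalent_diameter(self):
        # oracle: d = 2 sqrt(A/pi) with A = 4.7 x 4.7 mm^2 -> 5.3029 mm
        vol = _flat_volume()
        vol.values[4, 7, 7] = 10 * B
        roi = iso.isocontour_roi(vol, (4, 7, 7), 0.9, upsample=1, axial_refine=False)
        m = iso.measure_lesion(vol, roi)
        assert roi.mask.sum() == 1
        assert m.d_thr_mm == pytest.approx(2 * math.sqrt(4.7 * 4.7 / math.pi), abs=1e-9)
        assert m.v_thr_ml == pytest.approx(math.pi / 6 * m.d_thr_mm**3 / 1000.0)

    def test_uniform_mask_mean_equals_value(self):
        vol = _flat_volume(value=0.05)
        roi = iso.isocontour_roi(vol, (4, 7, 7), 0.6, upsample=1, axial_refine=False)
        m = iso.measure_lesion(vol, roi)
        assert m.c_thr == pytest.approx(0.05)
        assert m.c_thr <= m.max_value + 1e-12

    def test_37mm_sphere_contour_smaller_than_actual(self):
        spec = ph.single_sphere_phantom(37.0, 5 * B, noise_scale=0.0)
        vol = ph.simulate_phantom(spec)
        m = iso.measure_at_threshold(
            vol, center_seed_voxel(spec), 0.60, search_radius_mm=37.0
        )
        assert m.d_thr_mm < 37.0  # positive percentage difference

    def test_empty_mask_rejected(self):
        vol = _flat_volume()
        roi = iso.isocontour_roi(vol, (4, 7, 7), 0.6, upsample=1, axial_refine=False)
        roi.mask[:] = False
        with pytest.raises(ValueError):
            iso.measure_lesion(vol, roi)


class TestBackground:
    def test_flat_background_recovered_exactly(self):
        vol = _flat_volume(shape=(9, 25, 25))
        lesion = np.zeros(vol.shape[1:], dtype=bool)
        lesion[12, 12] = True
        b = iso.measure_background(vol, (4, 12, 12), lesion, d_thr_mm=10.0)
        assert b == pytest.approx(B)

    def test_rois_exclude_lesion_and_hot_organ_raises(self):
        vol = _flat_volume(shape=(9, 25, 25))
        lesion = np.zeros(vol.shape[1:], dtype=bool)
        lesion[10:15, 10:15] = True
        # ROIs fit around a small lesion
        assert iso.measure_background(vol, (4, 12, 12), lesion, d_thr_mm=10.0) > 0
        # but a lesion mask covering the whole slice cannot be avoided
        with pytest.raises(ValueError, match="manual"):
            iso.measure_background(
                vol, (4, 12, 12), np.ones_like(lesion), d_thr_mm=10.0
            )

    def test_compute_lbm_examples_and_flags(self):
        assert iso.compute_lbm(0.05, 0.05)[0] == pytest.approx(1.0)
        lbm, flags = iso.compute_lbm(0.03774, 0.01258)
        assert lbm == pytest.approx(3.0, abs=0.001)
        assert flags == []
        _, flags = iso.compute_lbm(0.005, 0.01)
        assert any("not hotter" in f for f in flags)
        with pytest.raises(ValueError):
            iso.compute_lbm(0.05, 0.0)


class TestScaleInvariance:
    @settings(max_examples=10, deadline=None)
    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_measurement_invariant_under_global_rescaling(
        self, noiseless_sphere_volume, factor
    ):
        vol, spec = noiseless_sphere_volume
        seed = center_seed_voxel(spec)
        m1 = iso.measure_at_threshold(vol, seed, 0.60, search_radius_mm=17.0)
        scaled = ph.VolumeImage(vol.values * factor, vol.voxel_size_mm)
        m2 = iso.measure_at_threshold(scaled, seed, 0.60, search_radius_mm=17.0)
        assert m2.d_thr_mm == pytest.approx(m1.d_thr_mm, rel=1e-9)
        assert m2.lbm == pytest.approx(m1.lbm, rel=1e-9)
        assert m2.c_thr == pytest.approx(m1.c_thr * factor, rel=1e-9)

    def test_rerun_is_bit_identical(self, noiseless_sphere_volume):
        vol, spec = noiseless_sphere_volume
        seed = center_seed_voxel(spec)
        m1 = iso.measure_at_threshold(vol, seed, 0.60, search_radius_mm=17.0)
        m2 = iso.measure_at_threshold(vol, seed, 0.60, search_radius_mm=17.0)
        assert (m1.c_thr, m1.b_m, m1.d_thr_mm) == (m2.c_thr, m2.b_m, m2.d_thr_mm)


class TestThresholdOptimization:
    def test_percent_diameter_difference_worked_examples(self):
        assert iso.percent_diameter_difference(10, 9) == pytest.approx(10.0)
        assert iso.percent_diameter_difference(10, 12) == pytest.approx(-20.0)
        assert iso.percent_diameter_difference(17, 17) == 0.0
        with pytest.raises(ValueError):
            iso.percent_diameter_difference(0, 5)

    def test_reference_table_selects_60_percent(self):
        table = datasets.threshold_optimization_diameters()
        evals = []
        for thr, grp in table.groupby("threshold"):
            evals.append(
                iso.ThresholdEvaluation(
                    thr, list(grp["d_mm"]), list(grp["d_thr_mm"])
                )
            )
        best, warnings = iso.optimize_threshold(evals)
        assert best == pytest.approx(0.60)
        assert warnings == []
        # the 50% threshold is disqualified by the oversized 10 mm contour
        ev50 = next(e for e in evals if e.threshold_fraction == 0.50)
        assert not ev50.all_nonnegative

    def test_exact_threshold_wins_for_single_sphere(self):
        evals = [
            iso.ThresholdEvaluation(0.5, [10.0], [9.0]),
            iso.ThresholdEvaluation(0.6, [10.0], [10.0]),
            iso.ThresholdEvaluation(0.7, [10.0], [8.0]),
        ]
        best, _ = iso.optimize_threshold(evals)
        assert best == 0.6

    def test_all_negative_falls_back_with_warning(self):
        evals = [
            iso.ThresholdEvaluation(0.5, [10.0], [12.0]),
            iso.ThresholdEvaluation(0.6, [10.0], [11.0]),
        ]
        best, warnings = iso.optimize_threshold(evals)
        assert best == 0.6
        assert warnings
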