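"""RC samples, hyperbolic curve fitting, and the RC lookup surface."""

import numpy as np
import pytest

from rcpvc import calibration as cal


class TestGoldStandardRatio:
    @pytest.mark.parametrize(
        "c_sphere, c_bkg, expected",
        [(0.07363, 0.01258, 5.9), (0.05550, 0.01258, 4.4)],
    )
    def test_reference_session_values(self, c_sphere, c_bkg, expected):
        lb, _ = cal.compute_lb_gs(c_sphere, c_bkg)
        assert round(lb, 1) == expected

    def test_identity_and_errors(self):
        assert cal.compute_lb_gs(0.02, 0.02)[0] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            cal.compute_lb_gs(0.0, 0.01)
        with pytest.raises(ValueError):
            cal.compute_lb_gs(0.01, -1.0)

    def test_uncertainty_propagates_in_quadrature(self):
        lb, u = cal.compute_lb_gs(0.06, 0.012, u_sphere=0.003, u_background=0.0006)
        # oracle: lb * sqrt((0.003/0.06)^2 + (0.0006/0.012)^2)
        assert lb == pytest.approx(5.0)
        assert u == pytest.approx(5.0 * np.hypot(0.05, 0.05))


class TestRecoveryCoefficient:
    def test_identity_division_and_warning(self):
        assert cal.compute_rc(4.0, 4.0)[0] == pytest.approx(1.0)
        rc, flags = cal.compute_rc(2.0, 6.3)
        assert rc == pytest.approx(0.317, abs=5e-4)
        assert flags == []
        _, flags = cal.compute_rc(8.0, 6.3)
        assert "super-recovery" in flags
        with pytest.raises(ValueError):
            cal.compute_rc(2.0, 0.0)


def _samples_from_hyperbola(a, b, c, xs, d=13.0):
    return [
        cal.RCSample(d_actual_mm=d, d_measured_mm=11.0, lbm=x, lb_gs=x / (a - b / (x + c)))
        for x in xs
    ]


class TestCurveFit:
    def test_exact_parameter_recovery_from_noiseless_samples(self):
        a, b, c = 0.85, 0.9, 1.5
        samples = _samples_from_hyperbola(a, b, c, np.linspace(2, 28, 10))
        curve = cal.fit_rc_curve(samples)
        assert curve.a == pytest.approx(a, abs=1e-6)
        assert curve.b == pytest.approx(b, abs=1e-5)
        assert curve.c == pytest.approx(c, abs=1e-4)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_samples_flagged_degenerate(self):
        samples = [
            cal.RCSample(13.0, 11.0, x, x / 0.7) for x in (2.0, 5.0, 10.0, 20.0)
        ]
        curve = cal.fit_rc_curve(samples)
        assert curve.degenerate
        assert curve(7.0) == pytest.approx(0.7)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cal.fit_rc_curve(_samples_from_hyperbola(0.8, 0.5, 1.0, [2, 5, 9]))


def _surface_two_curves():
    c1 = cal.RCCurve(10.0, 0.5, 0.0, 1.0, 1.0, (2.0, 30.0), True)
    c2 = cal.RCCurve(20.0, 0.9, 0.0, 1.0, 1.0, (2.0, 30.0), True)
    return cal.build_rc_surface([c1, c2])


class TestSurface:
    def test_query_at_calibration_diameter_matches_curve(self):
        surface = _surface_two_curves()
        rc, flags = surface.evaluate(10.0, 10.0)
        assert rc == pytest.approx(0.5)
        assert flags == []
        rc, _ = surface.evaluate(10.0, 20.0)
        assert rc == pytest.approx(0.9)

    def test_midpoint_interpolates_linearly_between_two_curves(self):
        surface = _surface_two_curves()
        rc, _ = surface.evaluate(10.0, 15.0)
        assert rc == pytest.approx(0.7)

    def test_out_of_box_queries_clamped_and_flagged(self):
        surface = _surface_two_curves()
        rc, flags = surface.evaluate(45.0, 15.0)
        assert "lbm_clamped" in flags
        assert rc == pytest.approx(surface.evaluate(30.0, 15.0)[0])
        rc, flags = surface.evaluate(10.0, 90.0)
        assert "diameter_clamped" in flags
        assert rc == pytest.approx(0.9)

    def test_single_curve_degenerates_with_warning(self):
        c1 = cal.RCCurve(10.0, 0.5, 0.0, 1.0, 1.0, (2.0, 30.0), True)
        surface = cal.build_rc_surface([c1])
        assert any("single curve" in w for w in surface.warnings)
        assert surface.evaluate(5.0, 33.0)[0] == pytest.approx(0.5)

    def test_surface_bounded_on_calibration_box(self, calibrated):
        surface, _ = calibrated
        dlo = min(c.d_at(x) for c in surface.curves for x in (2, 10, 30))
        dhi = max(c.d_at(x) for c in surface.curves for x in (2, 10, 30))
        for lbm in np.linspace(2, 30, 12):
            for d in np.linspace(dlo, dhi, 12):
                rc, _ = surface.evaluate(float(lbm), float(d))
                assert 0.0 < rc <= 1.1

    def test_yaml_roundtrip_is_lossless(self, calibrated, tmp_path):
        surface, _ = calibrated
        path = tmp_path / "surface.yaml"
        surface.to_yaml(path)
        back = cal.RCSurface.from_yaml(path)
        assert back.threshold_fraction == surface.threshold_fraction
        assert back.lbm_range == tuple(surface.lbm_range)
        for c0, c1 in zip(surface.curves, back.curves):
            assert (c0.a, c0.b, c0.c) == (c1.a, c1.b, c1.c)
            assert c0.d_knots == c1.d_knots
        for q in [(3.0, 11.0), (12.0, 20.0), (25.0, 33.0)]:
            assert back.evaluate(*q)[0] == pytest.approx(surface.evaluate(*q)[0])


class TestSimulatedCalibration:
    def test_samples_live_inside_validity_box(self, calibrated):
        _, samples = calibrated
        for s in samples:
            assert 2.0 <= s.lbm <= 30.0
            assert s.rc > 0

    def test_rc_nondecreasing_with_diameter_at_matched_contrast(self, calibrated):
        _, samples = calibrated
        # group samples by gold-standard level; RC ordering must follow size
        by_level = {}
        for s in samples:
            by_level.setdefault(s.lb_gs, {})[s.d_actual_mm] = s.rc
        checked = 0
        for level, rcs in by_level.items():
            if len(rcs) == 6:
                ordered = [rcs[d] for d in sorted(rcs)]
                assert np.all(np.diff(ordered) > -0.03)  # noise tolerance
                checked += 1
        assert checked >= 4

    def test_small_sphere_underestimation_within_reported_envelope(self, calibrated):
        surface, samples = calibrated
        # PVE severity for the 10 mm sphere: 26-70% underestimation
        small = [s for s in samples if s.d_actual_mm == 10.0]
        assert small
        for s in small:
            assert 26.0 <= 100.0 * (1.0 - s.rc) <= 70.0
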