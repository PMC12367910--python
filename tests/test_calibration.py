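"""Calibration: linear relaxivity fits and the Hill curve + its inverse."""

import json

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from rphmri.calibration import (
    HillCalibration,
    fit_hill,
    fit_relaxivity,
    hill_forward,
    ph_from_r1,
    read_hill_table,
    read_relaxivity_table,
    reconstructed_sensor_calibration,
)
from rphmri.errors import DegenerateDataError, ValidationError

PHANTOM_CONC = np.array([0.0, 0.5, 2.5, 5.0])  # mM


class TestFitRelaxivity:
    def test_exact_line_through_phantom_series(self):
        rates = 0.25 + 1.98 * PHANTOM_CONC
        cal = fit_relaxivity(PHANTOM_CONC, rates)
        assert cal.r1_slope == pytest.approx(1.98, abs=1e-12)
        assert cal.r1_intercept == pytest.approx(0.25, abs=1e-12)
        assert np.allclose(cal.residuals, 0.0, atol=1e-12)
        assert cal.r_squared == pytest.approx(1.0)

    def test_flat_rates_give_zero_slope(self):
        cal = fit_relaxivity(PHANTOM_CONC, np.full(4, 0.7))
        assert cal.r1_slope == pytest.approx(0.0, abs=1e-12)

    def test_two_point_line(self):
        cal = fit_relaxivity([0.0, 1.0], [0.3, 0.3 + 2.1])
        assert cal.r1_slope == pytest.approx(2.1)
        assert cal.r1_intercept == pytest.approx(0.3)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateDataError):
            fit_relaxivity([1.0, 1.0, 1.0], [0.5, 0.6, 0.7])
        with pytest.raises(ValidationError):
            fit_relaxivity([0.0, 1.0], [-0.1, 0.5])
        with pytest.raises(ValidationError):
            fit_relaxivity([-1.0, 1.0], [0.1, 0.5])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_normal_equations_oracle(self, seed):
        """Slope/intercept agree with a brute-force normal-equations solve."""
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 12)
        c = np.sort(rng.uniform(0, 5, n))
        c[0] = 0.0  # ensure distinct span incl. blank
        r = np.abs(rng.normal(1.0, 0.5)) * c + abs(rng.normal(0.5, 0.2)) + rng.normal(0, 0.01, n)
        r = np.clip(r, 0, None)
        X = np.column_stack([c, np.ones_like(c)])
        slope_o, intercept_o = np.linalg.solve(X.T @ X, X.T @ r)
        cal = fit_relaxivity(c, r)
        assert cal.r1_slope == pytest.approx(slope_o, rel=1e-9, abs=1e-9)
        assert cal.r1_intercept == pytest.approx(intercept_o, rel=1e-9, abs=1e-9)


valid_cals = st.builds(
    HillCalibration,
    top=st.floats(1.5, 3.0),
    bottom=st.floats(0.3, 1.0),
    log_ic50=st.floats(5.8, 7.0),
    hill_slope=st.floats(0.5, 2.5),
).filter(lambda c: c.top > c.bottom + 0.3)


class TestHillForwardInverse:
    def test_midpoint_and_asymptotes(self, sensor_cal):
        mid = hill_forward(sensor_cal.log_ic50, sensor_cal)
        assert mid == pytest.approx((sensor_cal.top + sensor_cal.bottom) / 2, rel=1e-12)
        assert hill_forward(100.0, sensor_cal) == pytest.approx(sensor_cal.bottom, abs=1e-9)
        assert hill_forward(-100.0, sensor_cal) == pytest.approx(sensor_cal.top, abs=1e-9)

    def test_reconstructed_fixture_reproduces_anchors(self, sensor_cal):
        """The default sensor curve passes through 0.86 at pH 7.4 and 2.7x that at 5.5."""
        assert hill_forward(7.4, sensor_cal) == pytest.approx(0.86, abs=1e-6)
        assert hill_forward(5.5, sensor_cal) == pytest.approx(2.7 * 0.86, abs=1e-6)

    @given(valid_cals)
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_ph(self, cal):
        grid = np.linspace(3.0, 10.0, 200)
        vals = hill_forward(grid, cal)
        assert np.all(np.diff(vals) < 0)
        assert vals.min() > cal.bottom and vals.max() < cal.top

    def test_inverse_at_midpoint(self, sensor_cal):
        r_mid = (sensor_cal.top + sensor_cal.bottom) / 2
        assert ph_from_r1(r_mid, sensor_cal) == pytest.approx(sensor_cal.log_ic50, abs=1e-12)

    @given(valid_cals, st.floats(5.5, 7.4))
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_identity(self, cal, ph):
        r1 = hill_forward(ph, cal)
        eps = 0.01 * (cal.top - cal.bottom)
        # inside the guard band the inversion deliberately returns NaN
        assume(cal.bottom + eps < r1 < cal.top - eps)
        assert ph_from_r1(r1, cal) == pytest.approx(ph, abs=1e-9)

    def test_boundary_and_nonfinite_yield_nan(self, sensor_cal):
        assert np.isnan(ph_from_r1(sensor_cal.top, sensor_cal))
        assert np.isnan(ph_from_r1(sensor_cal.bottom, sensor_cal))
        assert np.isnan(ph_from_r1(np.nan, sensor_cal))
        assert np.isnan(ph_from_r1(np.inf, sensor_cal))
        # just inside the guard band is still invalid
        eps = 0.01 * (sensor_cal.top - sensor_cal.bottom)
        assert np.isnan(ph_from_r1(sensor_cal.top - 0.5 * eps, sensor_cal))

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValidationError):
            HillCalibration(top=1.0, bottom=2.0, log_ic50=6.5, hill_slope=1.0)
        with pytest.raises(ValidationError):
            HillCalibration(top=2.0, bottom=1.0, log_ic50=6.5, hill_slope=-1.0)
        with pytest.raises(ValidationError):
            HillCalibration(top=2.0, bottom=1.0, log_ic50=6.5, hill_slope=1.0,
                            valid_ph_range=(7.4, 5.5))


HILL_PH_POINTS = np.array([5.0, 5.5, 6.0, 6.5, 7.0, 7.4, 8.0])


class TestFitHill:
    def test_noiseless_self_consistency(self, sensor_cal):
        r1 = hill_forward(HILL_PH_POINTS, sensor_cal)
        fit = fit_hill(HILL_PH_POINTS, r1).calibration
        for name in ("top", "bottom", "log_ic50", "hill_slope"):
            assert getattr(fit, name) == pytest.approx(getattr(sensor_cal, name), rel=1e-6)

    @given(valid_cals)
    @settings(max_examples=30, deadline=None)
    def test_noiseless_recovery_random_parameters(self, cal):
        r1 = hill_forward(HILL_PH_POINTS, cal)
        fit = fit_hill(HILL_PH_POINTS, r1).calibration
        for name in ("top", "bottom", "log_ic50", "hill_slope"):
            assert getattr(fit, name) == pytest.approx(getattr(cal, name), rel=1e-5)

    def test_noisy_fit_tracks_true_curve(self, sensor_cal):
        """With 1% noise the fitted curve stays within ~2% of the true curve."""
        rng = np.random.default_rng(42)
        r1 = hill_forward(HILL_PH_POINTS, sensor_cal)
        fit = fit_hill(HILL_PH_POINTS, r1 + rng.normal(0, 0.01 * sensor_cal.top, r1.shape))
        grid = np.linspace(5.5, 7.4, 50)
        dev = np.abs(hill_forward(grid, fit.calibration) - hill_forward(grid, sensor_cal))
        assert dev.max() < 0.02 * sensor_cal.top

    def test_degenerate_flat_data(self):
        with pytest.raises(DegenerateDataError):
            fit_hill(HILL_PH_POINTS, np.full_like(HILL_PH_POINTS, 1.3))

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            fit_hill([5.5, 6.5, 7.4], [2.0, 1.5, 0.9])


class TestPersistence:
    def test_json_roundtrip(self, sensor_cal, tmp_path):
        p = tmp_path / "cal.json"
        sensor_cal.save(p)
        back = HillCalibration.load(p)
        assert back == sensor_cal
        keys = set(json.loads(p.read_text()))
        assert {"top", "bottom", "log_ic50", "hill_slope", "valid_ph_range"} <= keys

    def test_csv_readers(self, tmp_path):
        p = tmp_path / "rel.csv"
        p.write_text("concentration_mM,R1_per_s\n0,0.25\n0.5,1.24\n")
        c, r = read_relaxivity_table(p)
        assert c.tolist() == [0.0, 0.5] and r.tolist() == [0.25, 1.24]
        q = tmp_path / "hill.csv"
        q.write_text("pH,r1\n5.5,2.3\n7.4,0.86\n")
        ph, r1 = read_hill_table(q)
        assert ph.tolist() == [5.5, 7.4]

    def test_reconstructed_fixture_requires_bracketing_plateaus(self):
        with pytest.raises(ValidationError):
            reconstructed_sensor_calibration(top=2.0)  # below the acidic anchor
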