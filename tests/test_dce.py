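"""DCE series: baselines, M0, signal-to-R1 inversion, curves and TMI."""

import numpy as np
import pytest

from rphmri.dce import (
    DCECurve,
    Injection,
    InjectionSchedule,
    VolumeSeries,
    baseline_signal,
    compute_m0,
    compute_tmi,
    extract_curve,
    frames_in_window,
    signal_to_r1,
)
from rphmri.errors import ValidationError
from rphmri.t1map import AcquisitionParams, spgr_signal

ACQ = AcquisitionParams(tr_ms=13.0, flip_angles_deg=(15.0,), frame_interval_s=5.0)


def make_series(data, dt=5.0, theta=15.0):
    data = np.asarray(data, float)
    times = np.arange(data.shape[-1]) * dt
    return VolumeSeries(data=data, frame_times_s=times, params=ACQ, flip_angle_deg=theta)


class TestVolumeSeriesValidation:
    def test_rejects_bad_shapes_and_times(self):
        with pytest.raises(ValidationError):
            VolumeSeries(np.zeros((4, 4, 4)), [0.0], ACQ, 15.0)  # 3D
        with pytest.raises(ValidationError):
            VolumeSeries(np.zeros((2, 2, 2, 3)), [0.0, 2.0, 1.0], ACQ, 15.0)
        with pytest.raises(ValidationError):
            VolumeSeries(-np.ones((2, 2, 2, 2)), [0.0, 1.0], ACQ, 15.0)

    def test_schedule_rejects_overlapping_windows(self):
        with pytest.raises(ValidationError):
            InjectionSchedule(
                injections=[Injection("a", "control", 30.0), Injection("b", "sensor", 120.0)],
                post_window_s=100.0, baseline_window_s=30.0,
            )


class TestBaseline:
    def test_mean_of_two_frames(self):
        data = np.stack(
            [np.full((2, 2, 1), 10.0), np.full((2, 2, 1), 20.0), np.full((2, 2, 1), 60.0)],
            axis=-1,
        )
        series = make_series(data)
        out = baseline_signal(series, [0, 1])
        assert np.allclose(out, 15.0)

    def test_single_frame_window(self):
        series = make_series(np.arange(8.0).reshape(1, 1, 1, 8))
        assert baseline_signal(series, [3]) == pytest.approx(3.0)

    def test_empty_window_raises(self):
        series = make_series(np.ones((1, 1, 1, 4)))
        with pytest.raises(ValidationError):
            baseline_signal(series, [])


class TestComputeM0:
    def test_theta_90_closed_form(self):
        s0 = np.full((2, 2, 2), 80.0)
        t10 = np.full((2, 2, 2), 1000.0)
        m0, ok = compute_m0(s0, t10, 90.0, 13.0)
        e10 = np.exp(-13.0 / 1000.0)
        assert np.allclose(m0[ok], 80.0 / (1 - e10))

    def test_algebraic_roundtrip_from_forward_model(self):
        m0_true, t10 = 1234.5, 850.0
        s0 = spgr_signal(m0_true, t10, 13.0, 15.0)
        m0, ok = compute_m0(np.full((1, 1, 1), s0), np.full((1, 1, 1), t10), 15.0, 13.0)
        assert ok.all()
        assert m0.ravel()[0] == pytest.approx(m0_true, abs=1e-9 * m0_true)

    def test_long_tr_limit(self):
        s0 = np.array([[[50.0]]])
        m0, _ = compute_m0(s0, np.array([[[1.0]]]), 30.0, 1000.0)  # TR >> T10
        assert m0.ravel()[0] == pytest.approx(50.0 / np.sin(np.deg2rad(30.0)), rel=1e-6)

    def test_zero_theta_rejected(self):
        with pytest.raises(ValidationError):
            compute_m0(np.ones((1, 1, 1)), np.ones((1, 1, 1)), 0.0, 13.0)


class TestSignalToR1:
    T10 = 500.0  # ms -> R1 = 2.0 s^-1

    def maps(self):
        t10 = np.full((1, 1, 1), self.T10)
        m0 = np.full((1, 1, 1), 1000.0)
        s0 = spgr_signal(m0, t10, 13.0, 15.0)
        return s0, m0, t10

    def test_baseline_identity(self):
        s0, m0, t10 = self.maps()
        r1, ok, sat = signal_to_r1(s0, s0, m0, t10, 15.0, 13.0)
        assert ok.all() and not sat.any()
        assert r1.ravel()[0] == pytest.approx(1000.0 / self.T10, abs=1e-9)

    def test_forward_model_oracle(self):
        """Signal generated at R1 = 2 s^-1 inverts back to exactly 2 s^-1."""
        s0, m0, t10 = self.maps()
        s_t = spgr_signal(m0, 500.0, 13.0, 15.0)
        r1, ok, _ = signal_to_r1(s_t, s0, m0, t10, 15.0, 13.0)
        assert r1.ravel()[0] == pytest.approx(2.0, abs=1e-9)

    def test_saturation_above_ceiling(self):
        s0, m0, t10 = self.maps()
        ceiling = m0 * np.sin(np.deg2rad(15.0))
        r1, ok, sat = signal_to_r1(ceiling * 1.01, s0, m0, t10, 15.0, 13.0)
        assert sat.all() and not ok.any()
        assert np.isnan(r1).all()

    def test_grid_roundtrip(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            r1_true = rng.uniform(0.3, 10.0)
            m0v = rng.uniform(200, 2000)
            theta = rng.uniform(5, 60)
            t10 = rng.uniform(300, 3000)
            tr = 13.0
            t10_map = np.full((1, 1, 1), t10)
            m0 = np.full((1, 1, 1), m0v)
            s0 = spgr_signal(m0, t10_map, tr, theta)
            s_t = spgr_signal(m0, 1000.0 / r1_true, tr, theta)
            r1, ok, _ = signal_to_r1(s_t, s0, m0, t10_map, theta, tr)
            assert ok.all()
            assert r1.ravel()[0] == pytest.approx(r1_true, abs=1e-9)


class TestCurvesAndTmi:
    def test_extract_curve_means(self):
        data = np.zeros((2, 1, 1, 3))
        data[0, 0, 0] = [1.0, 1.0, 1.0]
        data[1, 0, 0] = [3.0, 3.0, 3.0]
        series = make_series(data)
        roi = np.ones((2, 1, 1), dtype=bool)
        curve = extract_curve(series, roi)
        assert np.allclose(curve.intensities, 2.0)
        single = extract_curve(series, np.array([[[True]], [[False]]]))
        assert np.allclose(single.intensities, 1.0)

    def test_extract_curve_empty_roi(self):
        series = make_series(np.ones((2, 2, 2, 3)))
        with pytest.raises(ValidationError):
            extract_curve(series, np.zeros((2, 2, 2), dtype=bool))

    def test_tmi_arithmetic(self):
        """Injection at 60 s, peak at frame 12 of a 12 s series -> 1.4 min."""
        times = np.arange(20) * 12.0
        intens = np.zeros(20)
        intens[12] = 5.0
        curve = DCECurve(times, intens)
        assert compute_tmi(curve, 60.0, 200.0) == pytest.approx(1.4)

    def test_tmi_peak_at_injection_frame(self):
        curve = DCECurve(np.arange(10) * 10.0, np.r_[0, 0, 0, 9, 5, 4, 3, 2, 1, 0.0])
        assert compute_tmi(curve, 30.0, 60.0) == 0.0

    def test_tmi_plateau_ties_to_earliest(self):
        curve = DCECurve(np.arange(10) * 10.0, np.r_[0, 0, 0, 7, 7, 7, 7, 0, 0, 0.0])
        assert compute_tmi(curve, 20.0, 70.0) == pytest.approx(10.0 / 60.0)

    def test_tmi_empty_window(self):
        curve = DCECurve(np.arange(5) * 10.0, np.ones(5))
        with pytest.raises(ValidationError):
            compute_tmi(curve, 100.0, 50.0)

    @pytest.mark.parametrize("transform", [np.exp, np.sqrt, lambda x: 3 * x + 7])
    def test_tmi_invariant_under_monotone_transform(self, transform):
        rng = np.random.default_rng(5)
        intens = np.abs(rng.normal(10, 3, 40)).cumsum() / np.arange(1, 41)
        curve = DCECurve(np.arange(40) * 6.0, intens)
        tmi0 = compute_tmi(curve, 30.0, 150.0)
        curve2 = DCECurve(curve.times_s, transform(intens))
        assert compute_tmi(curve2, 30.0, 150.0) == tmi0


def test_frames_in_window_inclusive():
    t = np.arange(10) * 5.0
    assert frames_in_window(t, 10.0, 20.0).tolist() == [2, 3, 4]
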