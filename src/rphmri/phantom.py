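"""Digital phantom: synthetic dual-injection pH-MRI sessions with known truth.

The phantom emulates the study design that motivates ratiometric pH MRI: a
subcutaneous tumor with an **acidic, poorly perfused core** and a **less
acidic, better perfused rim**, imaged at 7 T through two sequential bolus
injections — first a pH-insensitive control chelate (the concentration
reporter), then the pH sensor at the same dose.  Two features of the real
experiment are made *exact* by construction:

* both injections share one per-voxel peak-concentration field
  (``c_peak_truth``), so the pipeline's equal-concentration assumption holds
  identically and any end-to-end bias is attributable to the implementation;
* relaxation is fast-exchange linear, R1(t) = 1/T10 + r1_agent * C(t), with a
  constant r1 for the control and the Hill curve evaluated at the local true
  pH for the sensor.

Wash-in/wash-out is a gamma-variate surrogate,

    C(t) = c_peak * (tau/tp)^a * exp(a * (1 - tau/tp)),  tau = t - onset,

whose maximum is exactly ``c_peak`` at tau = tp.  Noise is Rician (magnitude
MRI), with the SD given in signal units at baseline; every stochastic call
takes an explicit seed and there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import HillCalibration, LinearRelaxivity, hill_forward
from .dce import Injection, InjectionSchedule, VolumeSeries
from .errors import ValidationError
from .t1map import AcquisitionParams, spgr_signal

__all__ = [
    "KineticsParams",
    "DigitalPhantom",
    "SimulatedSession",
    "uptake_curve",
    "make_phantom",
    "simulate_session",
    "rician",
    "default_acquisition",
    "default_schedule",
    "default_control_calibration",
]

# Desk-scale defaults mirroring the in-vivo protocol: SPGR TR 13 ms, VFA
# angles {2, 5, 15, 30, 50, 70} deg, DCE flip angle 15 deg.
DEFAULT_FLIP_ANGLES = (2.0, 5.0, 15.0, 30.0, 50.0, 70.0)
DEFAULT_TR_MS = 13.0
DEFAULT_DCE_FLIP_DEG = 15.0
DEFAULT_FRAME_INTERVAL_S = 5.0


@dataclass
class KineticsParams:
    """Gamma-variate bolus kinetics (onset delay, time to peak, shape)."""

    onset_s: float = 5.0
    time_to_peak_s: float = 60.0
    shape_a: float = 3.0

    def __post_init__(self):
        if min(self.onset_s, self.time_to_peak_s, self.shape_a) <= 0:
            raise ValidationError("kinetics parameters must all be positive")


@dataclass
class DigitalPhantom:
    """Ground-truth maps shared by both injections."""

    ph_truth: np.ndarray
    c_peak_truth: np.ndarray
    t10_truth_ms: np.ndarray
    m0_truth: np.ndarray
    tumor_mask: np.ndarray
    core_mask: np.ndarray
    rim_mask: np.ndarray
    seed: int = 0

    @property
    def shape(self):
        return self.ph_truth.shape


@dataclass
class SimulatedSession:
    """Everything the pipeline needs, plus the truth it should recover."""

    vfa_stack: np.ndarray  # (..., n_angles)
    vfa_params: AcquisitionParams
    dce: VolumeSeries
    schedule: InjectionSchedule
    control_cal: LinearRelaxivity
    sensor_cal: HillCalibration
    phantom: DigitalPhantom
    noise_sd: float
    seed: int


def uptake_curve(t, k: KineticsParams, c_peak):
    """Gamma-variate concentration at time(s) t (seconds); peak = c_peak."""
    t = np.asarray(t, dtype=float)
    tau = t - k.onset_s
    out = np.zeros(np.shape(tau), dtype=float)
    pos = tau > 0
    x = np.asarray(tau, dtype=float)[pos] / k.time_to_peak_s
    out[pos] = x**k.shape_a * np.exp(k.shape_a * (1.0 - x))
    out = out * c_peak
    return out if out.ndim else float(out)


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def make_phantom(
    shape=(48, 64, 8),
    tumor_center=None,
    tumor_semiaxes=(14.0, 18.0, 3.0),
    ph_core: float = 6.51,
    ph_rim: float = 6.74,
    c_core_mM: float = 0.4,
    c_rim_mM: float = 0.8,
    t10_tumor_ms: float = 2000.0,
    t10_tissue_ms: float = 1800.0,
    m0_tumor: float = 1100.0,
    m0_tissue: float = 1000.0,
    ph_background: float = 7.2,
    c_background_mM: float = 0.2,
    core_fraction: float = 0.7,
    seed: int = 0,
) -> DigitalPhantom:
    """Ellipsoidal tumor with radial core-to-rim pH and concentration ramps.

    pH and peak concentration are constant at the core value for normalized
    elliptical radius rho < 0.5, ramp smoothly to the rim value by rho = 0.9,
    and hold it to the boundary; the core mask is rho <= ``core_fraction``
    (matching a 0.7 centroid-scaling of the whole-tumor ROI for an ellipse).
    The truth maps are deterministic — the seed is stored for the noise
    stages only.  Defaults place the core more acidic and less concentrated
    than the rim, the structure the method is designed to disentangle.
    """
    if ph_core > ph_rim:
        raise ValidationError("ph_core must be <= ph_rim")
    shape = tuple(int(n) for n in shape)
    if tumor_center is None:
        tumor_center = tuple(n / 2.0 for n in shape)
    semi = np.asarray(tumor_semiaxes, dtype=float)
    center = np.asarray(tumor_center, dtype=float)
    if np.any(center - semi < 0) or np.any(center + semi > np.asarray(shape)):
        raise ValidationError("tumor ellipsoid does not fit inside the image")

    grid = np.indices(shape, dtype=float)
    rho = np.sqrt(sum(((grid[k] - center[k]) / semi[k]) ** 2 for k in range(3)))
    tumor = rho <= 1.0
    core = rho <= core_fraction
    rim = tumor & ~core

    ramp = _smoothstep((rho - 0.5) / 0.4)  # 0 in the deep core, 1 at the edge
    ph = np.full(shape, ph_background, dtype=float)
    ph[tumor] = ph_core + (ph_rim - ph_core) * ramp[tumor]
    c_peak = np.full(shape, c_background_mM, dtype=float)
    c_peak[tumor] = c_core_mM + (c_rim_mM - c_core_mM) * ramp[tumor]
    t10 = np.full(shape, t10_tissue_ms, dtype=float)
    t10[tumor] = t10_tumor_ms
    m0 = np.full(shape, m0_tissue, dtype=float)
    m0[tumor] = m0_tumor

    return DigitalPhantom(
        ph_truth=ph, c_peak_truth=c_peak, t10_truth_ms=t10, m0_truth=m0,
        tumor_mask=tumor, core_mask=core, rim_mask=rim, seed=int(seed),
    )


def rician(signal, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Rician-distributed magnitude sample around a noiseless signal."""
    signal = np.asarray(signal, dtype=float)
    if sd == 0:
        return signal.copy()
    re = signal + rng.normal(0.0, sd, signal.shape)
    im = rng.normal(0.0, sd, signal.shape)
    return np.sqrt(re**2 + im**2)


def default_acquisition(frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S) -> AcquisitionParams:
    return AcquisitionParams(
        tr_ms=DEFAULT_TR_MS,
        flip_angles_deg=DEFAULT_FLIP_ANGLES,
        te_ms=2.4,
        frame_interval_s=frame_interval_s,
        voxel_size_mm=(0.4, 0.4, 3.0),
    )


def default_schedule(
    control_time_s: float = 30.0,
    sensor_time_s: float = 630.0,
    post_window_s: float = 300.0,
    baseline_window_s: float = 30.0,
    dose_mmol_per_kg: float = 0.25,
) -> InjectionSchedule:
    """Control-then-sensor schedule at equal dose (desk-scale timings)."""
    return InjectionSchedule(
        injections=[
            Injection("control", "control", control_time_s, dose_mmol_per_kg),
            Injection("sensor", "sensor", sensor_time_s, dose_mmol_per_kg),
        ],
        post_window_s=post_window_s,
        baseline_window_s=baseline_window_s,
    )


def default_control_calibration() -> LinearRelaxivity:
    """pH-insensitive control chelate in serum at 7 T: r1 = 1.98 mM^-1 s^-1."""
    return LinearRelaxivity(r1_slope=1.98, r1_intercept=0.4, field_strength_T=7.0, medium="serum")


def simulate_session(
    phantom: DigitalPhantom,
    acq: AcquisitionParams | None = None,
    schedule: InjectionSchedule | None = None,
    control_cal: LinearRelaxivity | None = None,
    sensor_cal: HillCalibration | None = None,
    kinetics: KineticsParams | None = None,
    noise_sd: float = 0.0,
    baseline_snr: float | None = None,
    dce_flip_deg: float = DEFAULT_DCE_FLIP_DEG,
    duration_s: float | None = None,
    dose_scale: float = 1.0,
    seed: int = 0,
) -> SimulatedSession:
    """Forward-simulate a full two-injection session from a phantom.

    Both boluses carry ``dose_scale * c_peak_truth`` (identical fields — the
    equal-concentration assumption is exact).  The dynamic R1 is the linear
    superposition of baseline, control and sensor contributions; the signal
    follows the SPGR forward model; Rician noise of the given SD (or derived
    from ``baseline_snr`` = mean tumor baseline signal / SD) is added to both
    the DCE frames and the VFA stack.  Same seed, same params => bit-identical
    outputs.
    """
    from .calibration import reconstructed_sensor_calibration  # local: default only

    acq = acq or default_acquisition()
    schedule = schedule or default_schedule()
    control_cal = control_cal or default_control_calibration()
    sensor_cal = sensor_cal or reconstructed_sensor_calibration()
    kinetics = kinetics or KineticsParams()

    controls = schedule.by_role("control")
    sensors = schedule.by_role("sensor")
    if len(controls) != 1 or len(sensors) != 1:
        raise ValidationError("schedule must contain exactly one control and one sensor injection")
    if controls[0].time_s >= sensors[0].time_s:
        raise ValidationError("control injection must precede the sensor injection")
    if acq.frame_interval_s is None:
        raise ValidationError("acquisition needs frame_interval_s for the dynamic series")

    if duration_s is None:
        duration_s = sensors[0].time_s + schedule.post_window_s + 30.0
    n_frames = int(np.floor(duration_s / acq.frame_interval_s)) + 1
    frame_times = np.arange(n_frames) * acq.frame_interval_s

    shape = phantom.shape
    n_vox = int(np.prod(shape))
    c_peak = dose_scale * phantom.c_peak_truth.reshape(-1)
    r10 = 1000.0 / phantom.t10_truth_ms.reshape(-1)  # s^-1
    r1_sensor = hill_forward(phantom.ph_truth, sensor_cal).reshape(-1)

    def bolus(injection_time_s: float) -> np.ndarray:
        k = KineticsParams(
            onset_s=injection_time_s + kinetics.onset_s,
            time_to_peak_s=kinetics.time_to_peak_s,
            shape_a=kinetics.shape_a,
        )
        return uptake_curve(frame_times, k, 1.0)

    g_ctrl = bolus(controls[0].time_s)
    g_sens = bolus(sensors[0].time_s)

    # (n_vox, n_frames) dynamic R1 in s^-1
    r1_t = (
        r10[:, None]
        + control_cal.r1_slope * c_peak[:, None] * g_ctrl[None, :]
        + r1_sensor[:, None] * c_peak[:, None] * g_sens[None, :]
    )
    t1_t_ms = 1000.0 / r1_t
    m0 = phantom.m0_truth.reshape(-1)
    signal = spgr_signal(m0[:, None], t1_t_ms, acq.tr_ms, dce_flip_deg)

    if baseline_snr is not None:
        base = float(signal[phantom.tumor_mask.reshape(-1), 0].mean())
        noise_sd = base / baseline_snr

    rng = np.random.default_rng(seed)
    dce_data = rician(signal, noise_sd, rng).reshape(shape + (n_frames,))

    vfa_clean = np.stack(
        [spgr_signal(phantom.m0_truth, phantom.t10_truth_ms, acq.tr_ms, a)
         for a in acq.flip_angles_deg], axis=-1,
    )
    vfa_stack = rician(vfa_clean, noise_sd, rng)

    series = VolumeSeries(
        data=dce_data, frame_times_s=frame_times, params=acq, flip_angle_deg=dce_flip_deg
    )
    return SimulatedSession(
        vfa_stack=vfa_stack, vfa_params=acq, dce=series, schedule=schedule,
        control_cal=control_cal, sensor_cal=sensor_cal, phantom=phantom,
        noise_sd=float(noise_sd), seed=int(seed),
    )
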