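"""The ratiometric pH-mapping core.

Stages, mirroring the dual-injection experiment:

1. pre-contrast T10/S0 from the variable-flip-angle stack;
2. the dynamic series converted to R1(t);
3. per-injection temporal peak ("temporal MIP"): the per-voxel maximum of
   R1(t) within the post-injection window — equivalent to a maximum-intensity
   projection of the raw signal because the SPGR signal is monotone in R1;
4. Delta-R1 of the control injection divided by the control relaxivity gives
   the **concentration map**;
5. the same concentration field is assumed for the sensor injection (the
   method's central assumption), so the sensor's Delta-R1 divided by the
   concentration map gives the per-voxel **sensor relaxivity map**;
6. the Hill inverse turns relaxivity into the **pH map**.

Each injection uses its own baseline (frames averaged immediately before it),
so residual signal of the first agent is absorbed into the second baseline.
Invalid/saturated voxels propagate as mask bits, never as exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import HillCalibration, LinearRelaxivity, ph_from_r1, DEFAULT_GUARD_FRAC
from .dce import (
    InjectionSchedule,
    VolumeSeries,
    baseline_signal,
    compute_m0,
    compute_tmi,
    extract_curve,
    frames_in_window,
    r1_series,
)
from .errors import ConfigurationError, ValidationError
from .t1map import AcquisitionParams, T1MapResult, fit_vfa

__all__ = ["PhMapResult", "temporal_peak_r1", "concentration_map", "sensor_r1_map", "ph_map", "run_rph"]

DEFAULT_C_MIN_MM = 0.05


@dataclass
class PhMapResult:
    """All maps produced by a ratiometric pH run, plus QC scalars."""

    conc_map: np.ndarray
    sensor_r1_map: np.ndarray
    ph_map: np.ndarray
    valid_mask: np.ndarray
    qc: dict
    # intermediates, kept for inspection/writing
    t1_result: T1MapResult | None = None
    delta_r1_control: np.ndarray | None = None
    delta_r1_sensor: np.ndarray | None = None
    peak_time_control_s: np.ndarray | None = None
    peak_time_sensor_s: np.ndarray | None = None


def temporal_peak_r1(r1_4d: np.ndarray, frame_indices, frame_times_s):
    """Per-voxel max of R1(t) over a frame window and the time it occurs.

    Ties resolve to the earliest frame (argmax semantics).  NaN frames are
    ignored; voxels NaN throughout the window peak as NaN.
    """
    idx = np.asarray(frame_indices, dtype=int)
    if idx.size == 0:
        raise ValidationError("temporal peak window contains no frames")
    sub = r1_4d[..., idx]
    with np.errstate(invalid="ignore"):
        arg = np.nanargmax(np.where(np.isfinite(sub), sub, -np.inf), axis=-1)
    peak = np.take_along_axis(sub, arg[..., None], axis=-1)[..., 0]
    times = np.asarray(frame_times_s, dtype=float)[idx][arg]
    return peak, times


def concentration_map(delta_r1_control, control_cal: LinearRelaxivity, c_min_mM: float = DEFAULT_C_MIN_MM):
    """Concentration map C = Delta-R1 / r1_slope; masked below ``c_min_mM``."""
    if control_cal.r1_slope <= 0:
        raise ValidationError("control relaxivity slope must be > 0")
    d = np.asarray(delta_r1_control, dtype=float)
    conc = d / control_cal.r1_slope
    mask = np.isfinite(conc) & (conc >= c_min_mM)
    out = np.where(mask, conc, np.nan)
    return out, mask


def sensor_r1_map(delta_r1_sensor, conc_mM, mask):
    """Per-voxel sensor relaxivity r1 = Delta-R1_sensor / C on valid voxels."""
    d = np.asarray(delta_r1_sensor, dtype=float)
    c = np.asarray(conc_mM, dtype=float)
    ok = np.asarray(mask, dtype=bool) & np.isfinite(d) & np.isfinite(c) & (c > 0)
    out = np.full(d.shape, np.nan)
    out[ok] = d[ok] / c[ok]
    return out, ok


def ph_map(r1_map, cal: HillCalibration, mask, guard_frac: float = DEFAULT_GUARD_FRAC):
    """Invert the Hill calibration voxelwise; mask out-of-band relaxivities.

    Voxels whose inverted pH falls outside ``cal.valid_ph_range`` are masked
    too — the calibration is not trusted beyond its tested interval.
    """
    ph = ph_from_r1(np.asarray(r1_map, dtype=float), cal, guard_frac=guard_frac)
    lo, hi = cal.valid_ph_range
    ok = np.asarray(mask, dtype=bool) & np.isfinite(ph) & (ph >= lo) & (ph <= hi)
    ph = np.where(ok, ph, np.nan)
    return ph, ok


def run_rph(
    vfa_stack: np.ndarray,
    vfa_params: AcquisitionParams,
    dce: VolumeSeries,
    schedule: InjectionSchedule,
    control_cal: LinearRelaxivity,
    sensor_cal: HillCalibration,
    c_min_mM: float = DEFAULT_C_MIN_MM,
    guard_frac: float = DEFAULT_GUARD_FRAC,
    tumor_roi: np.ndarray | None = None,
    noise_sd: float | None = None,
) -> PhMapResult:
    """Execute the full ratiometric pipeline on one session.

    Requires exactly one control and one sensor injection, control first,
    and geometric alignment of the VFA stack with the dynamic series.
    ``tumor_roi`` (optional) selects the region whose mean curve defines the
    QC time-to-maximal-intensity values; defaults to all T1-valid voxels.
    """
    controls = schedule.by_role("control")
    sensors = schedule.by_role("sensor")
    if len(controls) != 1 or len(sensors) != 1:
        raise ConfigurationError("session must have exactly one control and one sensor injection")
    ctrl, sens = controls[0], sensors[0]
    if ctrl.time_s >= sens.time_s:
        raise ConfigurationError("control injection must precede the sensor injection")
    if vfa_stack.shape[:-1] != dce.shape3d:
        raise ValidationError(
            f"VFA stack geometry {vfa_stack.shape[:-1]} does not match DCE {dce.shape3d}"
        )

    # 1. pre-contrast T10 / S0
    t1_res = fit_vfa(vfa_stack, vfa_params, noise_sd=noise_sd)
    t10 = t1_res.t1_ms

    # 2. M0 from the pre-contrast DCE baseline, then R1(t) for every frame
    t = dce.frame_times_s
    pre_idx = frames_in_window(t, ctrl.time_s - schedule.baseline_window_s, ctrl.time_s)
    pre_idx = pre_idx[t[pre_idx] < ctrl.time_s]
    if pre_idx.size == 0:
        raise ValidationError("no pre-contrast frames before the control injection")
    s0_pre = baseline_signal(dce, pre_idx)
    m0, m0_ok = compute_m0(s0_pre, t10, dce.flip_angle_deg, dce.params.tr_ms, valid=t1_res.valid_mask)
    r1_t, r1_ok, saturated = r1_series(dce, s0_pre, m0, t10)

    def injection_delta(inj):
        base_idx = frames_in_window(t, inj.time_s - schedule.baseline_window_s, inj.time_s)
        base_idx = base_idx[t[base_idx] < inj.time_s]
        if base_idx.size == 0:
            raise ValidationError(f"no baseline frames before injection {inj.label!r}")
        base_r1 = np.nanmean(r1_t[..., base_idx], axis=-1)
        peak_idx = frames_in_window(t, inj.time_s, inj.time_s + schedule.post_window_s)
        peak, peak_time = temporal_peak_r1(r1_t, peak_idx, t)
        return peak - base_r1, peak_time

    with np.errstate(invalid="ignore"):
        d_ctrl, t_peak_ctrl = injection_delta(ctrl)
        d_sens, t_peak_sens = injection_delta(sens)

    # 4-6. concentration -> sensor relaxivity -> pH
    conc, conc_mask = concentration_map(d_ctrl, control_cal, c_min_mM=c_min_mM)
    conc_mask &= m0_ok
    r1_map, r1_mask = sensor_r1_map(d_sens, conc, conc_mask)
    ph, ok = ph_map(r1_map, sensor_cal, r1_mask, guard_frac=guard_frac)

    # QC: pharmacokinetic similarity of the two injections + masking summary
    roi = tumor_roi if tumor_roi is not None else t1_res.valid_mask
    qc: dict = {}
    if roi is not None and np.asarray(roi).any():
        curve = extract_curve(dce, np.asarray(roi, dtype=bool), label="qc")
        qc["tmi_control_min"] = compute_tmi(curve, ctrl.time_s, schedule.post_window_s)
        qc["tmi_sensor_min"] = compute_tmi(curve, sens.time_s, schedule.post_window_s)
    qc["fraction_masked"] = float(1.0 - ok.mean())
    qc["saturation_count"] = int(np.asarray(saturated).any(axis=-1).sum())

    return PhMapResult(
        conc_map=conc, sensor_r1_map=r1_map, ph_map=ph, valid_mask=ok, qc=qc,
        t1_result=t1_res, delta_r1_control=d_ctrl, delta_r1_sensor=d_sens,
        peak_time_control_s=t_peak_ctrl, peak_time_sensor_s=t_peak_sens,
    )
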