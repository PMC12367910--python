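"""Dynamic contrast-enhanced (DCE) series: signal-to-R1 conversion and curves.

The dynamic SPGR signal is converted to the longitudinal relaxation rate
R1(t) by the standard two-step procedure: first the equilibrium magnetization

    M0 = S0 * (1 - cos(theta) * E10) / (sin(theta) * (1 - E10)),
    E10 = exp(-TR / T10)

from the pre-contrast baseline signal S0 (the average of pre-injection
frames) and the pre-contrast T10 map from the variable-flip-angle fit;
then per frame

    A(t) = (S(t) - S0) / (M0 * sin(theta)),
    B    = (1 - E10) / (1 - cos(theta) * E10),
    R1(t) = -(1/TR) * ln( (1 - (A+B)) / (1 - cos(theta) * (A+B)) )

which is the exact algebraic inverse of the SPGR forward model.  TR is
accepted in ms at the interface and converted to seconds internally, so R1
comes out in s^-1.  Voxels whose signal meets or exceeds the model ceiling
M0*sin(theta) (log argument <= 0) are flagged saturated and masked, never
raised — masks are the error channel at map scale.

Time conventions: frame times in seconds from series start, frames 0-based,
time-to-maximal-intensity (TMI) reported in minutes from injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .t1map import AcquisitionParams

__all__ = [
    "VolumeSeries",
    "DCECurve",
    "Injection",
    "InjectionSchedule",
    "frames_in_window",
    "baseline_signal",
    "compute_m0",
    "signal_to_r1",
    "r1_series",
    "extract_curve",
    "compute_tmi",
]


@dataclass
class VolumeSeries:
    """A 4D dynamic acquisition: (x, y, z, frame) + per-frame times."""

    data: np.ndarray
    frame_times_s: np.ndarray
    params: AcquisitionParams
    flip_angle_deg: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError(f"series data must be 4D, got ndim={self.data.ndim}")
        if self.frame_times_s.ndim != 1 or self.frame_times_s.size != self.data.shape[-1]:
            raise ValidationError("frame_times_s length must match the frame axis")
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise ValidationError("frame_times_s must be strictly increasing")
        if np.any(self.data < 0):
            raise ValidationError("magnitude signal data must be non-negative")
        if not (0 < self.flip_angle_deg <= 90):
            raise ValidationError("flip_angle_deg must lie in (0, 90]")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class DCECurve:
    """Mean ROI intensity per frame."""

    times_s: np.ndarray
    intensities: np.ndarray
    roi_label: str = ""

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_s.shape != self.intensities.shape:
            raise ValidationError("times and intensities must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValidationError("curve times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times_s, "intensity": self.intensities})


@dataclass
class Injection:
    label: str
    agent_role: str  # "control" | "sensor"
    time_s: float
    dose_mmol_per_kg: float = 0.0

    def __post_init__(self):
        if self.agent_role not in ("control", "sensor"):
            raise ValidationError(f"agent_role must be 'control' or 'sensor', got {self.agent_role!r}")
        if self.time_s < 0:
            raise ValidationError("injection time must be >= 0")


@dataclass
class InjectionSchedule:
    """Sequential injections plus the analysis windows around each.

    ``baseline_window_s`` is averaged immediately *before* each injection,
    ``post_window_s`` is searched for the peak immediately *after* it.
    Windows of consecutive injections must not overlap.
    """

    injections: list[Injection]
    post_window_s: float
    baseline_window_s: float

    def __post_init__(self):
        if not self.injections:
            raise ValidationError("schedule needs at least one injection")
        if self.post_window_s <= 0 or self.baseline_window_s <= 0:
            raise ValidationError("windows must be positive")
        times = [inj.time_s for inj in self.injections]
        if np.any(np.diff(times) <= 0):
            raise ValidationError("injection times must be strictly increasing")
        for prev, nxt in zip(self.injections, self.injections[1:]):
            if prev.time_s + self.post_window_s > nxt.time_s - self.baseline_window_s:
                raise ValidationError(
                    f"windows of injections {prev.label!r} and {nxt.label!r} overlap"
                )

    def by_role(self, role: str) -> list[Injection]:
        return [i for i in self.injections if i.agent_role == role]


def frames_in_window(frame_times_s, start_s: float, end_s: float) -> np.ndarray:
    """Indices of frames with start <= t <= end (inclusive both ends)."""
    t = np.asarray(frame_times_s, dtype=float)
    idx = np.flatnonzero((t >= start_s) & (t <= end_s))
    return idx


def baseline_signal(series: VolumeSeries, frame_indices) -> np.ndarray:
    """Per-voxel mean over the given (pre-injection) frames."""
    idx = np.asarray(frame_indices, dtype=int)
    if idx.size == 0:
        raise ValidationError("baseline window contains no frames")
    return series.data[..., idx].mean(axis=-1)


def compute_m0(s0_map, t10_ms_map, theta_deg: float, tr_ms: float, valid=None):
    """Equilibrium magnetization map from baseline signal and T10.

    Returns ``(m0, valid)``; invalid wherever T10 is masked/non-finite.
    """
    if theta_deg <= 0 or theta_deg > 90:
        raise ValidationError("theta_deg must lie in (0, 90]")
    if tr_ms <= 0:
        raise ValidationError("tr_ms must be > 0")
    s0 = np.asarray(s0_map, dtype=float)
    t10 = np.asarray(t10_ms_map, dtype=float)
    ok = np.isfinite(t10) & (t10 > 0) & np.isfinite(s0)
    if valid is not None:
        ok = ok & valid
    th = np.deg2rad(theta_deg)
    m0 = np.full(s0.shape, np.nan)
    with np.errstate(all="ignore"):
        e10 = np.exp(-tr_ms / t10[ok])
        m0[ok] = s0[ok] * (1.0 - np.cos(th) * e10) / (np.sin(th) * (1.0 - e10))
    return m0, ok


def signal_to_r1(s_t, s0_map, m0_map, t10_ms_map, theta_deg: float, tr_ms: float):
    """Convert SPGR signal to R1 in s^-1 (exact inverse of the forward model).

    ``s_t`` may be a single 3D frame or a full 4D series (frame axis last);
    the baseline/M0/T10 maps broadcast across frames.  Returns
    ``(r1, valid, saturated)``: ``saturated`` marks voxels at/above the SPGR
    signal ceiling where the inversion has no solution.
    """
    if theta_deg <= 0 or theta_deg > 90:
        raise ValidationError("theta_deg must lie in (0, 90]")
    if tr_ms <= 0:
        raise ValidationError("tr_ms must be > 0")
    s_t = np.asarray(s_t, dtype=float)
    s0 = np.asarray(s0_map, dtype=float)
    m0 = np.asarray(m0_map, dtype=float)
    t10 = np.asarray(t10_ms_map, dtype=float)
    is_series = s_t.ndim == s0.ndim + 1
    if is_series:
        s0, m0, t10 = s0[..., None], m0[..., None], t10[..., None]
    th = np.deg2rad(theta_deg)
    tr_s = tr_ms / 1000.0
    with np.errstate(all="ignore"):
        e10 = np.exp(-tr_ms / t10)
        A = (s_t - s0) / (m0 * np.sin(th))
        B = (1.0 - e10) / (1.0 - np.cos(th) * e10)
        u = A + B
        arg = (1.0 - u) / (1.0 - np.cos(th) * u)
        finite = np.isfinite(u)
        saturated = finite & (u >= 1.0)
        ok = finite & (arg > 0)
        r1 = np.full(np.broadcast_shapes(s_t.shape, arg.shape), np.nan)
        r1[ok] = -np.log(arg[ok]) / tr_s
    return r1, ok, saturated


def r1_series(series: VolumeSeries, s0_map, m0_map, t10_ms_map):
    """R1(t) for every frame of a series: 4D array + per-frame masks."""
    return signal_to_r1(
        series.data, s0_map, m0_map, t10_ms_map,
        theta_deg=series.flip_angle_deg, tr_ms=series.params.tr_ms,
    )


def extract_curve(series: VolumeSeries, roi: np.ndarray, label: str = "") -> DCECurve:
    """Per-frame mean over an ROI mask."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != series.shape3d:
        raise ValidationError(f"roi shape {roi.shape} does not match series {series.shape3d}")
    if not roi.any():
        raise ValidationError("roi is empty")
    vals = series.data[roi, :].mean(axis=0)
    return DCECurve(times_s=series.frame_times_s, intensities=vals, roi_label=label)


def compute_tmi(curve: DCECurve, injection_time_s: float, search_window_s: float) -> float:
    """Time to maximal intensity, in minutes from injection.

    Searches frames with t in [injection, injection + window]; ties go to the
    earliest frame.  Invariant under any strictly increasing transform of the
    intensities (argmax is rank-based).
    """
    idx = frames_in_window(curve.times_s, injection_time_s, injection_time_s + search_window_s)
    if idx.size == 0:
        raise ValidationError("TMI search window contains no frames")
    sub = curve.intensities[idx]
    t_peak = curve.times_s[idx[int(np.argmax(sub))]]
    return float((t_peak - injection_time_s) / 60.0)
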