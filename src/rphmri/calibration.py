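"""In-vitro calibration of contrast agents.

Two calibrations feed the pH pipeline:

* a **linear relaxivity** for the pH-insensitive control chelate — the slope of
  the longitudinal relaxation rate ``R1 = 1/T1`` versus agent concentration,
  in mM^-1 s^-1 — which turns a Delta-R1 map into a concentration map;
* a **Hill (four-parameter logistic) curve** ``r1(pH)`` for the pH sensor,
  whose closed-form inverse is the per-voxel pH equation.

The forward Hill model is

    r1(pH) = bottom + (top - bottom) / (1 + 10**((pH - log_ic50) * hill_slope))

with ``hill_slope > 0`` so that relaxivity *decreases* with pH (the sensor is
brighter in acidic tissue).  Its exact algebraic inverse is

    pH = log_ic50 + log10((top - r1) / (r1 - bottom)) / hill_slope.

All logs are base 10, matching the IC50/HillSlope parameterization of common
curve-fitting software; ``log_ic50`` is read directly as the midpoint pH
because the abscissa of the calibration is pH itself, not a log concentration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateDataError, FitError, ValidationError

__all__ = [
    "LinearRelaxivity",
    "HillCalibration",
    "HillFitResult",
    "fit_relaxivity",
    "hill_forward",
    "ph_from_r1",
    "fit_hill",
    "reconstructed_sensor_calibration",
    "read_relaxivity_table",
    "read_hill_table",
]

#: fraction of (top - bottom) excluded at both asymptotes before inversion;
#: keeps the log argument finite under noise
DEFAULT_GUARD_FRAC = 0.01


@dataclass
class LinearRelaxivity:
    """Linear R1-vs-concentration calibration of a contrast agent.

    ``r1_slope`` is the relaxivity in mM^-1 s^-1; ``r1_intercept`` the solvent
    relaxation rate in s^-1.  A paramagnetic agent has a positive slope, but
    the constructor stays permissive (a flat fit legitimately returns slope 0);
    consumers that *require* a positive slope (concentration mapping) validate
    at the point of use.
    """

    r1_slope: float
    r1_intercept: float
    field_strength_T: float | None = None
    medium: str | None = None
    # fit diagnostics (populated by fit_relaxivity)
    residuals: np.ndarray | None = field(default=None, repr=False)
    r_squared: float | None = field(default=None, repr=False)
    stderr: float | None = field(default=None, repr=False)

    def r1_at(self, concentration_mM):
        return self.r1_intercept + self.r1_slope * np.asarray(concentration_mM, float)


@dataclass
class HillCalibration:
    """Four-parameter logistic r1(pH) curve of the pH sensor.

    ``top``/``bottom`` are the relaxivity plateaus (mM^-1 s^-1) at low/high pH,
    ``log_ic50`` the midpoint pH and ``hill_slope`` the (positive) steepness.
    ``valid_ph_range`` bounds the pH interval over which the inversion is
    trusted (default: the in-vitro tested range 5.5-7.4).
    """

    top: float
    bottom: float
    log_ic50: float
    hill_slope: float
    valid_ph_range: tuple[float, float] = (5.5, 7.4)
    units: str = "mM^-1 s^-1"
    medium: str | None = None
    field_strength_T: float | None = None

    def __post_init__(self):
        if not (self.top > self.bottom > 0):
            raise ValidationError(
                f"require top > bottom > 0, got top={self.top}, bottom={self.bottom}"
            )
        if not self.hill_slope > 0:
            raise ValidationError(f"hill_slope must be > 0, got {self.hill_slope}")
        lo, hi = self.valid_ph_range
        if not (0 < lo < hi < 14):
            raise ValidationError(f"valid_ph_range must be ordered within (0, 14), got {self.valid_ph_range}")
        self.valid_ph_range = (float(lo), float(hi))

    # ---- JSON persistence -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "top": self.top,
            "bottom": self.bottom,
            "log_ic50": self.log_ic50,
            "hill_slope": self.hill_slope,
            "valid_ph_range": list(self.valid_ph_range),
            "units": self.units,
            "medium": self.medium,
            "field_strength_T": self.field_strength_T,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "HillCalibration":
        try:
            return cls(
                top=float(d["top"]),
                bottom=float(d["bottom"]),
                log_ic50=float(d["log_ic50"]),
                hill_slope=float(d["hill_slope"]),
                valid_ph_range=tuple(d.get("valid_ph_range", (5.5, 7.4))),
                units=d.get("units", "mM^-1 s^-1"),
                medium=d.get("medium"),
                field_strength_T=d.get("field_strength_T"),
            )
        except KeyError as e:  # pragma: no cover - message path
            raise ValidationError(f"calibration JSON missing key {e}") from e

    @classmethod
    def load(cls, path) -> "HillCalibration":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class HillFitResult:
    calibration: HillCalibration
    covariance: np.ndarray
    residuals: np.ndarray
    rmse: float


# ---------------------------------------------------------------------------


def fit_relaxivity(
    concentrations: Sequence[float],
    relaxation_rates: Sequence[float],
    field_strength_T: float | None = None,
    medium: str | None = None,
) -> LinearRelaxivity:
    """Least-squares line through (concentration, R1); the slope is r1.

    Raises :class:`DegenerateDataError` for fewer than 2 distinct
    concentrations and :class:`ValidationError` for negative inputs.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(relaxation_rates, dtype=float)
    if c.shape != r.shape or c.ndim != 1:
        raise ValidationError("concentrations and rates must be equal-length 1-D sequences")
    if np.any(c < 0):
        raise ValidationError("concentrations must be >= 0")
    if np.any(r < 0):
        raise ValidationError("relaxation rates must be >= 0")
    if np.unique(c).size < 2:
        raise DegenerateDataError("need at least 2 distinct concentrations")
    res = stats.linregress(c, r)
    fitted = res.intercept + res.slope * c
    out = LinearRelaxivity(
        r1_slope=float(res.slope),
        r1_intercept=float(res.intercept),
        field_strength_T=field_strength_T,
        medium=medium,
    )
    out.residuals = r - fitted
    out.r_squared = float(res.rvalue**2)
    out.stderr = float(res.stderr)
    return out


def hill_forward(ph, cal: HillCalibration):
    """Sensor relaxivity at a given pH (mM^-1 s^-1); strictly decreasing."""
    ph = np.asarray(ph, dtype=float)
    out = cal.bottom + (cal.top - cal.bottom) / (
        1.0 + 10.0 ** ((ph - cal.log_ic50) * cal.hill_slope)
    )
    return out if out.ndim else float(out)


def ph_from_r1(r1, cal: HillCalibration, guard_frac: float = DEFAULT_GUARD_FRAC):
    """Invert the Hill curve; NaN marks values outside the invertible band.

    Relaxivities within ``guard_frac * (top - bottom)`` of either plateau are
    treated as uninformative (the log blows up) and returned as NaN rather
    than raising — map-scale callers deal in masks, not exceptions.
    """
    r1 = np.asarray(r1, dtype=float)
    eps = guard_frac * (cal.top - cal.bottom)
    valid = np.isfinite(r1) & (r1 > cal.bottom + eps) & (r1 < cal.top - eps)
    out = np.full(r1.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        rv = r1[valid]
        out[valid] = cal.log_ic50 + np.log10((cal.top - rv) / (rv - cal.bottom)) / cal.hill_slope
    return out if out.ndim else float(out)


def _hill_model(ph, top, bottom, log_ic50, hill_slope):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((ph - log_ic50) * hill_slope))


def fit_hill(
    ph_values: Sequence[float],
    r1_values: Sequence[float],
    init: HillCalibration | None = None,
) -> HillFitResult:
    """Nonlinear least-squares fit of the four-parameter logistic.

    Needs >= 4 points spanning both sides of the transition.  Flat data raise
    :class:`DegenerateDataError`; non-convergence raises :class:`FitError`.
    """
    ph = np.asarray(ph_values, dtype=float)
    r1 = np.asarray(r1_values, dtype=float)
    if ph.shape != r1.shape or ph.ndim != 1:
        raise ValidationError("ph_values and r1_values must be equal-length 1-D sequences")
    if np.unique(ph).size < 4:
        raise ValidationError("need at least 4 distinct pH points")
    if np.ptp(r1) <= 1e-8 + 1e-6 * max(1.0, float(np.abs(r1).max())):
        raise DegenerateDataError("r1 values are flat; Hill parameters unidentifiable")

    if init is not None:
        p0 = [init.top, init.bottom, init.log_ic50, init.hill_slope]
    else:
        lo, hi = float(r1.min()), float(r1.max())
        span = hi - lo
        mid = 0.5 * (lo + hi)
        # midpoint pH guess: pH of the sample closest to the half-response
        p0 = [hi + 0.02 * span, max(lo - 0.02 * span, 1e-6),
              float(ph[np.argmin(np.abs(r1 - mid))]), 1.0]
    bounds = ([1e-9, 1e-9, 0.0, 1e-3], [np.inf, np.inf, 14.0, 100.0])
    try:
        popt, pcov = optimize.curve_fit(
            _hill_model, ph, r1, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as e:
        raise FitError(f"Hill fit did not converge: {e}") from e
    top, bottom, log_ic50, hill_slope = (float(v) for v in popt)
    if not top > bottom:
        raise FitError("Hill fit returned top <= bottom (non-monotone solution)")
    cal = HillCalibration(
        top=top,
        bottom=bottom,
        log_ic50=log_ic50,
        hill_slope=hill_slope,
        valid_ph_range=(max(ph.min(), 0.01), min(ph.max(), 13.99)),
    )
    resid = r1 - _hill_model(ph, *popt)
    return HillFitResult(
        calibration=cal,
        covariance=pcov,
        residuals=resid,
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


def reconstructed_sensor_calibration(
    top: float = 2.5,
    bottom: float = 0.75,
    r1_neutral: float = 0.86,
    acid_ratio: float = 2.7,
    ph_neutral: float = 7.4,
    ph_acid: float = 5.5,
) -> HillCalibration:
    """Default sensor calibration — **reconstructed, not a measured fit**.

    Built from two anchor relaxivities of the pH sensor in serum at 7 T:
    r1 = 0.86 mM^-1 s^-1 at pH 7.4 and ``acid_ratio`` (2.7) times that at
    pH 5.5.  The plateau values ``top``/``bottom`` are *assumed* (they must
    bracket the anchors); midpoint and slope are then solved in closed form
    so the curve passes through both anchors exactly.
    """
    r1_acid = acid_ratio * r1_neutral
    if not (top > r1_acid and bottom < r1_neutral):
        raise ValidationError("assumed plateaus must bracket the anchor relaxivities")
    x_acid = np.log10((top - r1_acid) / (r1_acid - bottom))
    x_neutral = np.log10((top - r1_neutral) / (r1_neutral - bottom))
    hill_slope = (x_neutral - x_acid) / (ph_neutral - ph_acid)
    log_ic50 = ph_acid - x_acid / hill_slope
    return HillCalibration(
        top=top,
        bottom=bottom,
        log_ic50=float(log_ic50),
        hill_slope=float(hill_slope),
        valid_ph_range=(ph_acid, ph_neutral),
        medium="serum (reconstructed)",
        field_strength_T=7.0,
    )


# ---- tabular I/O ----------------------------------------------------------


def read_relaxivity_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (concentration_mM, R1_per_s) CSV with a one-line header."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (concentration, R1)")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def read_hill_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (pH, r1_mM_s) CSV with a one-line header."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (pH, r1)")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
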