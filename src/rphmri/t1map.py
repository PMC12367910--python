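"""Voxelwise pre-contrast T1 / S0 mapping.

Two estimators are provided:

* :func:`fit_vfa` — variable flip angle (VFA) mapping from spoiled gradient
  echo (SPGR/FLASH) stacks.  The steady-state SPGR signal is

      S(alpha) = S0 * (1 - E1) * sin(alpha) / (1 - cos(alpha) * E1),
      E1 = exp(-TR / T1)

  Initialization is the DESPOT1 linearization (regress S/sin(alpha) on
  S/tan(alpha): the slope is E1), followed by a damped Gauss-Newton
  refinement of (T1, S0) with T1 bounded to [1, 10000] ms.  On noiseless
  data the linearization is already exact.

* :func:`fit_vtr` — variable repetition time saturation-recovery mapping,
  S(TR) = S0 * (1 - exp(-TR/T1)), used for spin-echo phantom series.
  Initialized by a coarse log-grid search over T1 (S0 is linear given T1),
  then the same Gauss-Newton refinement.

Flip angles are taken as nominal; no B1+ correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["AcquisitionParams", "T1MapResult", "spgr_signal", "fit_vfa", "fit_vtr"]

T1_BOUNDS_MS = (1.0, 10000.0)


@dataclass
class AcquisitionParams:
    """SPGR acquisition metadata. TR/TE in ms, angles in degrees."""

    tr_ms: float
    flip_angles_deg: tuple[float, ...] = ()
    te_ms: float | None = None
    frame_interval_s: float | None = None
    voxel_size_mm: tuple[float, float, float] | None = None
    matrix: tuple[int, int, int] | None = None

    def __post_init__(self):
        if self.tr_ms <= 0:
            raise ValidationError(f"tr_ms must be > 0, got {self.tr_ms}")
        self.flip_angles_deg = tuple(float(a) for a in self.flip_angles_deg)
        for a in self.flip_angles_deg:
            if not (0 < a <= 90):
                raise ValidationError(f"flip angles must lie in (0, 90] degrees, got {a}")
        if self.frame_interval_s is not None and self.frame_interval_s <= 0:
            raise ValidationError("frame_interval_s must be > 0")


@dataclass
class T1MapResult:
    """Voxelwise T1 (ms), S0, RMS fit residual and validity mask."""

    t1_ms: np.ndarray
    s0: np.ndarray
    fit_error: np.ndarray
    valid_mask: np.ndarray

    @property
    def r1_per_s(self) -> np.ndarray:
        """Relaxation rate 1/T1 in s^-1 (NaN where invalid)."""
        out = np.full(self.t1_ms.shape, np.nan)
        out[self.valid_mask] = 1000.0 / self.t1_ms[self.valid_mask]
        return out


def spgr_signal(s0, t1_ms, tr_ms, alpha_deg):
    """Steady-state spoiled gradient-echo signal (broadcasts over arrays)."""
    s0 = np.asarray(s0, dtype=float)
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValidationError("t1_ms must be > 0")
    if np.any(np.asarray(tr_ms, dtype=float) <= 0):
        raise ValidationError("tr_ms must be > 0")
    a = np.deg2rad(alpha_deg)
    e1 = np.exp(-np.asarray(tr_ms, dtype=float) / t1)
    out = s0 * (1.0 - e1) * np.sin(a) / (1.0 - np.cos(a) * e1)
    return out if np.ndim(out) else float(out)


def _gauss_newton_refine(S, model_fn, jac_fn, t1, s0, n_iter=30, damping=1e-3):
    """Damped Gauss-Newton on per-voxel (t1, s0); all arrays (N,) / (N, n)."""
    lo, hi = T1_BOUNDS_MS
    for _ in range(n_iter):
        m = model_fn(t1, s0)
        r = S - m
        j_t1, j_s0 = jac_fn(t1, s0)
        a = np.sum(j_t1 * j_t1, axis=1)
        b = np.sum(j_t1 * j_s0, axis=1)
        c = np.sum(j_s0 * j_s0, axis=1)
        g1 = np.sum(j_t1 * r, axis=1)
        g2 = np.sum(j_s0 * r, axis=1)
        a = a * (1.0 + damping) + 1e-300
        c = c * (1.0 + damping) + 1e-300
        det = a * c - b * b
        ok = det > 0
        dt1 = np.where(ok, (c * g1 - b * g2) / np.where(ok, det, 1.0), 0.0)
        ds0 = np.where(ok, (a * g2 - b * g1) / np.where(ok, det, 1.0), 0.0)
        # trust-region style cap keeps early steps from overshooting
        dt1 = np.clip(dt1, -0.5 * t1, 0.5 * t1)
        t1 = np.clip(t1 + dt1, lo, hi)
        s0 = np.maximum(s0 + ds0, 0.0)
    return t1, s0


def _finalize(shape, n, t1, s0, resid_rms, valid):
    res = T1MapResult(
        t1_ms=t1.reshape(shape),
        s0=s0.reshape(shape),
        fit_error=resid_rms.reshape(shape),
        valid_mask=valid.reshape(shape),
    )
    res.t1_ms[~res.valid_mask] = np.nan
    res.s0[~res.valid_mask] = np.nan
    return res


def fit_vfa(
    stack: np.ndarray,
    params: AcquisitionParams,
    noise_sd: float | None = None,
    signal_floor_factor: float = 5.0,
    n_iter: int = 30,
) -> T1MapResult:
    """Fit (T1, S0) per voxel from a variable-flip-angle SPGR stack.

    ``stack`` has the flip-angle dimension last: shape ``(..., n_angles)``,
    ordered as ``params.flip_angles_deg``.  If ``noise_sd`` is given, voxels
    whose maximum signal is below ``signal_floor_factor * noise_sd`` are
    masked invalid (air/background); degenerate voxels (flat across angles,
    e.g. all-zero) are always masked, never raised.
    """
    angles = np.asarray(params.flip_angles_deg, dtype=float)
    if angles.size < 3:
        raise ValidationError("fit_vfa needs at least 3 flip angles")
    stack = np.asarray(stack, dtype=float)
    if stack.shape[-1] != angles.size:
        raise ValidationError(
            f"stack last axis ({stack.shape[-1]}) must match number of flip angles ({angles.size})"
        )
    tr = float(params.tr_ms)
    shape = stack.shape[:-1]
    S = stack.reshape(-1, angles.size)
    a = np.deg2rad(angles)
    sa, ca = np.sin(a), np.cos(a)

    valid = np.isfinite(S).all(axis=1)
    if noise_sd is not None:
        valid &= S.max(axis=1) >= signal_floor_factor * noise_sd
    # flat across angles carries no T1 information
    valid &= np.ptp(S, axis=1) > 1e-12 + 1e-9 * np.abs(S).max(axis=1)

    # DESPOT1 linearization: y = E1 * x + S0 (1 - E1)
    with np.errstate(all="ignore"):
        x = S * ca / sa
        y = S / sa
        xm = x.mean(axis=1, keepdims=True)
        ym = y.mean(axis=1, keepdims=True)
        varx = np.sum((x - xm) ** 2, axis=1)
        cov = np.sum((x - xm) * (y - ym), axis=1)
        e1 = np.where(varx > 0, cov / np.where(varx > 0, varx, 1.0), np.nan)
    valid &= np.isfinite(e1)
    e1 = np.clip(np.nan_to_num(e1, nan=0.5), 1e-8, 1.0 - 1e-8)
    t1 = np.clip(-tr / np.log(e1), *T1_BOUNDS_MS)
    s0 = np.maximum((y - e1[:, None] * x).mean(axis=1) / (1.0 - e1), 0.0)

    def model(t1_, s0_):
        e = np.exp(-tr / t1_)[:, None]
        return s0_[:, None] * (1.0 - e) * sa / (1.0 - ca * e)

    def jac(t1_, s0_):
        e = np.exp(-tr / t1_)[:, None]
        denom = 1.0 - ca * e
        dm_ds0 = (1.0 - e) * sa / denom
        dm_de = s0_[:, None] * sa * (ca - 1.0) / denom**2
        de_dt1 = e * (tr / t1_**2)[:, None]
        return dm_de * de_dt1, dm_ds0

    t1, s0 = _gauss_newton_refine(S, model, jac, t1, s0, n_iter=n_iter)
    resid = S - model(t1, s0)
    rms = np.sqrt(np.mean(resid**2, axis=1))
    valid &= (t1 > T1_BOUNDS_MS[0]) & (t1 < T1_BOUNDS_MS[1]) & (s0 > 0)
    return _finalize(shape, angles.size, t1, s0, rms, valid)


def fit_vtr(
    signals: np.ndarray,
    tr_list_ms,
    noise_sd: float | None = None,
    signal_floor_factor: float = 5.0,
    n_iter: int = 50,
) -> T1MapResult:
    """Fit (T1, S0) per voxel from a variable-TR saturation-recovery series.

    ``signals`` has the TR dimension last, ordered as ``tr_list_ms``.
    Voxels flat across TRs (all TR >> T1 — signal fully recovered) are
    masked invalid: the model degenerates to S = S0 there.
    """
    trs = np.asarray(tr_list_ms, dtype=float)
    if trs.size < 3:
        raise ValidationError("fit_vtr needs at least 3 repetition times")
    if np.any(trs <= 0):
        raise ValidationError("repetition times must be > 0")
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != trs.size:
        raise ValidationError("signals last axis must match number of TRs")
    shape = signals.shape[:-1]
    S = signals.reshape(-1, trs.size)

    valid = np.isfinite(S).all(axis=1)
    if noise_sd is not None:
        valid &= S.max(axis=1) >= signal_floor_factor * noise_sd
    valid &= np.ptp(S, axis=1) > 1e-12 + 1e-6 * np.abs(S).max(axis=1)

    # coarse grid over T1; S0 is linear given T1
    grid = np.logspace(0.5, 4.0, 80)  # ms
    f = 1.0 - np.exp(-trs[None, :] / grid[:, None])  # (G, n)
    ff = np.sum(f * f, axis=1)  # (G,)
    Sf = S @ f.T  # (N, G)
    s0_grid = Sf / ff[None, :]
    sse = np.sum(S**2, axis=1)[:, None] - s0_grid**2 * ff[None, :]
    best = np.argmin(sse, axis=1)
    t1 = grid[best]
    s0 = np.maximum(s0_grid[np.arange(S.shape[0]), best], 0.0)

    def model(t1_, s0_):
        return s0_[:, None] * (1.0 - np.exp(-trs / t1_[:, None]))

    def jac(t1_, s0_):
        e = np.exp(-trs / t1_[:, None])
        dm_ds0 = 1.0 - e
        dm_dt1 = -s0_[:, None] * e * trs / (t1_**2)[:, None]
        return dm_dt1, dm_ds0

    t1, s0 = _gauss_newton_refine(S, model, jac, t1, s0, n_iter=n_iter)
    resid = S - model(t1, s0)
    rms = np.sqrt(np.mean(resid**2, axis=1))
    valid &= (t1 > T1_BOUNDS_MS[0]) & (t1 < T1_BOUNDS_MS[1]) & (s0 > 0)
    return _finalize(shape, trs.size, t1, s0, rms, valid)
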