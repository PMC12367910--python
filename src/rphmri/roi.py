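"""Whole/core/rim ROI construction and summary statistics on pH maps.

The tumor interior ("core") is obtained by shrinking the whole-tumor ROI by a
linear factor (0.7 by default in the pipeline) about its centroid; the rim is
the set difference (equivalently XOR, since the core is a subset).  Scaling
is a centroid-anchored affine with nearest-neighbour rasterization: an output
pixel belongs to the core iff its centre, mapped back through the inverse
scaling, lands inside the whole mask.  Rounding is half-up (floor(q + 0.5)),
giving half-open-interval semantics so that e.g. a 10-px square at factor 0.7
rasterizes to exactly 7 px a side.  The scaled mask is intersected with its
parent, so core <= whole holds for non-convex masks as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "RoiMask",
    "scale_roi",
    "rim_roi",
    "largest_area_slice",
    "summarize_ph",
    "compare_regions",
    "RegionComparison",
]


@dataclass
class RoiMask:
    """A labelled boolean region (2D slice or 3D volume)."""

    mask: np.ndarray
    label: str = ""
    slice_index: int | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim not in (2, 3):
            raise ValidationError("RoiMask must be 2D or 3D")
        if not self.mask.any():
            raise ValidationError(f"ROI {self.label!r} is empty")

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def centroid(self) -> np.ndarray:
        return np.argwhere(self.mask).mean(axis=0)


def scale_roi(whole: RoiMask, factor: float, label: str = "core") -> RoiMask:
    """Shrink/keep a mask by ``factor`` about its centroid (0 < factor <= 1)."""
    if not (0 < factor <= 1):
        raise ValidationError(f"scale factor must lie in (0, 1], got {factor}")
    mask = whole.mask
    c = whole.centroid()
    coords = np.indices(mask.shape, dtype=float)
    c_bc = c.reshape((-1,) + (1,) * mask.ndim)
    src = (coords - c_bc) / factor + c_bc
    idx = np.floor(src + 0.5).astype(int)
    inside = np.ones(mask.shape, dtype=bool)
    for k, n in enumerate(mask.shape):
        inside &= (idx[k] >= 0) & (idx[k] < n)
    out = np.zeros(mask.shape, dtype=bool)
    out[inside] = mask[tuple(idx[:, inside])]
    out &= mask  # core is by definition part of the tumor
    return RoiMask(mask=out, label=label, slice_index=whole.slice_index)


def rim_roi(whole: RoiMask, core: RoiMask, label: str = "rim") -> RoiMask:
    """Rim = whole XOR core (set difference, since core must be a subset)."""
    if whole.mask.shape != core.mask.shape:
        raise ValidationError("whole and core masks must share a shape")
    if np.any(core.mask & ~whole.mask):
        raise ValidationError("core ROI is not a subset of the whole ROI")
    rim = whole.mask ^ core.mask
    if not rim.any():
        raise ValidationError("rim ROI is empty (core equals whole)")
    return RoiMask(mask=rim, label=label, slice_index=whole.slice_index)


def largest_area_slice(mask3d: np.ndarray, axis: int = 2) -> int:
    """Index of the slice with the largest in-plane area (tumor 'size' slice)."""
    mask3d = np.asarray(mask3d, dtype=bool)
    areas = mask3d.sum(axis=tuple(i for i in range(3) if i != axis))
    return int(np.argmax(areas))


def summarize_ph(ph_map: np.ndarray, rois: list[RoiMask]) -> pd.DataFrame:
    """Per-ROI statistics over *valid* (finite) pH voxels.

    An ROI with zero valid voxels yields a flagged row rather than an error.
    """
    ph_map = np.asarray(ph_map, dtype=float)
    rows = []
    for roi in rois:
        if roi.mask.shape != ph_map.shape:
            raise ValidationError(f"ROI {roi.label!r} shape does not match the pH map")
        vals = ph_map[roi.mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            rows.append(
                {"label": roi.label, "n_valid": 0, "mean": np.nan, "sd": np.nan,
                 "min": np.nan, "max": np.nan, "flagged": True}
            )
        else:
            rows.append(
                {"label": roi.label, "n_valid": int(vals.size),
                 "mean": float(vals.mean()),
                 "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                 "min": float(vals.min()), "max": float(vals.max()),
                 "flagged": False}
            )
    return pd.DataFrame(rows)


@dataclass
class RegionComparison:
    paired_t: float
    p_paired: float
    pearson_r: float | None
    p_pearson: float | None
    mean_difference: float
    degenerate: bool  # zero variance of paired differences (exact tie)


def compare_regions(
    core_means,
    rim_means,
    sizes=None,
    whole_means=None,
) -> RegionComparison:
    """Paired t-test core vs rim, plus Pearson correlation of size vs pH.

    The paired statistic is t = mean(d) / (sd(d)/sqrt(n)) on n-1 degrees of
    freedom, two-tailed.  Zero variance of the differences is reported via
    ``degenerate=True`` (p is undefined for an exact tie), not an exception.
    When ``sizes`` is given, Pearson r is computed against ``whole_means``
    (falling back to the core/rim average if whole-tumor means are absent).
    """
    core = np.asarray(core_means, dtype=float)
    rim = np.asarray(rim_means, dtype=float)
    if core.shape != rim.shape or core.ndim != 1:
        raise ValidationError("core and rim means must be equal-length 1-D sequences")
    if core.size < 3:
        raise ValidationError("need at least 3 paired tumors")
    d = core - rim
    if np.ptp(d) == 0:
        return RegionComparison(
            paired_t=0.0 if d[0] == 0 else np.nan,
            p_paired=np.nan,
            pearson_r=None, p_pearson=None,
            mean_difference=float(d.mean()), degenerate=True,
        )
    t, p = stats.ttest_rel(core, rim)
    r = pr = None
    if sizes is not None:
        sizes = np.asarray(sizes, dtype=float)
        if sizes.shape != core.shape:
            raise ValidationError("sizes must pair with the tumor lists")
        whole = np.asarray(whole_means, dtype=float) if whole_means is not None else 0.5 * (core + rim)
        res = stats.pearsonr(sizes, whole)
        r, pr = float(res.statistic), float(res.pvalue)
    return RegionComparison(
        paired_t=float(t), p_paired=float(p),
        pearson_r=r, p_pearson=pr,
        mean_difference=float(d.mean()), degenerate=False,
    )
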