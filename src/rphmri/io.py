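"""NIfTI-1 volume I/O, session configuration and provenance records.

NIfTI-1 is the interchange format; vendor raw formats are converted upstream.
Dynamic frame timing travels in a JSON sidecar (``<volume>.json`` with key
``frame_times_s``) because the NIfTI time-axis metadata is unreliable across
tools.  Voxel indices are 0-based everywhere; world coordinates exist only
through the stored affine, which is carried unchanged onto every output map.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import nibabel as nib
import numpy as np
from pydantic import BaseModel, Field, ValidationError as PydanticValidationError

from . import __version__
from .calibration import HillCalibration, LinearRelaxivity
from .dce import Injection, InjectionSchedule
from .errors import ConfigurationError, ValidationError
from .t1map import AcquisitionParams

log = logging.getLogger("rphmri")

__all__ = [
    "read_volume",
    "write_volume",
    "SessionConfig",
    "load_session",
    "write_provenance",
]


# ---------------------------------------------------------------------------
# volumes


def write_volume(path, data: np.ndarray, affine: np.ndarray | None = None, frame_times_s=None) -> Path:
    """Write a 3D/4D volume; 4D volumes get a frame-time sidecar JSON."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim not in (3, 4):
        raise ValidationError(f"volumes must be 3D or 4D, got ndim={data.ndim}")
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    nib.save(img, str(path))
    if frame_times_s is not None:
        ft = np.asarray(frame_times_s, dtype=float)
        if data.ndim != 4 or ft.size != data.shape[-1]:
            raise ValidationError("frame_times_s must match the 4D frame axis")
        _sidecar_path(path).write_text(json.dumps({"frame_times_s": ft.tolist()}))
    return path


def read_volume(path, expect: Literal["3d", "4d", None] = None):
    """Read a NIfTI volume -> (data, affine, frame_times_s or None).

    ``expect`` enforces dimensionality; a 4D file's frame count is checked
    against its sidecar when one exists.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if expect == "3d" and data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    if expect == "4d" and data.ndim != 4:
        raise ValidationError(f"{path}: expected a 4D series, got ndim={data.ndim}")
    frame_times = None
    sc = _sidecar_path(path)
    if sc.exists():
        frame_times = np.asarray(json.loads(sc.read_text())["frame_times_s"], dtype=float)
        if data.ndim == 4 and frame_times.size != data.shape[-1]:
            raise ValidationError(
                f"{path}: sidecar lists {frame_times.size} frame times but the series has "
                f"{data.shape[-1]} frames"
            )
    return data, np.asarray(img.affine), frame_times


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


# ---------------------------------------------------------------------------
# session configuration (schema-validated, units explicit)


class AcquisitionSection(BaseModel):
    tr_ms: float = Field(gt=0)
    flip_angles_deg: list[float]
    dce_flip_angle_deg: float = Field(default=15.0, gt=0, le=90)
    te_ms: Optional[float] = None
    frame_interval_s: Optional[float] = Field(default=None, gt=0)

    def to_params(self) -> AcquisitionParams:
        return AcquisitionParams(
            tr_ms=self.tr_ms,
            flip_angles_deg=tuple(self.flip_angles_deg),
            te_ms=self.te_ms,
            frame_interval_s=self.frame_interval_s,
        )


class InjectionSection(BaseModel):
    label: str
    agent_role: Literal["control", "sensor"]
    time_s: float = Field(ge=0)
    dose_mmol_per_kg: float = Field(default=0.0, ge=0)


class ScheduleSection(BaseModel):
    injections: list[InjectionSection]
    post_window_s: float = Field(gt=0)
    baseline_window_s: float = Field(gt=0)

    def to_schedule(self) -> InjectionSchedule:
        return InjectionSchedule(
            injections=[Injection(i.label, i.agent_role, i.time_s, i.dose_mmol_per_kg)
                        for i in self.injections],
            post_window_s=self.post_window_s,
            baseline_window_s=self.baseline_window_s,
        )


class OptionsSection(BaseModel):
    c_min_mM: float = 0.05
    guard_frac: float = 0.01


class ControlCalSection(BaseModel):
    r1_slope: float
    r1_intercept: float = 0.0
    field_strength_T: Optional[float] = None
    medium: Optional[str] = None

    def to_calibration(self) -> LinearRelaxivity:
        return LinearRelaxivity(self.r1_slope, self.r1_intercept,
                                self.field_strength_T, self.medium)


class SessionConfig(BaseModel):
    """A full pH-mapping session: paths, acquisition, schedule, options."""

    vfa_path: str
    dce_path: str
    acquisition: AcquisitionSection
    schedule: ScheduleSection
    control_calibration: ControlCalSection
    sensor_calibration_path: str
    tumor_roi_path: Optional[str] = None
    options: OptionsSection = OptionsSection()
    seed: int = 0

    def sensor_calibration(self) -> HillCalibration:
        return HillCalibration.load(self.sensor_calibration_path)


def load_session(config_path) -> SessionConfig:
    """Load + validate a session config; defaults are filled and logged.

    Referenced paths must exist at load time.  Schema violations raise
    :class:`ConfigurationError` naming the offending key.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise ConfigurationError(f"config file not found: {config_path}")
    try:
        raw = json.loads(config_path.read_text())
    except json.JSONDecodeError as e:
        raise ConfigurationError(f"{config_path}: not valid JSON ({e})") from e
    try:
        cfg = SessionConfig.model_validate(raw)
    except PydanticValidationError as e:
        first = e.errors()[0]
        key = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigurationError(f"{config_path}: invalid key '{key}': {first['msg']}") from e
    base = config_path.parent
    resolved = {}
    for attr in ("vfa_path", "dce_path", "sensor_calibration_path", "tumor_roi_path"):
        val = getattr(cfg, attr)
        if val is None:
            continue
        p = Path(val)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise ConfigurationError(f"{config_path}: path for '{attr}' does not exist: {p}")
        resolved[attr] = str(p)
    cfg = cfg.model_copy(update=resolved)
    for key, default in (("options.c_min_mM", cfg.options.c_min_mM),
                         ("options.guard_frac", cfg.options.guard_frac),
                         ("seed", cfg.seed)):
        if _key_absent(raw, key):
            log.info("config %s: using default %s = %s", config_path.name, key, default)
    return cfg


def _key_absent(raw: dict, dotted: str) -> bool:
    node = raw
    for part in dotted.split("."):
        if not isinstance(node, dict) or part not in node:
            return True
        node = node[part]
    return False


def write_provenance(out_dir, config_path=None, seed: int | None = None, extra: dict | None = None) -> Path:
    """Record config hash, seed and package version alongside the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec = {"rphmri_version": __version__, "seed": seed}
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
        rec["config_path"] = str(config_path)
        rec["config_sha256"] = digest
    if extra:
        rec.update(extra)
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(rec, indent=2))
    return path
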