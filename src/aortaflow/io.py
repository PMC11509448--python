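"""Readers and writers: NIfTI stacks, JSON sidecars, CSV tables.

The native on-disk convention is a NIfTI image with cardiac frames stacked
on the third axis, accompanied by a JSON sidecar holding the acquisition
metadata a DICOM header would otherwise carry (venc, pixel spacing, frame
times, optional intensity scaling).  Index and agreement tables are plain
CSV under fixed column contracts; every table written here starts with a
provenance comment line (config hash + seed), which the paired readers
skip.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .config import RunConfig
from .flow import INDEX_COLUMNS
from .series import LumenMaskSeries, VelocitySeries

logger = logging.getLogger("aortaflow")

__all__ = [
    "SidecarMeta",
    "read_velocity_series",
    "write_velocity_series",
    "read_mask_series",
    "write_mask_series",
    "write_indices_csv",
    "read_indices_csv",
    "write_agreement_outputs",
]


@dataclass
class SidecarMeta:
    """Acquisition metadata carried alongside a velocity NIfTI stack."""

    venc_cm_s: float
    pixel_spacing_mm: tuple[float, float]
    frame_times_ms: list[float]
    rr_ms: float | None = None
    scale: tuple[float, float] | None = None  # (slope, intercept) -> cm/s
    unwrapped: bool = False
    case_id: str = "case"

    def __post_init__(self) -> None:
        if not (self.venc_cm_s > 0):
            raise ValueError("sidecar field 'venc_cm_s' must be positive")
        if np.any(np.diff(self.frame_times_ms) <= 0):
            raise ValueError(
                "sidecar field 'frame_times_ms' must be strictly increasing"
            )
        if self.scale is not None and self.scale[0] == 0:
            raise ValueError("sidecar field 'scale' slope must be nonzero")

    @classmethod
    def from_json(cls, path) -> "SidecarMeta":
        with open(path) as fh:
            data = json.load(fh)
        if "venc_cm_s" not in data:
            raise ValueError(f"sidecar {path}: missing required field 'venc_cm_s'")
        for field in ("pixel_spacing_mm", "frame_times_ms"):
            if field not in data:
                raise ValueError(f"sidecar {path}: missing required field {field!r}")
        return cls(
            venc_cm_s=float(data["venc_cm_s"]),
            pixel_spacing_mm=tuple(data["pixel_spacing_mm"]),
            frame_times_ms=list(data["frame_times_ms"]),
            rr_ms=data.get("rr_ms"),
            scale=tuple(data["scale"]) if data.get("scale") else None,
            unwrapped=bool(data.get("unwrapped", False)),
            case_id=data.get("case_id", "case"),
        )

    def to_json(self, path) -> None:
        data = {
            "venc_cm_s": self.venc_cm_s,
            "pixel_spacing_mm": list(self.pixel_spacing_mm),
            "frame_times_ms": list(map(float, self.frame_times_ms)),
            "rr_ms": self.rr_ms,
            "scale": list(self.scale) if self.scale else None,
            "unwrapped": self.unwrapped,
            "case_id": self.case_id,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


def _nifti_affine(spacing: tuple[float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], 1.0, 1.0])


def write_velocity_series(vel: VelocitySeries, image_path, sidecar_path) -> None:
    """Write a velocity stack (frames on the third axis) plus its sidecar."""
    data = np.transpose(vel.velocity, (1, 2, 0))
    img = nib.Nifti1Image(data.astype(np.float64), _nifti_affine(vel.pixel_spacing_mm))
    nib.save(img, str(image_path))
    SidecarMeta(
        venc_cm_s=vel.venc_cm_s,
        pixel_spacing_mm=vel.pixel_spacing_mm,
        frame_times_ms=list(map(float, vel.frame_times_ms)),
        rr_ms=vel.rr_ms,
        unwrapped=vel.unwrapped,
        case_id=vel.case_id,
    ).to_json(sidecar_path)
    logger.info("wrote velocity series %s (%d frames)", image_path, vel.n_frames)


def read_velocity_series(image_path, sidecar_path) -> VelocitySeries:
    """Read a velocity stack and sidecar into a validated VelocitySeries.

    Stored values are mapped to cm/s through the sidecar ``scale``
    (slope, intercept) when present.  Velocities beyond venc without the
    ``unwrapped`` flag draw a warning, not an error.
    """
    meta = SidecarMeta.from_json(sidecar_path)
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected a 3-D NIfTI (rows, cols, frames)")
    if data.shape[2] != len(meta.frame_times_ms):
        raise ValueError(
            f"frame-count mismatch: image has {data.shape[2]} frames, "
            f"sidecar lists {len(meta.frame_times_ms)}"
        )
    vel = np.transpose(data, (2, 0, 1))
    if meta.scale is not None:
        slope, intercept = meta.scale
        vel = slope * vel + intercept
    if not meta.unwrapped and np.abs(vel).max() > meta.venc_cm_s:
        warnings.warn(
            "velocities exceed venc but data are not flagged unwrapped",
            stacklevel=2,
        )
    return VelocitySeries(
        velocity=vel,
        pixel_spacing_mm=meta.pixel_spacing_mm,
        frame_times_ms=np.asarray(meta.frame_times_ms, dtype=float),
        venc_cm_s=meta.venc_cm_s,
        rr_ms=meta.rr_ms,
        unwrapped=meta.unwrapped,
        case_id=meta.case_id,
    )


def write_mask_series(
    masks: LumenMaskSeries, path, pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
) -> None:
    data = np.transpose(masks.masks.astype(np.uint8), (1, 2, 0))
    nib.save(nib.Nifti1Image(data, _nifti_affine(pixel_spacing_mm)), str(path))


def read_mask_series(path, atol: float = 1e-6) -> LumenMaskSeries:
    """Read a mask stack, binarising at 0.5; non-binary values are an error."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected a 3-D NIfTI mask stack")
    off_binary = np.minimum(np.abs(data), np.abs(data - 1.0))
    if off_binary.max() > atol:
        raise ValueError("mask file contains non-binary values")
    return LumenMaskSeries(np.transpose(data > 0.5, (2, 0, 1)))


def _provenance_line(config: RunConfig | None) -> str:
    config = config or RunConfig()
    return f"# aortaflow config={config.digest()} seed={config.seed}\n"


def write_indices_csv(table: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """Write a per-case index table under the fixed column contract."""
    missing = [c for c in ["case_id"] + INDEX_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"index table missing columns: {missing}")
    with open(path, "w") as fh:
        fh.write(_provenance_line(config))
        table[["case_id"] + INDEX_COLUMNS].to_csv(fh, index=False)
    logger.info("wrote indices table %s (%d cases)", path, len(table))


def read_indices_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_agreement_outputs(results, outdir, config: RunConfig | None = None) -> None:
    """Write agreement.csv, bland_altman.csv and per-index plot data."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance_line(config)
    with open(outdir / "agreement.csv", "w") as fh:
        fh.write(prov)
        results.agreement_table().to_csv(fh)
    with open(outdir / "bland_altman.csv", "w") as fh:
        fh.write(prov)
        results.bland_altman_table().to_csv(fh)
    for index in results.summary().index:
        with open(outdir / f"ba_points_{index}.csv", "w") as fh:
            fh.write(prov)
            results.ba_points(index).to_csv(fh, index=False)
    logger.info("wrote agreement outputs to %s", outdir)
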