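"""File I/O: NIfTI volumes, JSON schedule sidecars, CSV TACs.

Layout on disk mirrors common dynamic-PET conventions: a 4D NIfTI image,
a JSON sidecar ``{"frames": [[start_s, end_s], ...], "calibration": ...}``,
and tidy CSV TACs with columns ``mid_s, mean, sd, units``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .frames import (
    TAC,
    CountsCalibration,
    DynamicImage,
    FrameSchedule,
    ValidationError,
)

__all__ = [
    "write_dynamic",
    "read_dynamic",
    "write_mask",
    "read_mask",
    "write_tac",
    "read_tac",
    "write_schedule",
    "read_schedule",
]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.diag([*voxel_size_mm, 1.0])
    return aff


def write_schedule(path: str | Path, schedule: FrameSchedule,
                   calibration: CountsCalibration | None = None) -> None:
    doc: dict = {"frames": [[s, e] for s, e in schedule.frames]}
    if calibration is not None:
        doc["calibration"] = {
            "sensitivity": calibration.sensitivity,
            "dose_fraction": calibration.dose_fraction,
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_schedule(path: str | Path) -> tuple[FrameSchedule, CountsCalibration | None]:
    doc = json.loads(Path(path).read_text())
    schedule = FrameSchedule(tuple((float(s), float(e)) for s, e in doc["frames"]))
    cal = None
    if "calibration" in doc:
        cal = CountsCalibration(**doc["calibration"])
    return schedule, cal


def write_dynamic(image: DynamicImage, image_path: str | Path,
                  sidecar_path: str | Path | None = None) -> None:
    """Write a 4D NIfTI plus its JSON schedule/calibration sidecar."""
    image_path = Path(image_path)
    if sidecar_path is None:
        sidecar_path = image_path.with_suffix("").with_suffix(".json") \
            if image_path.name.endswith(".nii.gz") else image_path.with_suffix(".json")
    nii = nib.Nifti1Image(image.voxels.astype(np.float64), _affine(image.voxel_size_mm))
    nii.header.set_xyzt_units("mm", "sec")
    nib.save(nii, str(image_path))
    write_schedule(sidecar_path, image.schedule, image.calibration)


def read_dynamic(image_path: str | Path, sidecar_path: str | Path | None = None) -> DynamicImage:
    image_path = Path(image_path)
    if sidecar_path is None:
        sidecar_path = image_path.with_suffix("").with_suffix(".json") \
            if image_path.name.endswith(".nii.gz") else image_path.with_suffix(".json")
    nii = nib.load(str(image_path))
    voxels = np.asarray(nii.dataobj, dtype=float)
    if voxels.ndim == 3:
        voxels = voxels[..., None]
    schedule, cal = read_schedule(sidecar_path)
    if voxels.shape[3] != schedule.n_frames:
        raise ValidationError(
            f"image has {voxels.shape[3]} frames but sidecar lists {schedule.n_frames}"
        )
    voxel_size = tuple(float(v) for v in nii.header.get_zooms()[:3])
    return DynamicImage(voxels, voxel_size, schedule, cal or CountsCalibration())


def write_mask(mask: np.ndarray, voxel_size_mm, path: str | Path) -> None:
    nii = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size_mm))
    nib.save(nii, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def write_tac(tac: TAC, path: str | Path) -> None:
    pd.DataFrame(
        {"mid_s": tac.mid_s, "mean": tac.mean, "sd": tac.sd, "units": tac.units}
    ).to_csv(path, index=False)


def read_tac(path: str | Path) -> TAC:
    df = pd.read_csv(path)
    units = str(df["units"].iloc[0]) if "units" in df else "kBq/ml"
    return TAC(
        mid_s=df["mid_s"].to_numpy(float),
        mean=df["mean"].to_numpy(float),
        sd=df["sd"].to_numpy(float) if "sd" in df else np.zeros(len(df)),
        units=units,
    )
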