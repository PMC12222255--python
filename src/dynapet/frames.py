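"""Frame schedules, dynamic image containers, ROI tools, and SUV scaling.

Dynamic PET data are represented as a 4D activity-concentration volume
(kBq/ml) bound to an ordered frame schedule.  Frames are half-open
intervals [start_s, end_s) in seconds, contiguous and non-overlapping.
A :class:`CountsCalibration` record converts concentration to expected
detected counts, which is what every noise, thinning, and count-matching
operation in this package works with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FrameSchedule",
    "CountsCalibration",
    "DynamicImage",
    "TAC",
    "SubjectMeta",
    "parse_schedule_spec",
    "roi_extract",
    "threshold_voi",
    "suv_scale",
    "STANDARD_SCHEDULES",
]


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered sequence of contiguous half-open frame intervals, in seconds."""

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("schedule must contain at least one frame")
        prev_end = None
        for start, end in self.frames:
            if end <= start:
                raise ValidationError(f"frame [{start}, {end}) has non-positive duration")
            if prev_end is None:
                if start < 0:
                    raise ValidationError("first frame must start at t >= 0")
            elif start != prev_end:
                raise ValidationError("frames must be contiguous (start == previous end)")
            prev_end = end

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def start_s(self) -> np.ndarray:
        return np.array([f[0] for f in self.frames], dtype=float)

    @property
    def end_s(self) -> np.ndarray:
        return np.array([f[1] for f in self.frames], dtype=float)

    @property
    def mid_s(self) -> np.ndarray:
        return 0.5 * (self.start_s + self.end_s)

    @property
    def duration_s(self) -> np.ndarray:
        return self.end_s - self.start_s

    @property
    def total_duration_s(self) -> float:
        return float(self.frames[-1][1] - self.frames[0][0])


@dataclass(frozen=True)
class CountsCalibration:
    """Image-space counts proxy: expected counts per (kBq/ml * ml * s).

    ``dose_fraction`` records how much of the originally injected dose the
    image represents (1.0 for a full-dose acquisition, 0.05 after 1/20
    thinning); expected counts scale linearly with it.
    """

    sensitivity: float = 60.0
    dose_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.sensitivity > 0:
            raise ValidationError("sensitivity must be > 0")
        if not (0 < self.dose_fraction <= 1):
            raise ValidationError("dose_fraction must lie in (0, 1]")

    def scaled(self, factor: float) -> "CountsCalibration":
        return CountsCalibration(self.sensitivity, self.dose_fraction * factor)


@dataclass
class DynamicImage:
    """4D activity-concentration volume (kBq/ml), indexed (x, y, z, frame)."""

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule
    calibration: CountsCalibration = field(default_factory=CountsCalibration)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValidationError("voxels must be a 4D array (x, y, z, frame)")
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise ValidationError(
                f"image has {self.voxels.shape[3]} frames but schedule has "
                f"{self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("activity values must be finite")
        if not all(v > 0 for v in self.voxel_size_mm):
            raise ValidationError("voxel_size_mm must be positive")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def frame(self, i: int) -> np.ndarray:
        return self.voxels[..., i]

    def time_weighted_mean(self, after_s: float = 0.0) -> np.ndarray:
        """Duration-weighted mean over frames whose mid-time is >= ``after_s``."""
        sel = self.schedule.mid_s >= after_s
        if not np.any(sel):
            sel = np.ones(self.schedule.n_frames, dtype=bool)
        w = self.schedule.duration_s[sel]
        return np.tensordot(self.voxels[..., sel], w / w.sum(), axes=([3], [0]))


@dataclass
class TAC:
    """Time-activity curve: per-frame mean and spatial SD inside a region."""

    mid_s: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    units: str = "kBq/ml"

    def __post_init__(self) -> None:
        self.mid_s = np.asarray(self.mid_s, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.mid_s) == len(self.mean) == len(self.sd)):
            raise ValidationError("mid_s, mean, sd must have equal length")
        if np.any(self.sd < 0):
            raise ValidationError("sd must be non-negative")


@dataclass(frozen=True)
class SubjectMeta:
    """Injected dose, body weight and tracer identity for SUV scaling."""

    injected_dose_MBq: float
    weight_kg: float
    tracer: str = "FDG"
    half_life_s: float = 6586.2  # F-18

    def __post_init__(self) -> None:
        if self.injected_dose_MBq <= 0 or self.weight_kg <= 0 or self.half_life_s <= 0:
            raise ValidationError("SubjectMeta fields must be positive")


def parse_schedule_spec(spec: Sequence[tuple[int, float]]) -> FrameSchedule:
    """Expand a run-length frame specification into a contiguous schedule.

    ``spec`` is a sequence of ``(count, duration_s)`` groups, e.g. the
    60-min protocol ``[(12, 5), (6, 10), (3, 20), (2, 30), (6, 60),
    (10, 300)]`` expands to 39 frames totalling 3600 s.
    """
    if not spec:
        raise ValidationError("schedule spec is empty")
    frames: list[tuple[float, float]] = []
    t = 0.0
    for count, duration in spec:
        if int(count) != count or count < 1:
            raise ValidationError(f"frame count must be a positive integer, got {count}")
        if duration <= 0:
            raise ValidationError(f"frame duration must be > 0, got {duration}")
        for _ in range(int(count)):
            frames.append((t, t + duration))
            t += duration
    return FrameSchedule(tuple(frames))


#: Frame groupings of the dynamic protocols used throughout the docs/tests:
#: a 60-min FDG scan, a 30-min glutamine-tracer scan, and the two halves of
#: a sequential dual-tracer session (29-min FGln followed by 65-min FDG).
STANDARD_SCHEDULES: dict[str, tuple[tuple[int, float], ...]] = {
    "fdg_60min": ((12, 5), (6, 10), (3, 20), (2, 30), (6, 60), (10, 300)),
    "fgln_30min": ((24, 5), (6, 10), (3, 20), (2, 30), (5, 60), (4, 300)),
    "dual_fgln_29min": ((12, 5), (6, 10), (3, 20), (2, 30), (6, 60), (3, 300), (1, 240)),
    "dual_fdg_65min": ((12, 5), (6, 10), (3, 20), (2, 30), (6, 60), (11, 300)),
}


def roi_extract(image: DynamicImage, mask: np.ndarray) -> TAC:
    """Per-frame mean and population SD of voxel values inside ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape3d:
        raise ValidationError(
            f"mask shape {mask.shape} does not match image {image.shape3d}"
        )
    if not mask.any():
        raise ValidationError("mask is empty")
    vals = image.voxels[mask]  # (n_voxels, n_frames)
    return TAC(
        mid_s=image.schedule.mid_s,
        mean=vals.mean(axis=0),
        sd=vals.std(axis=0, ddof=0),
        units="kBq/ml",
    )


def threshold_voi(image3d: np.ndarray, parent_mask: np.ndarray, fraction: float) -> np.ndarray:
    """Voxels inside ``parent_mask`` at or above ``fraction`` of the in-mask max.

    Used for isocontour lesion definition, e.g. 60 % of the maximum voxel
    value inside a generous parent VOI.
    """
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must lie in (0, 1]")
    image3d = np.asarray(image3d, dtype=float)
    parent_mask = np.asarray(parent_mask, dtype=bool)
    if parent_mask.shape != image3d.shape:
        raise ValidationError("parent mask shape does not match image")
    if not parent_mask.any():
        raise ValidationError("parent mask is empty")
    peak = image3d[parent_mask].max()
    if peak <= 0:
        raise ValidationError("parent region is all-zero; threshold undefined")
    out = np.zeros_like(parent_mask)
    out[parent_mask] = image3d[parent_mask] >= fraction * peak
    return out


def suv_scale(tac: TAC, meta: SubjectMeta) -> TAC:
    """Convert a kBq/ml TAC to SUV (body-weight normalized).

    SUV = concentration / (injected dose [kBq] / body weight [g]); with
    tissue density 1 g/ml this is the conventional unitless SUV.
    """
    if tac.units.lower() not in ("kbq/ml", "kbq/cc"):
        raise ValidationError(f"expected a kBq/ml TAC, got units {tac.units!r}")
    dose_kBq = meta.injected_dose_MBq * 1000.0
    weight_g = meta.weight_kg * 1000.0
    factor = weight_g / dose_kBq
    return TAC(mid_s=tac.mid_s.copy(), mean=tac.mean * factor, sd=tac.sd * factor, units="SUV")
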