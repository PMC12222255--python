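"""Synthetic dynamic-PET phantom with known ground-truth kinetics.

The phantom is a stack of ellipsoidal organ regions on a voxel grid, each
driven by a compartment model (or flagged as a blood pool carrying the
arterial input function).  Count statistics are emulated in image space:
expected detected counts per voxel-frame are

    counts = concentration [kBq/ml] * voxel volume [ml] * frame duration [s]
             * sensitivity * dose_fraction,

on which Poisson noise, binomial dose-reduction thinning, and Poisson
bootstrap replicates operate.  This deliberately ignores reconstruction
noise correlations (no projection-space simulation) while preserving the
dose / duration / activity dependence that drives low-dose analyses.

All stochastic operations take an explicit seed; :func:`spawn_seeds`
documents the master-seed fan-out rule (``numpy.random.SeedSequence``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .frames import (
    CountsCalibration,
    DynamicImage,
    FrameSchedule,
    SubjectMeta,
    ValidationError,
    parse_schedule_spec,
    STANDARD_SCHEDULES,
)
from .kinetics import (
    KineticParams,
    frame_average,
    model_tac_1tcm,
    model_tac_2tcm_irr,
)

__all__ = [
    "IFParams",
    "Region",
    "PhantomSpec",
    "DoseLevel",
    "feng_if",
    "region_masks",
    "render_dynamic",
    "expected_counts",
    "counts_to_image",
    "add_poisson_noise",
    "thin_counts",
    "bootstrap_counts",
    "default_phantom",
    "simulate_noisy_dynamic",
    "spawn_seeds",
]


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Fan a master seed out into ``n`` independent child seeds (< 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


@dataclass(frozen=True)
class IFParams:
    """Analytic arterial input function: linear rise times a fast exponential
    plus two slower washout exponentials (the classic tri-exponential form).

    Cp(t) = (A1*tau - A2 - A3) e^{-l1 tau} + A2 e^{-l2 tau} + A3 e^{-l3 tau}
    for tau = t - t0 >= 0, zero before the appearance delay t0.
    A1 is in kBq/ml/min, A2/A3 in kBq/ml, l1 > l2 > l3 >= 0 in 1/min.
    """

    A1: float = 800.0
    A2: float = 20.0
    A3: float = 21.0
    l1: float = 4.0
    l2: float = 0.12
    l3: float = 0.01
    t0_s: float = 10.0

    def __post_init__(self) -> None:
        if not (self.l1 > self.l2 > self.l3 >= 0):
            raise ValidationError("require l1 > l2 > l3 >= 0")
        if self.A1 <= 0 or self.t0_s < 0:
            raise ValidationError("A1 must be > 0 and t0 >= 0")


def feng_if(params: IFParams, t_s: np.ndarray) -> np.ndarray:
    """Evaluate the analytic input function on a time grid (seconds)."""
    t_s = np.asarray(t_s, dtype=float)
    if np.any(np.diff(t_s) < 0) or np.any(t_s < 0):
        raise ValidationError("time grid must be ascending and non-negative")
    tau = (t_s - params.t0_s) / 60.0  # minutes since appearance
    tau = np.maximum(tau, 0.0)
    c = ((params.A1 * tau - params.A2 - params.A3) * np.exp(-params.l1 * tau)
         + params.A2 * np.exp(-params.l2 * tau)
         + params.A3 * np.exp(-params.l3 * tau))
    c[t_s < params.t0_s] = 0.0
    if c.min() < -1e-9:
        raise ValidationError("input-function parameters yield negative values")
    return np.maximum(c, 0.0)


@dataclass(frozen=True)
class Region:
    """Ellipsoidal tissue or blood-pool region."""

    name: str
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    model: Literal["1tcm", "2tcm_irr", "blood"]
    kinetics: KineticParams | None = None

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValidationError("semi-axes must be positive")
        if self.model == "blood":
            if self.kinetics is not None:
                raise ValidationError("blood-pool regions carry no tissue kinetics")
        elif self.kinetics is None:
            raise ValidationError(f"region {self.name!r} needs kinetic parameters")


@dataclass(frozen=True)
class PhantomSpec:
    """Voxel grid plus layered regions (later regions overwrite earlier)."""

    grid: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        if any(g < 8 for g in self.grid):
            raise ValidationError("grid dimensions must be >= 8")


@dataclass(frozen=True)
class DoseLevel:
    factor: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.factor <= 1):
            raise ValidationError("dose factor must lie in (0, 1]")


def region_masks(phantom: PhantomSpec) -> dict[str, np.ndarray]:
    """Boolean mask per region, honoring last-writer-wins layering."""
    nx, ny, nz = phantom.grid
    vx, vy, vz = phantom.voxel_size_mm
    x = (np.arange(nx) + 0.5) * vx
    y = (np.arange(ny) + 0.5) * vy
    z = (np.arange(nz) + 0.5) * vz
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    owner = np.full(phantom.grid, -1, dtype=int)
    for i, r in enumerate(phantom.regions):
        cx, cy, cz = r.center_mm
        ax, ay, az = r.semi_axes_mm
        inside = ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0
        owner[inside] = i
    return {r.name: owner == i for i, r in enumerate(phantom.regions)}


def region_curve(region: Region, if_curve: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Continuous concentration curve of a region on the IF grid."""
    if region.model == "blood":
        return np.asarray(if_curve, dtype=float)
    if region.model == "1tcm":
        return model_tac_1tcm(region.kinetics, if_curve, dt)
    if region.model == "2tcm_irr":
        return model_tac_2tcm_irr(region.kinetics, if_curve, dt)
    raise ValidationError(f"region {region.name!r} references unknown model {region.model!r}")


def render_dynamic(
    phantom: PhantomSpec,
    if_curve: np.ndarray,
    schedule: FrameSchedule,
    dt: float = 1.0,
    calibration: CountsCalibration | None = None,
) -> DynamicImage:
    """Noiseless 4D image: each voxel holds its region's frame-averaged curve.

    ``if_curve`` is the arterial input sampled on a uniform ``dt`` grid from
    t = 0 covering the schedule; background voxels are zero.
    """
    n_needed = int(np.ceil(schedule.end_s[-1] / dt)) + 1
    if len(if_curve) < n_needed:
        raise ValidationError("input-function grid does not cover the schedule")
    masks = region_masks(phantom)
    voxels = np.zeros((*phantom.grid, schedule.n_frames), dtype=float)
    for region in phantom.regions:
        mask = masks[region.name]
        if not mask.any():
            continue
        curve = region_curve(region, if_curve, dt)
        voxels[mask] = frame_average(curve, dt, schedule)
    return DynamicImage(voxels, phantom.voxel_size_mm, schedule,
                        calibration or CountsCalibration())


def expected_counts(image: DynamicImage) -> np.ndarray:
    """Expected detected counts per voxel-frame under the image calibration."""
    cal = image.calibration
    scale = image.voxel_volume_ml * cal.sensitivity * cal.dose_fraction
    counts = image.voxels * image.schedule.duration_s * scale
    if counts.min() < 0:
        raise ValidationError("negative expected counts")
    return counts


def counts_to_image(counts: np.ndarray, template: DynamicImage,
                    calibration: CountsCalibration | None = None) -> DynamicImage:
    """Convert a counts array back to concentration via a calibration."""
    cal = calibration or template.calibration
    scale = template.voxel_volume_ml * cal.sensitivity * cal.dose_fraction
    voxels = np.asarray(counts, dtype=float) / (template.schedule.duration_s * scale)
    return DynamicImage(voxels, template.voxel_size_mm, template.schedule, cal)


def add_poisson_noise(image: DynamicImage, seed: int) -> DynamicImage:
    """Sample Poisson counts around the expected counts and convert back."""
    lam = expected_counts(image)
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(lam).astype(float)
    return counts_to_image(noisy, image)


def thin_counts(
    counts: np.ndarray,
    level: DoseLevel | float,
    seed: int,
    complementary: bool = False,
):
    """Binomial thinning of integer counts (dose-reduction analog).

    Each entry n becomes Binomial(n, factor); with ``complementary`` the
    pair (thinned, n - thinned) is returned, which partitions the events.
    """
    factor = level.factor if isinstance(level, DoseLevel) else float(level)
    if not (0 < factor <= 1):
        raise ValidationError("thinning factor must lie in (0, 1]")
    counts = np.asarray(counts)
    if counts.min() < 0:
        raise ValidationError("counts must be non-negative")
    n = np.rint(counts).astype(np.int64)
    if factor == 1.0:
        thinned = n.copy()
    else:
        rng = np.random.default_rng(seed)
        thinned = rng.binomial(n, factor)
    if complementary:
        return thinned, n - thinned
    return thinned


def bootstrap_counts(counts: np.ndarray, B: int, seed: int) -> np.ndarray:
    """Poisson resampling replicates of an observed count array.

    Image-space analog of list-mode bootstrapping: each replicate entry is
    Poisson(observed), independent across replicates; returns an array of
    shape (B, *counts.shape).
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    n = np.rint(np.asarray(counts)).astype(np.int64)
    reps = np.empty((B,) + n.shape, dtype=np.int64)
    for b, s in enumerate(spawn_seeds(seed, B)):
        reps[b] = np.random.default_rng(s).poisson(n)
    return reps


# --------------------------------------------------------------------------
# default desk-scale phantom

_DEFAULT_KINETICS: dict[str, tuple[str, KineticParams]] = {
    # low-uptake soft-tissue background filling the body contour
    "body": ("2tcm_irr", KineticParams(K1=0.02, k2=0.35, k3=0.002, vB=0.03)),
    # FDG-like tissues (irreversible 2-TCM)
    "liver": ("2tcm_irr", KineticParams(K1=0.66, k2=0.66, k3=0.011, vB=0.22)),
    "lung": ("2tcm_irr", KineticParams(K1=0.02, k2=0.25, k3=0.006, vB=0.15)),
    "muscle": ("2tcm_irr", KineticParams(K1=0.03, k2=0.30, k3=0.010, vB=0.02)),
    "thalamus": ("2tcm_irr", KineticParams(K1=0.10, k2=0.13, k3=0.062, vB=0.04)),
    # glutamine-tracer-like lesion (reversible 1-TCM); the necrotic core has
    # reduced delivery and distribution volume
    "lesion": ("1tcm", KineticParams(K1=0.30, k2=0.15, vB=0.05)),
    "lesion_core": ("1tcm", KineticParams(K1=0.08, k2=0.16, vB=0.02)),
}


def default_phantom(size: str = "small") -> tuple[PhantomSpec, IFParams, SubjectMeta]:
    """Documented multi-organ phantom with stored ground-truth kinetics.

    ``small`` is a 32^3 grid of 4 mm voxels holding a soft-tissue body
    background enclosing liver, lung, muscle, thalamus, descending aorta
    (DA), right ventricle (RV), and a lesion with a low-uptake core;
    ``demo`` is the same layout at 48^3.
    """
    if size not in ("small", "demo"):
        raise ValidationError(f"unknown phantom size {size!r}")
    n = 32 if size == "small" else 48
    vox = 4.0
    extent = n * vox  # mm
    s = extent / 128.0  # scale factor relative to the reference 128 mm layout

    def c(x, y, z):
        return (x * s, y * s, z * s)

    def r(x, y, z):
        return (x * s, y * s, z * s)

    regions = (
        Region("body", c(64, 64, 64), r(58, 58, 60), "2tcm_irr",
               _DEFAULT_KINETICS["body"][1]),
        Region("liver", c(44, 44, 42), r(17, 14, 13), "2tcm_irr",
               _DEFAULT_KINETICS["liver"][1]),
        Region("lung", c(44, 44, 88), r(14, 13, 15), "2tcm_irr",
               _DEFAULT_KINETICS["lung"][1]),
        Region("muscle", c(84, 44, 40), r(9, 9, 18), "2tcm_irr",
               _DEFAULT_KINETICS["muscle"][1]),
        Region("thalamus", c(44, 86, 90), r(9, 9, 9), "2tcm_irr",
               _DEFAULT_KINETICS["thalamus"][1]),
        Region("descending_aorta", c(64, 88, 64), r(7, 7, 30), "blood"),
        Region("right_ventricle", c(86, 86, 36), r(11, 11, 11), "blood"),
        Region("lesion", c(86, 84, 88), r(12, 12, 12), "1tcm",
               _DEFAULT_KINETICS["lesion"][1]),
        Region("lesion_core", c(86, 84, 88), r(5, 5, 5), "1tcm",
               _DEFAULT_KINETICS["lesion_core"][1]),
    )
    phantom = PhantomSpec((n, n, n), (vox, vox, vox), regions)
    meta = SubjectMeta(injected_dose_MBq=370.0, weight_kg=74.0, tracer="FDG")
    return phantom, IFParams(), meta


def simulate_noisy_dynamic(
    size: str,
    schedule_name: str,
    seed: int,
    dose_factor: float = 1.0,
) -> tuple[DynamicImage, DynamicImage, dict[str, np.ndarray], np.ndarray]:
    """Convenience pipeline: phantom -> clean image -> thinned noisy image.

    Returns (noisy, clean, region masks, input-function fine-grid curve).
    The full-dose acquisition is Poisson-sampled once and, for
    dose_factor < 1, binomially thinned — mirroring sub-sampling of an
    acquired scan rather than an independent low-dose acquisition.
    """
    phantom, ifp, _ = default_phantom(size)
    schedule = parse_schedule_spec(STANDARD_SCHEDULES[schedule_name])
    t = np.arange(0.0, schedule.end_s[-1] + 1.0)
    cp = feng_if(ifp, t)
    clean = render_dynamic(phantom, cp, schedule)
    seeds = spawn_seeds(seed, 2)
    noisy_full = add_poisson_noise(clean, seeds[0])
    if dose_factor < 1.0:
        counts = expected_counts(noisy_full)  # full-dose observed counts
        thinned = thin_counts(counts, dose_factor, seeds[1])
        noisy = counts_to_image(thinned, clean,
                                clean.calibration.scaled(dose_factor))
    else:
        noisy = noisy_full
    return noisy, clean, region_masks(phantom), cp
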