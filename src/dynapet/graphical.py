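"""Patlak and Logan graphical analysis at ROI and voxel level.

Patlak (irreversible tracers): CT(t)/Cp(t) regressed on
int_0^t Cp / Cp(t); the slope after the equilibrium time t* is the net
influx rate Ki.  Logan (reversible tracers): int_0^t CT / CT(t) regressed
on int_0^t Cp / CT(t); the slope is the total volume of distribution VT.

Plasma integrals are evaluated by trapezoid on the fine input-function
grid; tissue integrals by trapezoid over frame mid-times with a zero
anchor at t = 0.  A frame enters the regression iff its mid-time is
>= t*.  Voxels whose series violate the preconditions (non-positive CT
for Logan) are masked out of parametric maps rather than clamped, and
negative slopes are retained so that noise-induced bias stays measurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import TAC, DynamicImage, ValidationError
from .kinetics import cumtrapz_uniform

__all__ = [
    "GraphicalResult",
    "ParametricMap",
    "patlak_roi",
    "logan_roi",
    "patlak_image",
    "logan_image",
]


@dataclass(frozen=True)
class GraphicalResult:
    slope: float  # Ki (ml/min/cm^3) for Patlak, VT (ml/cm^3) for Logan
    intercept: float
    n_points: int
    r_squared: float


@dataclass
class ParametricMap:
    voxels: np.ndarray  # 3D slope values, 0 outside mask
    intercepts: np.ndarray
    mask: np.ndarray  # voxels actually fitted
    tstar_min: float


def _plasma_terms(cp: np.ndarray, dt: float, mid_s: np.ndarray):
    """Cp and int_0^t Cp (in conc*min) interpolated at frame mid-times."""
    t = np.arange(len(cp)) * dt
    if mid_s[-1] > t[-1] + dt:
        raise ValidationError("input-function grid does not cover the TAC")
    cum = cumtrapz_uniform(np.asarray(cp, float), dt) / 60.0  # conc * min
    return np.interp(mid_s, t, cp), np.interp(mid_s, t, cum)


def _tissue_integral(mid_s: np.ndarray, ct: np.ndarray) -> np.ndarray:
    """Trapezoid integral of the TAC over time (conc*min), zero anchor at 0."""
    tm = np.concatenate([[0.0], mid_s]) / 60.0
    c = np.concatenate([ct[..., :1] * 0.0, ct], axis=-1)
    dt = np.diff(tm)
    seg = (c[..., 1:] + c[..., :-1]) * (dt / 2)
    return np.cumsum(seg, axis=-1)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValidationError("degenerate regressor (zero variance)")
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    ss_res = np.sum((y - slope * x - intercept) ** 2)
    ss_tot = np.sum((y - ym) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(min(max(r2, 0.0), 1.0))


def _late(mid_s: np.ndarray, tstar_min: float) -> np.ndarray:
    sel = mid_s >= tstar_min * 60.0
    if sel.sum() < 2:
        raise ValidationError(
            f"fewer than 2 frames with mid-time >= t* = {tstar_min} min"
        )
    return sel


def patlak_roi(tac: TAC, cp: np.ndarray, tstar_min: float, dt: float = 1.0) -> GraphicalResult:
    """Patlak regression on an ROI TAC; slope is reported as Ki."""
    sel = _late(tac.mid_s, tstar_min)
    cp_mid, icp_mid = _plasma_terms(cp, dt, tac.mid_s)
    if np.any(cp_mid[sel] <= 0):
        raise ValidationError("non-positive plasma concentration in used frames")
    x = icp_mid[sel] / cp_mid[sel]
    y = tac.mean[sel] / cp_mid[sel]
    slope, intercept, r2 = _ols(x, y)
    return GraphicalResult(slope, intercept, int(sel.sum()), r2)


def logan_roi(tac: TAC, cp: np.ndarray, tstar_min: float, dt: float = 1.0) -> GraphicalResult:
    """Logan regression on an ROI TAC; slope is reported as VT."""
    sel = _late(tac.mid_s, tstar_min)
    if np.any(tac.mean[sel] <= 0):
        raise ValidationError("non-positive tissue concentration in used frames")
    cp_mid, icp_mid = _plasma_terms(cp, dt, tac.mid_s)
    ict = _tissue_integral(tac.mid_s, tac.mean)
    x = icp_mid[sel] / tac.mean[sel]
    y = ict[sel] / tac.mean[sel]
    slope, intercept, r2 = _ols(x, y)
    return GraphicalResult(slope, intercept, int(sel.sum()), r2)


def _vector_ols(x: np.ndarray, y: np.ndarray):
    """OLS slope/intercept for shared or per-voxel x against y (..., n)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        xm = x.mean(axis=-1, keepdims=True)
        ym = y.mean(axis=-1, keepdims=True)
        sxx = np.sum((x - xm) ** 2, axis=-1)
        sxy = np.sum((x - xm) * (y - ym), axis=-1)
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        intercept = ym[..., 0] - slope * xm[..., 0]
    return slope, intercept


def patlak_image(
    img: DynamicImage, cp: np.ndarray, tstar_min: float,
    mask: np.ndarray, dt: float = 1.0,
) -> ParametricMap:
    """Voxelwise Patlak Ki map inside ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape3d:
        raise ValidationError("mask shape mismatch")
    if not mask.any():
        raise ValidationError("empty mask")
    mid_s = img.schedule.mid_s
    sel = _late(mid_s, tstar_min)
    cp_mid, icp_mid = _plasma_terms(cp, dt, mid_s)
    if np.any(cp_mid[sel] <= 0):
        raise ValidationError("non-positive plasma concentration in used frames")
    x = icp_mid[sel] / cp_mid[sel]  # shared regressor
    ct = img.voxels[mask][:, sel]
    y = ct / cp_mid[sel]
    slope, intercept = _vector_ols(np.broadcast_to(x, y.shape), y)
    ok = np.isfinite(slope)
    out_mask = np.zeros_like(mask)
    out_mask[mask] = ok
    slopes = np.zeros(img.shape3d)
    intercepts = np.zeros(img.shape3d)
    slopes[mask] = np.where(ok, slope, 0.0)
    intercepts[mask] = np.where(ok, intercept, 0.0)
    if not out_mask.any():
        raise ValidationError("no usable voxels in mask")
    return ParametricMap(slopes, intercepts, out_mask, tstar_min)


def logan_image(
    img: DynamicImage, cp: np.ndarray, tstar_min: float,
    mask: np.ndarray, dt: float = 1.0,
) -> ParametricMap:
    """Voxelwise Logan VT map inside ``mask``.

    Voxels with non-positive CT in any used frame are excluded from the
    output mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape3d:
        raise ValidationError("mask shape mismatch")
    if not mask.any():
        raise ValidationError("empty mask")
    mid_s = img.schedule.mid_s
    sel = _late(mid_s, tstar_min)
    cp_mid, icp_mid = _plasma_terms(cp, dt, mid_s)
    ct_all = img.voxels[mask]  # (nvox, nframes)
    usable = np.all(ct_all[:, sel] > 0, axis=1)
    ict = _tissue_integral(mid_s, ct_all)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = icp_mid[sel] / ct_all[:, sel]
        y = ict[:, sel] / ct_all[:, sel]
    slope, intercept = _vector_ols(x, y)
    ok = usable & np.isfinite(slope)
    out_mask = np.zeros_like(mask)
    out_mask[mask] = ok
    slopes = np.zeros(img.shape3d)
    intercepts = np.zeros(img.shape3d)
    slopes[mask] = np.where(ok, slope, 0.0)
    intercepts[mask] = np.where(ok, intercept, 0.0)
    if not out_mask.any():
        raise ValidationError("no usable voxels in mask")
    return ParametricMap(slopes, intercepts, out_mask, tstar_min)
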