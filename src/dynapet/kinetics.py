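"""Compartment-model forward simulation and fitting.

Two tracer models are supported:

* 1-TCM (reversible one-tissue model), macro-parameter VT = K1/k2, the
  total volume of distribution of a reversible tracer such as
  [18F]fluoroglutamine;
* irreversible 2-TCM (k4 = 0), macro-parameter Ki = K1*k3/(k2+k3), the
  net influx (trapping) rate of [18F]FDG.

Rates are expressed in the field's conventional units (K1 in
ml.min^-1.cm^-3, k2/k3/k4 in min^-1) while time grids are in seconds;
conversion happens internally.  The measured curve seen by the scanner is
(1 - vB) * C_tissue + vB * C_blood with vB the fractional blood volume,
and the blood curve may be delayed by ``delay_s`` relative to the tissue
clock.

All convolutions with exponential kernels are evaluated exactly for a
piecewise-linear input on a uniform grid (a first-order recursive
filter), which avoids quadrature drift across the short early frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .frames import TAC, FrameSchedule, ValidationError

__all__ = [
    "KineticParams",
    "DualInputParams",
    "FitOptions",
    "FitResult",
    "expconv",
    "cumtrapz_uniform",
    "model_tac_1tcm",
    "model_tac_2tcm_irr",
    "ki_macro",
    "vt_macro",
    "dual_input",
    "fit_compartment",
    "frame_average",
]


@dataclass(frozen=True)
class KineticParams:
    """Micro-parameters of a tissue compartment model."""

    K1: float  # ml/min/cm^3
    k2: float  # 1/min
    k3: float = 0.0  # 1/min
    k4: float = 0.0  # 1/min; fixed 0 for the irreversible model
    vB: float = 0.05  # unitless blood-volume fraction
    delay_s: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ValidationError("rate constants must be non-negative")
        if not (0 <= self.vB <= 1):
            raise ValidationError("vB must lie in [0, 1]")

    @property
    def ki(self) -> float:
        return ki_macro(self.K1, self.k2, self.k3)

    @property
    def vt(self) -> float:
        return vt_macro(self.K1, self.k2)


@dataclass(frozen=True)
class DualInputParams:
    """Simplified dual-blood supply: arterial fraction + portal dispersion."""

    fa: float = 0.25  # arterial fraction of hepatic blood flow
    ka: float = 1.0  # portal-venous dispersion rate, 1/min

    def __post_init__(self) -> None:
        if not (0 <= self.fa <= 1):
            raise ValidationError("fa must lie in [0, 1]")
        if self.ka <= 0:
            raise ValidationError("ka must be > 0")


def ki_macro(K1: float, k2: float, k3: float) -> float:
    """Net influx rate Ki = K1*k3/(k2+k3) (ml.min^-1.cm^-3)."""
    if k2 + k3 <= 0:
        raise ValidationError("Ki undefined for k2 + k3 = 0")
    return K1 * k3 / (k2 + k3)


def vt_macro(K1: float, k2: float) -> float:
    """Total volume of distribution VT = K1/k2 (ml.cm^-3)."""
    if k2 <= 0:
        raise ValidationError("VT undefined for k2 = 0")
    return K1 / k2


def expconv(cp: np.ndarray, dt: float, k_per_s: float) -> np.ndarray:
    """Convolution of ``cp`` with exp(-k t) on a uniform grid.

    Exact for piecewise-linear ``cp``; returns y(t_i) = int_0^{t_i}
    cp(s) exp(-k (t_i - s)) ds with y(0) = 0.
    """
    cp = np.asarray(cp, dtype=float)
    if k_per_s < 0:
        raise ValidationError("rate must be non-negative")
    x = k_per_s * dt
    if x < 1e-10:  # pure integrator: trapezoid
        return cumtrapz_uniform(cp, dt)
    E = np.exp(-x)
    if x > 1e-6:
        a = -np.expm1(-x) / k_per_s
        b = (-np.expm1(-x) - x * E) / k_per_s**2
    else:  # series, avoids cancellation
        a = dt * (1 - x / 2 + x * x / 6)
        b = dt * dt * (0.5 - x / 3 + x * x / 8)
    # segment [i, i+1] contributes c_{i+1}*a - m*b, m = (c_{i+1}-c_i)/dt
    d = np.empty_like(cp)
    d[0] = 0.0
    d[1:] = (a - b / dt) * cp[1:] + (b / dt) * cp[:-1]
    return lfilter([1.0], [1.0, -E], d)


def cumtrapz_uniform(y: np.ndarray, dt: float) -> np.ndarray:
    out = np.empty_like(np.asarray(y, dtype=float))
    out[0] = 0.0
    np.cumsum((y[1:] + y[:-1]) * (dt / 2), out=out[1:])
    return out


def _delayed(cp: np.ndarray, dt: float, delay_s: float) -> np.ndarray:
    """cp(t - delay): positive delay shifts the curve later; zero before onset."""
    if delay_s == 0:
        return np.asarray(cp, dtype=float)
    n = len(cp)
    t = np.arange(n) * dt
    return np.interp(t - delay_s, t, cp, left=0.0, right=float(cp[-1]))


def model_tac_1tcm(params: KineticParams, cp: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Measured 1-TCM curve on the uniform grid carrying ``cp``.

    CT = K1 exp(-k2 t) (*) Cp(t - delay); measured = (1-vB) CT + vB Cb,
    with whole blood identified with plasma (Cb = Cp).
    """
    cpd = _delayed(cp, dt, params.delay_s)
    ct = (params.K1 / 60.0) * expconv(cpd, dt, params.k2 / 60.0)
    return (1 - params.vB) * ct + params.vB * cpd


def model_tac_2tcm_irr(params: KineticParams, cp: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Measured irreversible 2-TCM curve (k4 = 0).

    C_tissue = Ki * int_0^t Cp + K1*k2/(k2+k3) * exp(-(k2+k3)t) (*) Cp,
    the sum of trapped and free compartments.
    """
    if params.k4 != 0:
        raise ValidationError("irreversible model requires k4 = 0")
    cpd = _delayed(cp, dt, params.delay_s)
    kb = params.k2 + params.k3
    if kb == 0:
        ct = (params.K1 / 60.0) * cumtrapz_uniform(cpd, dt)  # pure integrator
    else:
        ki = params.K1 * params.k3 / kb
        free_coeff = params.K1 * params.k2 / kb
        ct = (ki / 60.0) * cumtrapz_uniform(cpd, dt) \
            + (free_coeff / 60.0) * expconv(cpd, dt, kb / 60.0)
    return (1 - params.vB) * ct + params.vB * cpd


def dual_input(ca: np.ndarray, dt: float, params: DualInputParams) -> np.ndarray:
    """Flow-weighted dual blood supply for the liver.

    The portal-venous component is the arterial curve dispersed through a
    unit-mass single-exponential kernel ka*exp(-ka t); the dual input is
    fa*Ca + (1-fa)*Cpv.
    """
    ka_s = params.ka / 60.0
    cpv = ka_s * expconv(np.asarray(ca, float), dt, ka_s)
    return params.fa * np.asarray(ca, float) + (1 - params.fa) * cpv


@dataclass
class FitOptions:
    """Controls for compartment-model fitting."""

    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "K1": (0.0, 5.0), "k2": (0.0, 5.0), "k3": (0.0, 5.0), "vB": (0.0, 0.5),
    })
    weights: Literal["uniform", "duration"] = "uniform"
    delay_grid_s: np.ndarray | None = None  # default -30..30 step 1
    fit_delay: bool = True
    multistart: int = 5
    seed: int = 0
    xtol: float = 1e-10

    def delay_grid(self) -> np.ndarray:
        if not self.fit_delay:
            return np.array([0.0])
        if self.delay_grid_s is None:
            return np.arange(-30.0, 31.0, 1.0)
        return np.asarray(self.delay_grid_s, dtype=float)


@dataclass
class FitResult:
    params: KineticParams
    macro_name: str  # "Ki" or "VT"
    macro: float
    objective: float
    converged: bool
    n_frames_used: int


def frame_average(curve: np.ndarray, dt: float, schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each frame interval (trapezoid)."""
    cum = cumtrapz_uniform(curve, dt)
    t = np.arange(len(curve)) * dt
    lo = np.interp(schedule.start_s, t, cum)
    hi = np.interp(schedule.end_s, t, cum)
    return (hi - lo) / schedule.duration_s


def _predict(model: str, x: np.ndarray, delay: float, cp: np.ndarray, dt: float,
             schedule: FrameSchedule | None, mid_s: np.ndarray) -> np.ndarray:
    if model == "2tcm_irr":
        p = KineticParams(K1=x[0], k2=x[1], k3=x[2], vB=x[3], delay_s=delay)
        curve = model_tac_2tcm_irr(p, cp, dt)
    else:
        p = KineticParams(K1=x[0], k2=x[1], vB=x[2], delay_s=delay)
        curve = model_tac_1tcm(p, cp, dt)
    if schedule is not None:
        return frame_average(curve, dt, schedule)
    t = np.arange(len(cp)) * dt
    return np.interp(mid_s, t, curve)


def fit_compartment(
    tac: TAC,
    cp: np.ndarray,
    model: Literal["1tcm", "2tcm_irr"],
    opts: FitOptions | None = None,
    schedule: FrameSchedule | None = None,
    dt: float = 1.0,
) -> FitResult:
    """Weighted NLLS fit of a compartment model to a measured TAC.

    ``cp`` is the blood input sampled on a uniform ``dt``-spaced grid
    starting at t = 0 and covering the scan.  The blood delay is resolved
    by grid search followed by parabolic refinement; micro-parameters are
    refined by bounded least squares with multistart.
    """
    if model not in ("1tcm", "2tcm_irr"):
        raise ValidationError(f"unknown model {model!r}")
    opts = opts or FitOptions()
    y = np.asarray(tac.mean, dtype=float)
    if len(y) < 6:
        raise ValidationError("need at least 6 frames to fit")
    if np.allclose(y, 0):
        raise ValidationError("TAC is identically zero")
    if opts.weights == "duration" and schedule is not None:
        w = np.sqrt(schedule.duration_s / schedule.duration_s.max())
    else:
        w = np.ones_like(y)

    names = ["K1", "k2", "k3", "vB"] if model == "2tcm_irr" else ["K1", "k2", "vB"]
    lo = np.array([opts.bounds[n][0] for n in names])
    hi = np.array([opts.bounds[n][1] for n in names])
    x0_default = np.array([{"K1": 0.5, "k2": 0.5, "k3": 0.05, "vB": 0.05}[n] for n in names])

    def solve(delay: float, x0: np.ndarray):
        res = least_squares(
            lambda x: w * (_predict(model, x, delay, cp, dt, schedule, tac.mid_s) - y),
            np.clip(x0, lo + 1e-9, hi - 1e-9), bounds=(lo, hi),
            xtol=opts.xtol, ftol=1e-12, gtol=1e-12, method="trf",
        )
        return res

    # -- delay grid search, warm-started along the grid
    grid = opts.delay_grid()
    best = None
    objs = np.empty(len(grid))
    x_prev = x0_default
    sols = []
    for i, d in enumerate(grid):
        r = solve(d, x_prev)
        objs[i] = r.cost
        sols.append(r)
        x_prev = r.x
        if best is None or r.cost < best[1]:
            best = (i, r.cost)
    i_best = best[0]
    delay = float(grid[i_best])
    x_best = sols[i_best].x

    # -- parabolic refinement of the delay on the objective samples
    if 0 < i_best < len(grid) - 1:
        f0, f1, f2 = objs[i_best - 1], objs[i_best], objs[i_best + 1]
        denom = f0 - 2 * f1 + f2
        if denom > 0:
            step = 0.5 * (f0 - f2) / denom
            d_ref = delay + step * (grid[i_best + 1] - grid[i_best])
            r = solve(d_ref, x_best)
            if r.cost < objs[i_best]:
                delay, x_best = float(d_ref), r.x

    # -- multistart at the chosen delay
    rng = np.random.default_rng(opts.seed)
    best_res = solve(delay, x_best)
    for _ in range(max(0, opts.multistart - 1)):
        x0 = lo + (hi - lo) * rng.uniform(0.05, 0.7, size=len(lo))
        r = solve(delay, x0)
        if r.cost < best_res.cost:
            best_res = r

    x = best_res.x
    if model == "2tcm_irr":
        params = KineticParams(K1=x[0], k2=x[1], k3=x[2], vB=x[3], delay_s=delay)
        macro_name, macro = "Ki", (params.ki if x[1] + x[2] > 0 else 0.0)
    else:
        params = KineticParams(K1=x[0], k2=x[1], vB=x[2], delay_s=delay)
        macro_name, macro = "VT", (params.vt if x[1] > 0 else np.inf)
    return FitResult(
        params=params, macro_name=macro_name, macro=float(macro),
        objective=float(2 * best_res.cost), converged=bool(best_res.success),
        n_frames_used=len(y),
    )
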