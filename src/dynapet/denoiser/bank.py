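"""Static-trained multi-count-level denoiser bank.

One denoising network is trained per count-reduction factor on pairs
built from a single static (late-uptake) frame: the full-count image is
the target and its binomially thinned version the input.  At inference a
dynamic frame is routed to the network whose training count level most
closely matches the frame's own total counts (log-scale nearest, ties to
the lower-count level), then denoised slice-by-slice along the
transverse, coronal, and sagittal views with per-slice mean
normalization, and the three per-view volumes are averaged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from ..frames import DynamicImage, ValidationError
from ..phantom import counts_to_image, expected_counts, spawn_seeds, thin_counts
from .autograd import Adam, mse
from .unet import AttentionUNet, NetConfig

__all__ = [
    "CountLevel",
    "TrainConfig",
    "LevelPairs",
    "DenoiserBank",
    "build_training_pairs",
    "train_bank",
    "match_level",
    "denoise_frame",
    "denoise_dynamic",
    "gaussian_denoise",
    "STANDARD_FACTORS",
]

#: The seven count-reduction factors of the static training protocol.
STANDARD_FACTORS: tuple[float, ...] = (1 / 2, 1 / 5, 1 / 10, 1 / 20, 1 / 60, 1 / 120, 1 / 300)


@dataclass(frozen=True)
class CountLevel:
    factor: float
    ref_total_counts: float

    def __post_init__(self) -> None:
        if not (0 < self.factor <= 1):
            raise ValidationError("factor must lie in (0, 1]")
        if self.ref_total_counts <= 0:
            raise ValidationError("ref_total_counts must be > 0")


@dataclass
class TrainConfig:
    """MSE + Adam training controls.

    The default learning rate is the full-scale protocol's 1e-5;
    :func:`demo_train_config` returns the desk-scale preset.
    """

    learning_rate: float = 1e-5
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0
    val_fraction: float = 0.1
    patience: int = 10

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValidationError("learning_rate must be > 0 and batch_size >= 1")


def demo_train_config(seed: int = 0, epochs: int = 25) -> TrainConfig:
    """Training preset for the small (~0.2 M parameter) configuration."""
    return TrainConfig(learning_rate=2e-3, batch_size=16, epochs=epochs,
                       seed=seed, patience=10)


@dataclass
class LevelPairs:
    """Paired, normalized slice windows for one count level."""

    factor: float
    ref_total_counts: float
    x: np.ndarray  # (N, 3, H, W) normalized noisy windows
    y: np.ndarray  # (N, 1, H, W) targets normalized by the input middle mean


@dataclass
class BankLevel:
    level: CountLevel
    net: AttentionUNet
    meta: dict = field(default_factory=dict)


@dataclass
class DenoiserBank:
    levels: list[BankLevel]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValidationError("bank must contain at least one level")
        self.levels.sort(key=lambda bl: -bl.level.factor)

    def __len__(self) -> int:
        return len(self.levels)

    # -- serialization: one npz of weights per level + a JSON manifest
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"levels": []}
        for i, bl in enumerate(self.levels):
            fname = f"level_{i}.npz"
            np.savez(directory / fname, **bl.net.state_dict())
            cfg = bl.net.config
            manifest["levels"].append({
                "file": fname,
                "factor": bl.level.factor,
                "ref_total_counts": bl.level.ref_total_counts,
                "net_config": {
                    "depth": cfg.depth, "base_channels": cfg.base_channels,
                    "conv_per_stage": cfg.conv_per_stage,
                    "attention_gates": cfg.attention_gates,
                    "residual": cfg.residual, "in_slices": cfg.in_slices,
                },
                "meta": {k: v for k, v in bl.meta.items()
                         if isinstance(v, (int, float, str, list))},
            })
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "DenoiserBank":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        levels = []
        for entry in manifest["levels"]:
            net = AttentionUNet(NetConfig(**entry["net_config"]))
            with np.load(directory / entry["file"]) as npz:
                net.load_state_dict(dict(npz))
            levels.append(BankLevel(
                CountLevel(entry["factor"], entry["ref_total_counts"]),
                net, entry.get("meta", {}),
            ))
        return cls(levels)


# ---------------------------------------------------------------------------
# training-pair construction


def _pad_hw(arr: np.ndarray, mult: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Edge-pad the trailing two axes up to multiples of ``mult``."""
    h, w = arr.shape[-2:]
    ph = (-h) % mult
    pw = (-w) % mult
    if ph or pw:
        pad = [(0, 0)] * (arr.ndim - 2) + [(0, ph), (0, pw)]
        arr = np.pad(arr, pad, mode="edge")
    return arr, (h, w)


def _view_windows(vol: np.ndarray, view: int, mult: int):
    """3-slice windows along one view, each channel mean-normalized.

    Returns (windows (S,3,H,W), target-normalization means (S,), crop).
    Edge slices replicate the boundary slice to fill the window.
    """
    v = np.moveaxis(vol, view, 0)
    v, crop = _pad_hw(v, mult)
    S = v.shape[0]
    idx = np.arange(S)
    lo = np.clip(idx - 1, 0, S - 1)
    hi = np.clip(idx + 1, 0, S - 1)
    win = np.stack([v[lo], v, v[hi]], axis=1)  # (S, 3, H, W)
    means = win.mean(axis=(2, 3))  # (S, 3) per-channel slice means
    scale = np.where(means > 0, means, 1.0)
    win = win / scale[:, :, None, None]
    return win, scale[:, 1], crop


def build_training_pairs(
    static_img: DynamicImage,
    factors,
    seed: int,
    net_min_size: int = 8,
    n_realizations: int = 1,
) -> list[LevelPairs]:
    """Per-level (thinned input, full-count target) slice datasets.

    ``static_img`` must hold a single frame (the late-uptake static
    acquisition).  For each reduction factor the frame's counts are
    binomially thinned, both volumes are resorted into transverse,
    coronal, and sagittal slice sequences, and 3-slice windows are formed
    with edge replication.  Each input slice is normalized by its own
    mean; the target slice is normalized by the input middle-slice mean
    so the residual connection sees consistent scales.  ``n_realizations``
    draws that many independent thinnings per factor to enlarge the
    dataset (the default keeps one, i.e. 3 orientations x slices pairs).
    """
    factors = list(factors)
    if not factors:
        raise ValidationError("factor list is empty")
    if static_img.schedule.n_frames != 1:
        raise ValidationError("training requires a single-frame static image")
    counts = expected_counts(static_img)[..., 0]
    target_vol = static_img.voxels[..., 0]
    out: list[LevelPairs] = []
    for factor, s in zip(factors, spawn_seeds(seed, len(factors))):
        if not (0 < factor < 1):
            raise ValidationError("training factors must lie in (0, 1)")
        xs, ys = [], []
        ref_counts = None
        for rs in spawn_seeds(s, n_realizations):
            thinned = thin_counts(counts, factor, rs)
            if ref_counts is None:
                ref_counts = float(thinned.sum())
            noisy_img = counts_to_image(
                thinned[..., None], static_img, static_img.calibration.scaled(factor))
            noisy_vol = noisy_img.voxels[..., 0]
            for view in range(3):
                win, mid_means, _ = _view_windows(noisy_vol, view, net_min_size)
                tgt = np.moveaxis(target_vol, view, 0)
                tgt, _ = _pad_hw(tgt, net_min_size)
                # zero-mean slices pass through at inference; skip in training
                keep = np.moveaxis(noisy_vol, view, 0).mean(axis=(1, 2)) > 0
                xs.append(win[keep])
                ys.append((tgt[keep] / mid_means[keep, None, None])[:, None])
        out.append(LevelPairs(
            factor=float(factor),
            ref_total_counts=ref_counts,
            x=np.concatenate(xs, axis=0),
            y=np.concatenate(ys, axis=0),
        ))
    return out


# ---------------------------------------------------------------------------
# training


def _train_one(pairs: LevelPairs, net_cfg: NetConfig, cfg: TrainConfig,
               seed: int) -> BankLevel:
    rng = np.random.default_rng(seed)
    net = AttentionUNet(net_cfg, seed=seed)
    n = pairs.x.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n))) if n > 1 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if train_idx.size == 0:
        train_idx = perm
    opt = Adam(net.params(), lr=cfg.learning_rate)
    history: list[float] = []
    val_history: list[float] = []
    best_val = np.inf
    best_state = net.state_dict()
    best_state = {k: v.copy() for k, v in best_state.items()}
    bad_epochs = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            opt.zero_grad()
            loss = mse(net.forward(pairs.x[idx], training=True), pairs.y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at factor 1/{round(1/pairs.factor)} "
                    f"(epoch {epoch}): non-finite loss")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))
        if val_idx.size:
            val_loss = float(mse(net.forward(pairs.x[val_idx], training=False),
                                 pairs.y[val_idx]).data)
        else:
            val_loss = history[-1]
        val_history.append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in net.state_dict().items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    net.load_state_dict(best_state)
    return BankLevel(
        CountLevel(pairs.factor, pairs.ref_total_counts),
        net,
        meta={"loss_history": history, "val_history": val_history,
              "n_pairs": int(n), "seed": int(seed),
              "n_parameters": net.n_parameters},
    )


def train_bank(pairs: list[LevelPairs], net_cfg: NetConfig | None = None,
               train_cfg: TrainConfig | None = None) -> DenoiserBank:
    """Train one network per count level; deterministic given the seed."""
    net_cfg = net_cfg or NetConfig()
    train_cfg = train_cfg or TrainConfig()
    if not pairs:
        raise ValidationError("no training pairs supplied")
    seeds = spawn_seeds(train_cfg.seed, len(pairs))
    return DenoiserBank([
        _train_one(p, net_cfg, train_cfg, s) for p, s in zip(pairs, seeds)
    ])


# ---------------------------------------------------------------------------
# inference


def match_level(total_counts: float, bank: DenoiserBank) -> BankLevel:
    """Level whose reference total counts are log-nearest to the frame's.

    Ties go to the lower-count level; zero-count frames route to the
    lowest-count level with a warning.  Frames outside the trained range
    clamp to the nearest end of the ladder.
    """
    ordered = sorted(bank.levels, key=lambda bl: bl.level.ref_total_counts)
    if total_counts <= 0:
        warnings.warn("zero-count frame: routing to the lowest-count level")
        return ordered[0]
    best = ordered[0]
    best_d = abs(np.log(total_counts) - np.log(best.level.ref_total_counts))
    for bl in ordered[1:]:
        d = abs(np.log(total_counts) - np.log(bl.level.ref_total_counts))
        if d < best_d - 1e-12:  # strict: ties stay with the lower-count level
            best, best_d = bl, d
    return best


def _denoise_volume(vol: np.ndarray, net: AttentionUNet) -> np.ndarray:
    """Three-view sliding-window inference with per-slice normalization."""
    mult = net.config.min_size
    acc = np.zeros_like(vol, dtype=float)
    for view in range(3):
        win, mid_means, (h, w) = _view_windows(vol, view, mult)
        pred = net.predict(win)  # (S, Hp, Wp)
        pred = pred[:, :h, :w] * mid_means[:, None, None]
        src = np.moveaxis(vol, view, 0)
        zero = src.mean(axis=(1, 2)) <= 0
        pred[zero] = src[zero]  # zero-mean slices pass through unchanged
        acc += np.moveaxis(pred, 0, view)
    return acc / 3.0


def denoise_frame(
    frame: np.ndarray,
    bank: DenoiserBank,
    level_override: BankLevel | None = None,
    total_counts: float | None = None,
) -> np.ndarray:
    """Denoise one 3D frame with the count-matched (or overridden) network."""
    frame = np.asarray(frame, dtype=float)
    if min(frame.shape) < 2:
        raise ValidationError("frame spatial dims too small for the network")
    if level_override is not None:
        bl = level_override
    else:
        if total_counts is None:
            raise ValidationError("need total_counts to match a level (or an override)")
        bl = match_level(total_counts, bank)
    return _denoise_volume(frame, bl.net)


def denoise_dynamic(
    img: DynamicImage,
    bank: DenoiserBank,
    level_override: BankLevel | None = None,
) -> tuple[DynamicImage, list[float]]:
    """Frame-by-frame denoising; returns the image and per-frame factors."""
    counts = expected_counts(img)
    out = np.empty_like(img.voxels)
    chosen: list[float] = []
    for f in range(img.schedule.n_frames):
        total = float(counts[..., f].sum())
        bl = level_override or match_level(total, bank)
        chosen.append(bl.level.factor)
        out[..., f] = _denoise_volume(img.voxels[..., f], bl.net)
    return (
        DynamicImage(out, img.voxel_size_mm, img.schedule, img.calibration),
        chosen,
    )


def demo_bank(
    factors=STANDARD_FACTORS,
    seed: int = 0,
    size: str = "small",
    epochs: int = 30,
    n_realizations: int = 2,
) -> tuple[DenoiserBank, DynamicImage, DynamicImage]:
    """Train the desk-scale bank on the phantom's static late frame.

    Simulates the 10-min late-uptake static acquisition of the default
    phantom, Poisson-samples it at full dose, builds thinned training
    pairs at ``factors`` (default: the seven-level ladder, whose
    reference count levels span the dynamic frames' statistics), and
    trains one small network per level.
    Returns (bank, noisy static image, clean static image).
    """
    from ..frames import FrameSchedule
    from ..phantom import add_poisson_noise, default_phantom, feng_if, render_dynamic

    phantom, ifp, _ = default_phantom(size)
    cp = feng_if(ifp, np.arange(0.0, 3601.0))
    static_sched = FrameSchedule(((3000.0, 3600.0),))
    clean_static = render_dynamic(phantom, cp, static_sched)
    s_noise, s_pairs, s_train = spawn_seeds(seed, 3)
    noisy_static = add_poisson_noise(clean_static, s_noise)
    cfg = NetConfig()
    pairs = build_training_pairs(noisy_static, factors, s_pairs,
                                 net_min_size=cfg.min_size,
                                 n_realizations=n_realizations)
    bank = train_bank(pairs, cfg, demo_train_config(seed=s_train, epochs=epochs))
    return bank, noisy_static, clean_static


def gaussian_denoise(frame: np.ndarray, fwhm_mm: float,
                     voxel_size_mm=(4.0, 4.0, 4.0)) -> np.ndarray:
    """Classical comparator: isotropic Gaussian smoothing (fwhm 0 = identity)."""
    if fwhm_mm < 0:
        raise ValidationError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return np.asarray(frame, dtype=float).copy()
    sigma = [fwhm_mm / 2.354820045 / v for v in voxel_size_mm]
    return gaussian_filter(np.asarray(frame, dtype=float), sigma=sigma)
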