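"""Losses, the optimization schedule, and full-volume inference.

Training minimizes an equally weighted combination of soft Dice and binary
cross entropy::

    DSC  = 2 sum(p g) / (sum(p^2) + sum(g^2))
    BCE  = -(1/N) sum[g log p + (1-g) log(1-p)]
    L    = 0.5 BCE + 0.5 (1 - DSC)

For the st4d variant a deep-supervision loss on the middle arm's output is
mixed with the final-layer loss at a 30:70 ratio by default.  Optimization
uses Adam with validation-loss-driven learning-rate reduction (factor 0.1
after 8 non-improving epochs) and early stopping (after 20), restoring the
best-validation weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Volume4D
from .models import ST3D, ST4D, _SpatialUNet
from .nn import Adam
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .preprocess import plan_volume_patch_origins, tmip

__all__ = [
    "TrainConfig",
    "soft_dice",
    "bce",
    "combined_loss",
    "st4d_loss",
    "train",
    "predict_volume",
]

DICE_EPS = 1e-6
BCE_EPS = 1e-7


def _check_pair(p, g) -> None:
    pshape = p.shape if hasattr(p, "shape") else np.shape(p)
    if tuple(pshape) != tuple(np.shape(g)):
        raise ValueError(f"prediction and ground truth shapes differ: {pshape} vs {np.shape(g)}")


def soft_dice(p, g, eps: float = DICE_EPS):
    """Squared-denominator soft Dice score in [0, 1].

    Accepts an autodiff :class:`Tensor` (returns a Tensor, differentiable)
    or plain arrays (returns a float).
    """
    _check_pair(p, g)
    if isinstance(p, Tensor):
        gt = ad.tensor(np.asarray(g, dtype=np.float32))
        num = 2.0 * ad.tsum(p * gt) + eps
        den = ad.tsum(p * p) + ad.tsum(gt * gt) + eps
        return num / den
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    return float((2.0 * (p * g).sum() + eps) / ((p * p).sum() + (g * g).sum() + eps))


def bce(p, g, eps: float = BCE_EPS):
    """Mean binary cross entropy with probability clipping."""
    _check_pair(p, g)
    if isinstance(p, Tensor):
        n = float(np.prod(p.shape))
        gt = ad.tensor(np.asarray(g, dtype=np.float32))
        pc = ad.clip(p, eps, 1.0 - eps)
        return (-1.0 / n) * ad.tsum(gt * ad.log(pc) + (1.0 - gt) * ad.log(1.0 - pc))
    p = np.clip(np.asarray(p, dtype=np.float64), eps, 1.0 - eps)
    g = np.asarray(g, dtype=np.float64)
    return float(-(g * np.log(p) + (1 - g) * np.log(1 - p)).mean())


def combined_loss(p, g):
    """0.5 * BCE + 0.5 * (1 - DSC): the training loss of every network variant."""
    d = soft_dice(p, g)
    b = bce(p, g)
    if isinstance(p, Tensor):
        return 0.5 * b + 0.5 * (1.0 - d)
    return 0.5 * b + 0.5 * (1.0 - d)


def st4d_loss(center_pair, final_pair, weights: tuple[float, float] = (0.3, 0.7)):
    """Deep-supervision mix: w_center * L(center) + w_final * L(final)."""
    w_center, w_final = weights
    if w_center < 0 or w_final < 0 or abs(w_center + w_final - 1.0) > 1e-9:
        raise ValueError("deep-supervision weights must be non-negative and sum to 1")
    lc = combined_loss(*center_pair)
    lf = combined_loss(*final_pair)
    return w_center * lc + w_final * lf


@dataclass
class TrainConfig:
    lr: float = 5e-4
    batch_size: int = 2
    max_epochs: int = 100
    early_stop_patience: int = 20
    lr_patience: int = 8
    lr_factor: float = 0.1
    ds_weights: tuple[float, float] = (0.3, 0.7)
    seed: int = 0
    min_improvement: float = 1e-5
    verbose: bool = False


def _batch_inputs(patches: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Stack patches and add the channel axis: (B, 1, *patch_dims)."""
    return np.ascontiguousarray(patches[idx][:, None], dtype=np.float32)


def _forward_loss(model, xb: np.ndarray, gb: np.ndarray, config: TrainConfig, train: bool):
    x = Tensor(xb)
    g = gb[:, None]  # (B, 1, X, Y)
    if isinstance(model, ST4D):
        main, deep = model(x)
        loss = st4d_loss((deep, g), (main, g), config.ds_weights)
    else:
        out = model(x)
        loss = combined_loss(out, g)
    return loss


def train(
    model,
    train_patches: np.ndarray,
    train_masks: np.ndarray,
    val_patches: np.ndarray,
    val_masks: np.ndarray,
    config: TrainConfig | None = None,
) -> dict:
    """Optimize a model on patch arrays; returns the training history.

    ``train_patches``/``val_patches`` are stacked model inputs without the
    channel axis (e.g. ``(P, X, Y, T)`` for st3d, ``(P, X, Y, 3, T)`` for
    st4d); masks are the matching 2D (or 3D for the spatial U-Nets) binary
    ground truths.  Fully seeded: identical configs reproduce identical
    histories.  The best-validation weights are restored at the end.
    """
    config = config or TrainConfig()
    if len(train_patches) == 0 or len(val_patches) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    history: dict = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_state = model.state_dict()
    stale = 0
    lr_stale = 0

    train_patches = np.asarray(train_patches, dtype=np.float32)
    val_patches = np.asarray(val_patches, dtype=np.float32)
    train_masks = np.asarray(train_masks, dtype=np.float32)
    val_masks = np.asarray(val_masks, dtype=np.float32)

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_patches))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = _batch_inputs(train_patches, idx)
            loss = _forward_loss(model, xb, train_masks[idx], config, train=True)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        val_losses = []
        with ad.no_grad():
            for start in range(0, len(val_patches), max(config.batch_size, 4)):
                idx = np.arange(start, min(start + max(config.batch_size, 4), len(val_patches)))
                xb = _batch_inputs(val_patches, idx)
                loss = _forward_loss(model, xb, val_masks[idx], config, train=False)
                val_losses.append(loss.item())
        tr, vl = float(np.mean(losses)), float(np.mean(val_losses))
        history["train_loss"].append(tr)
        history["val_loss"].append(vl)
        history["lr"].append(opt.lr)
        if config.verbose:
            print(f"epoch {epoch:3d}  train {tr:.4f}  val {vl:.4f}  lr {opt.lr:.1e}")

        if vl < best_val - config.min_improvement:
            best_val = vl
            best_state = model.state_dict()
            stale = 0
            lr_stale = 0
        else:
            stale += 1
            lr_stale += 1
            if lr_stale >= config.lr_patience:
                opt.lr *= config.lr_factor
                lr_stale = 0
            if stale >= config.early_stop_patience:
                break

    model.load_state_dict(best_state)
    history["best_val_loss"] = best_val
    history["epochs_run"] = len(history["train_loss"])
    return history


def _predict_batched(model, inputs: list[np.ndarray], batch_size: int = 4) -> list[np.ndarray]:
    outs: list[np.ndarray] = []
    with ad.no_grad():
        for start in range(0, len(inputs), batch_size):
            xb = np.stack(inputs[start : start + batch_size])[:, None].astype(np.float32)
            y = model(xb)
            if isinstance(y, tuple):
                y = y[0]
            outs.extend(y.data[:, 0])
    return outs


def predict_volume(
    model,
    volume: Volume4D,
    patch_dims: tuple[int, int, int] = (64, 64, 8),
    threshold: float = 0.5,
    batch_size: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Segment a preprocessed 4D volume and restitch to full resolution.

    Tiling follows the model family: per-slice for the 2D and st3d models,
    replicate-padded 3-slice windows for st4d (one output slice per input
    slice), and non-overlapping volumetric blocks for the 3D U-Net.  Returns
    ``(probabilities, mask)`` with the mask thresholded at ``threshold``.
    """
    data = np.asarray(volume.data, dtype=np.float32)
    x_, y_, z_, t_ = data.shape
    prob = np.zeros((x_, y_, z_), dtype=np.float32)

    if isinstance(model, ST4D):
        windows = []
        for z in range(z_):
            zm, zp = max(z - 1, 0), min(z + 1, z_ - 1)
            windows.append(np.stack([data[:, :, zm], data[:, :, z], data[:, :, zp]], axis=2))
        for z, out in enumerate(_predict_batched(model, windows, batch_size)):
            prob[:, :, z] = out
    elif isinstance(model, ST3D):
        slices = [data[:, :, z, :] for z in range(z_)]
        for z, out in enumerate(_predict_batched(model, slices, batch_size)):
            prob[:, :, z] = out
    elif isinstance(model, _SpatialUNet) and model.ndim == 2:
        proj = tmip(volume)
        slices = [proj[:, :, z] for z in range(z_)]
        for z, out in enumerate(_predict_batched(model, slices, batch_size)):
            prob[:, :, z] = out
    elif isinstance(model, _SpatialUNet) and model.ndim == 3:
        proj = tmip(volume)
        if any(s % p for s, p in zip(proj.shape, patch_dims)):
            raise ValueError(
                f"volume dims {proj.shape} not tileable by non-overlapping patches {patch_dims}"
            )
        origins = plan_volume_patch_origins(proj.shape, patch_dims, patch_dims)
        blocks = [proj[tuple(slice(o, o + p) for o, p in zip(org, patch_dims))] for org in origins]
        outs = _predict_batched(model, blocks, batch_size)
        for org, out in zip(origins, outs):
            prob[tuple(slice(o, o + p) for o, p in zip(org, patch_dims))] = out
    else:
        raise TypeError(f"cannot tile predictions for model type {type(model).__name__}")

    return prob, (prob >= threshold).astype(np.uint8)
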