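"""End-to-end orchestration: simulate -> ground truth -> prepare -> train ->
predict -> evaluate, with every stage seeded and logged to the artifact
directory alongside the fully resolved configuration."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import groundtruth, phantom, preprocess
from .core import SignalParams, Volume4D
from .evaluation import evaluate_subject, summarize_cohort
from .models import ArchConfig, build_model
from .training import TrainConfig, predict_volume, train

__all__ = ["run_pipeline", "default_config", "background_roi_for", "prepare_subject"]


def default_config() -> dict:
    return {
        "n_subjects": 6,
        "dims": [64, 64, 16],
        "n_frames": 24,
        "seed": 0,
        "model": "st3d",
        "refinement": "resdense",
        "base_channels": 8,
        "ds_weights": [0.3, 0.7],
        "lr": 5e-4,
        "batch_size": 2,
        "max_epochs": 10,
        "tolerance": 1,
        "level_k": 3.0,
        "test_fraction": 0.2,
        "out_dir": "artifacts",
    }


def background_roi_for(mask: np.ndarray, margin: int = 1) -> np.ndarray:
    """A corner background ROI guaranteed disjoint from the vasculature."""
    roi = np.zeros_like(mask, dtype=bool)
    size = max(4, mask.shape[0] // 8)
    roi[:size, :size, :] = True
    roi &= ~mask.astype(bool)
    return roi


def prepare_subject(volume: Volume4D, smooth_window: int = 3) -> Volume4D:
    """Training-time preparation: temporal smoothing then global z-score."""
    return preprocess.zscore_normalize(preprocess.temporal_moving_average(volume, smooth_window))


def _patches_for_model(variant: str, prepared: dict[str, Volume4D], masks: dict[str, np.ndarray]):
    """Assemble (inputs, targets) patch arrays for one model variant."""
    if variant == "st3d":
        vols = {sid: v.data for sid, v in prepared.items()}
        ps = preprocess.extract_xy_slices(vols)
        x = np.stack(ps.patches)
        y = np.stack([masks[sid][:, :, z] for sid, z in ps.sources])
    elif variant == "st4d":
        vols = {sid: v.data for sid, v in prepared.items()}
        ps = preprocess.extract_3slice_windows(vols, mode="train")
        x = np.stack(ps.patches)
        y = np.stack([masks[sid][:, :, z] for sid, z in ps.sources])
    elif variant == "unet2d":
        vols = {sid: preprocess.tmip(v) for sid, v in prepared.items()}
        ps = preprocess.extract_xy_slices(vols)
        x = np.stack(ps.patches)
        y = np.stack([masks[sid][:, :, z] for sid, z in ps.sources])
    elif variant == "unet3d":
        vols = {sid: preprocess.tmip(v) for sid, v in prepared.items()}
        dims = next(iter(vols.values())).shape
        patch = (min(64, dims[0]), min(64, dims[1]), min(8, dims[2]))
        ps = preprocess.extract_volume_patches(vols, patch, patch)
        x = np.stack(ps.patches)
        y = np.stack(
            [
                masks[sid][ox : ox + patch[0], oy : oy + patch[1], oz : oz + patch[2]]
                for sid, ox, oy, oz in ps.sources
            ]
        )
    else:
        raise ValueError(f"unknown model variant {variant!r}")
    return x.astype(np.float32), y.astype(np.float32)


def run_pipeline(config: dict) -> Path:
    """Run the full workflow; returns the artifact directory."""
    cfg = default_config()
    cfg.update(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(cfg, indent=2))
    seed = int(cfg["seed"])

    params = SignalParams(n_frames=int(cfg["n_frames"]))
    cohort = phantom.make_cohort(
        int(cfg["n_subjects"]), tuple(cfg["dims"]), params, seed=seed
    )

    # ground truth via level crossings on the smoothed signal
    gt_masks: dict[str, np.ndarray] = {}
    for sub in cohort:
        roi = background_roi_for(sub.truth_mask)
        level = groundtruth.auto_level(sub.volume, roi, k=cfg["level_k"], floor=1e-6)
        smoothed = preprocess.temporal_moving_average(sub.volume, 3)
        gt_masks[sub.subject_id] = groundtruth.lcc_mask(smoothed, level)

    split = preprocess.split_cohort(
        [s.subject_id for s in cohort], seed=seed, test_fraction=cfg["test_fraction"]
    )
    (out / "split.json").write_text(json.dumps(split.to_dict(), indent=2))

    prepared = {s.subject_id: prepare_subject(s.volume) for s in cohort}
    train_prepared = {sid: prepared[sid] for sid in split.train_subjects}
    x, y = _patches_for_model(cfg["model"], train_prepared, gt_masks)
    tr_idx, val_idx = split.assign_patches(len(x))

    arch = ArchConfig(
        variant=cfg["model"],
        base_channels=int(cfg["base_channels"]),
        refinement=cfg["refinement"],
        n_frames=int(cfg["n_frames"]),
        seed=seed,
    )
    model = build_model(arch)
    tcfg = TrainConfig(
        lr=float(cfg["lr"]),
        batch_size=int(cfg["batch_size"]),
        max_epochs=int(cfg["max_epochs"]),
        ds_weights=tuple(cfg["ds_weights"]),
        seed=seed,
    )
    history = train(model, x[tr_idx], y[tr_idx], x[val_idx], y[val_idx], tcfg)
    (out / "history.json").write_text(json.dumps(history, indent=2))

    from .models import save_weights

    save_weights(model, out / "weights.npz")

    reports = []
    by_id = {s.subject_id: s for s in cohort}
    for sid in split.test_subjects:
        sub = by_id[sid]
        prob, pred = predict_volume(model, prepared[sid])
        roi = background_roi_for(sub.truth_mask)
        reports.append(
            evaluate_subject(
                pred,
                gt_masks[sid],
                sub.volume,
                roi,
                subject_id=sid,
                tolerance=int(cfg["tolerance"]),
            )
        )
    table = summarize_cohort(reports)
    table.to_csv(out / "metrics.csv")
    table.to_json(out / "metrics.json", orient="index")
    return out
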