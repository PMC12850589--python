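"""NIfTI round-tripping and run configuration.

Volumes are stored as NIfTI-1 with the voxel spacing on the affine diagonal;
the frame duration (ms) and simulation parameters travel in a JSON sidecar
next to the image (NIfTI-1 temporal-unit headers are unreliable across
tools).  Coordinate convention: 0-based voxel indices, axis order X, Y, Z, T.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import DEFAULT_FRAME_DURATION, LabeledSubject, SignalParams, Volume4D

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_subject",
    "read_subject",
    "load_config",
]


class VolumeIOError(RuntimeError):
    pass


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(volume: Volume4D, path) -> None:
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), affine)
    img.header.set_zooms(tuple(volume.spacing) + (volume.frame_duration,))
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps({"frame_duration_ms": volume.frame_duration}))


def read_volume(path) -> Volume4D:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for non-NIfTI input
        raise VolumeIOError(f"not a readable NIfTI file: {path}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise VolumeIOError(f"{path}: expected a 4D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    frame_duration = DEFAULT_FRAME_DURATION
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        frame_duration = float(json.loads(sidecar.read_text())["frame_duration_ms"])
    elif len(img.header.get_zooms()) > 3 and img.header.get_zooms()[3] > 0:
        frame_duration = float(img.header.get_zooms()[3])
    return Volume4D(data=data, spacing=spacing, frame_duration=frame_duration)


def write_mask(mask: np.ndarray, path, spacing=(1.0, 1.0, 1.5)) -> None:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise VolumeIOError("mask values must be 0/1")
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    data = np.asanyarray(nib.load(str(path)).dataobj)
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D mask, got shape {data.shape}")
    if not np.isin(data, (0, 1)).all():
        raise VolumeIOError(f"{path}: mask values outside {{0,1}}")
    return data.astype(np.uint8)


def write_subject(subject: LabeledSubject, out_dir) -> None:
    """One synthetic participant as NIfTI volume + mask + ATT map + JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = subject.subject_id
    write_volume(subject.volume, out / f"{sid}_4d.nii.gz")
    write_mask(subject.truth_mask, out / f"{sid}_mask.nii.gz", subject.volume.spacing)
    affine = np.diag(list(subject.volume.spacing) + [1.0])
    nib.save(
        nib.Nifti1Image(subject.truth_att.astype(np.float32), affine),
        str(out / f"{sid}_att.nii.gz"),
    )
    meta = {
        "subject_id": sid,
        "seed": subject.seed,
        "params": dataclasses.asdict(subject.params),
        "frame_duration_ms": subject.volume.frame_duration,
        "spacing_mm": list(subject.volume.spacing),
    }
    (out / f"{sid}_meta.json").write_text(json.dumps(meta, indent=2))


def read_subject(out_dir, subject_id: str) -> LabeledSubject:
    out = Path(out_dir)
    meta = json.loads((out / f"{subject_id}_meta.json").read_text())
    volume = read_volume(out / f"{subject_id}_4d.nii.gz")
    mask = read_mask(out / f"{subject_id}_mask.nii.gz")
    att = np.asanyarray(nib.load(str(out / f"{subject_id}_att.nii.gz")).dataobj).astype(float)
    att = np.where(mask.astype(bool), att, np.nan)
    return LabeledSubject(
        volume=volume,
        truth_mask=mask,
        truth_att=att,
        params=SignalParams(**meta["params"]),
        seed=meta["seed"],
        subject_id=subject_id,
    )


KNOWN_CONFIG_KEYS = {
    "n_subjects",
    "dims",
    "n_frames",
    "seed",
    "model",
    "refinement",
    "base_channels",
    "ds_weights",
    "lr",
    "batch_size",
    "max_epochs",
    "tolerance",
    "level_k",
    "test_fraction",
    "out_dir",
}


def load_config(path) -> dict:
    """Declarative run configuration (YAML); unknown keys are rejected."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg
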