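"""Data preparation: smoothing, cropping, normalization, patch layouts, splits.

The networks consume one of four patch layouts, all planned here with exact,
brute-force-checkable origin arithmetic:

* ``XY`` — full axial slices of the temporal maximum intensity projection
  (one patch per slice per subject);
* ``XYT`` — full axial slices with the time axis kept;
* ``XYZT3`` — sliding windows of three adjacent ``XYT`` slices (stride one
  slice over the cohort-concatenated slice sequence for training, or
  per-volume with edge replication for inference, so every slice receives
  exactly one prediction);
* ``XYZ`` — volumetric patches on a regular stride grid, optionally paired
  with concentric context patches that must also fit inside the volume.

Temporal utilities cover the external-validation paths: zero-padding short
acquisitions, pairwise averaging of high-rate reconstructions, and linear
up-sampling of low-rate ones.  Radial-acquisition arithmetic (spokes per
frame x repetition time = frame duration) lives here too.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core import Volume4D

__all__ = [
    "PatchSet",
    "SplitPlan",
    "temporal_moving_average",
    "crop_volume",
    "zscore_normalize",
    "tmip",
    "plan_axis_origins",
    "plan_volume_patch_origins",
    "extract_xy_slices",
    "extract_3slice_windows",
    "extract_volume_patches",
    "stitch_volume_patches",
    "split_cohort",
    "temporal_resample",
    "frames_from_spokes",
]

LAYOUTS = ("XY", "XYT", "XYZT3", "XYZ", "XYZ_with_context")


@dataclass
class PatchSet:
    """A collection of same-shaped patches with source records for restitching."""

    layout: str
    patches: list[np.ndarray]
    sources: list[tuple]  # (subject_id, origin...) per patch
    patch_dims: tuple
    stride: tuple | None = None
    context_patches: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}; expected one of {LAYOUTS}")
        if len(self.patches) != len(self.sources):
            raise ValueError("patches and sources must align one-to-one")
        for p in self.patches:
            if tuple(p.shape) != tuple(self.patch_dims):
                raise ValueError("all patches must share patch_dims")

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class SplitPlan:
    """Subject-level test holdout plus a seeded patch-level train/val split."""

    train_subjects: list[str]
    test_subjects: list[str]
    seed: int = 0
    val_fraction: float = 0.25  # 3:1 train:val at the patch level

    def __post_init__(self) -> None:
        overlap = set(self.train_subjects) & set(self.test_subjects)
        if overlap:
            raise ValueError(f"subjects leak between train and test: {sorted(overlap)}")

    def assign_patches(self, n_patches: int) -> tuple[np.ndarray, np.ndarray]:
        """Seeded 3:1 split of patch indices into (train, validation)."""
        rng = np.random.default_rng(self.seed + 1)
        order = rng.permutation(n_patches)
        n_val = int(round(n_patches * self.val_fraction))
        return np.sort(order[n_val:]), np.sort(order[:n_val])

    def to_dict(self) -> dict:
        return {
            "train_subjects": list(self.train_subjects),
            "test_subjects": list(self.test_subjects),
            "seed": self.seed,
            "val_fraction": self.val_fraction,
        }


def temporal_moving_average(volume: Volume4D, window: int = 3) -> Volume4D:
    """Centered temporal moving average; the window truncates at the boundaries."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return volume.with_data(volume.data.copy())
    data = np.asarray(volume.data, dtype=np.float64)
    kernel = np.ones(window)
    summed = np.apply_along_axis(lambda s: np.convolve(s, kernel, mode="same"), -1, data)
    counts = np.convolve(np.ones(data.shape[-1]), kernel, mode="same")
    out = (summed / counts).astype(volume.data.dtype if np.issubdtype(volume.data.dtype, np.floating) else np.float32)
    return volume.with_data(out)


def crop_volume(volume: Volume4D, target: tuple[int, int, int, int]) -> Volume4D:
    """Center crop in X, Y, Z and keep the leading ``target[3]`` frames."""
    src = volume.shape
    if any(t > s for t, s in zip(target, src)):
        raise ValueError(f"crop target {target} exceeds source dims {src}")
    if target[0] % 8 or target[1] % 8:
        raise ValueError("target X and Y must be divisible by 8 (three 2x down-samplings)")
    off = [(s - t) // 2 for s, t in zip(src[:3], target[:3])]
    sl = tuple(slice(o, o + t) for o, t in zip(off, target[:3])) + (slice(0, target[3]),)
    return volume.with_data(volume.data[sl].copy())


def zscore_normalize(volume: Volume4D, subject_id: str = "subject") -> Volume4D:
    """Z-score over all voxels and frames of the subject (global mean 0, std 1)."""
    data = np.asarray(volume.data, dtype=np.float64)
    std = data.std()
    if std == 0:
        raise ValueError(f"{subject_id}: constant volume cannot be z-score normalized")
    return volume.with_data(((data - data.mean()) / std).astype(np.float32))


def tmip(volume: Volume4D) -> np.ndarray:
    """Temporal maximum intensity projection: voxelwise max over T."""
    return np.max(volume.data, axis=-1)


def plan_axis_origins(size: int, patch: int, stride: int, context: int | None = None) -> list[int]:
    """Valid patch origins along one axis.

    With a concentric context of extent ``context >= patch``, an origin is
    valid only if the context patch also fits:
    ``origin - margin >= 0`` and ``origin + patch + margin <= size`` with
    ``margin = (context - patch) // 2``.
    """
    if patch > size:
        return []
    margin = 0
    if context is not None:
        if context < patch:
            raise ValueError("context extent must be >= patch extent")
        margin = (context - patch) // 2
    first = margin
    last = size - patch - margin
    if last < first:
        return []
    return list(range(first, last + 1, stride))


def plan_volume_patch_origins(
    vol_dims: tuple[int, int, int],
    patch_dims: tuple[int, int, int],
    stride: tuple[int, int, int],
    context_dims: tuple[int, int, int] | None = None,
) -> list[tuple[int, int, int]]:
    """Grid of top-left origins for volumetric patches (optionally context-constrained)."""
    per_axis = [
        plan_axis_origins(
            vol_dims[ax], patch_dims[ax], stride[ax], None if context_dims is None else context_dims[ax]
        )
        for ax in range(3)
    ]
    return list(itertools.product(*per_axis))


def extract_xy_slices(volumes: dict[str, np.ndarray]) -> PatchSet:
    """One patch per axial slice per subject.

    3D inputs ``(X, Y, Z)`` (e.g. tMIPs) yield ``XY`` patches; 4D inputs
    ``(X, Y, Z, T)`` yield ``XYT`` patches with the time axis kept.  Sources
    are recorded as ``(subject_id, z)``.
    """
    patches: list[np.ndarray] = []
    sources: list[tuple] = []
    layout = None
    for sid, arr in volumes.items():
        arr = np.asarray(arr)
        if arr.ndim == 3:
            this_layout = "XY"
        elif arr.ndim == 4:
            this_layout = "XYT"
        else:
            raise ValueError(f"{sid}: expected 3D or 4D array, got shape {arr.shape}")
        if layout is None:
            layout = this_layout
        elif layout != this_layout:
            raise ValueError("all volumes must share dimensionality")
        for z in range(arr.shape[2]):
            patches.append(arr[:, :, z] if arr.ndim == 3 else arr[:, :, z, :])
            sources.append((sid, z))
    if not patches:
        raise ValueError("no volumes given")
    return PatchSet(layout=layout, patches=patches, sources=sources, patch_dims=patches[0].shape, stride=(1,))


def extract_3slice_windows(volumes: dict[str, np.ndarray], mode: str = "train") -> PatchSet:
    """Sliding windows of three adjacent XYT slices, stride one slice.

    ``mode="train"`` slides over the cohort-concatenated slice sequence
    (following the intact full-volume slice ordering), yielding
    ``total_slices - 2`` windows.  ``mode="inference"`` works per volume
    with edge-slice replication, yielding exactly one window — hence one
    predicted slice — per input slice.  Patches have shape ``(X, Y, 3, T)``
    and sources record ``(subject_id, center_z)`` of the middle slice (a
    cross-subject training window is attributed to its center slice).
    """
    if mode not in ("train", "inference"):
        raise ValueError("mode must be 'train' or 'inference'")
    slices: list[np.ndarray] = []
    labels: list[tuple] = []
    for sid, arr in volumes.items():
        arr = np.asarray(arr)
        if arr.ndim != 4:
            raise ValueError(f"{sid}: 3-slice windows need 4D (X,Y,Z,T) volumes")
        for z in range(arr.shape[2]):
            slices.append(arr[:, :, z, :])
            labels.append((sid, z))
    patches: list[np.ndarray] = []
    sources: list[tuple] = []
    if mode == "train":
        if len(slices) < 3:
            raise ValueError("need at least 3 slices in total for 3-slice windows")
        for i in range(1, len(slices) - 1):
            patches.append(np.stack(slices[i - 1 : i + 2], axis=2))
            sources.append(labels[i])
    else:
        start = 0
        for sid, arr in volumes.items():
            nz = np.asarray(arr).shape[2]
            for z in range(nz):
                zm = max(z - 1, 0)
                zp = min(z + 1, nz - 1)
                patches.append(np.stack([slices[start + zm], slices[start + z], slices[start + zp]], axis=2))
                sources.append((sid, z))
            start += nz
    return PatchSet(
        layout="XYZT3", patches=patches, sources=sources, patch_dims=patches[0].shape, stride=(1,)
    )


def extract_volume_patches(
    volumes: dict[str, np.ndarray],
    patch_dims: tuple[int, int, int],
    stride: tuple[int, int, int],
    context_dims: tuple[int, int, int] | None = None,
) -> PatchSet:
    """Volumetric (X, Y, Z) patches on a stride grid, optionally with context pairs."""
    patches: list[np.ndarray] = []
    contexts: list[np.ndarray] | None = [] if context_dims is not None else None
    sources: list[tuple] = []
    for sid, arr in volumes.items():
        arr = np.asarray(arr)
        if arr.ndim != 3:
            raise ValueError(f"{sid}: volumetric patches need 3D (X,Y,Z) volumes (tMIP)")
        for origin in plan_volume_patch_origins(arr.shape, patch_dims, stride, context_dims):
            sl = tuple(slice(o, o + p) for o, p in zip(origin, patch_dims))
            patches.append(arr[sl])
            sources.append((sid, *origin))
            if contexts is not None:
                m = [(c - p) // 2 for c, p in zip(context_dims, patch_dims)]
                csl = tuple(
                    slice(o - mm, o - mm + c) for o, mm, c in zip(origin, m, context_dims)
                )
                contexts.append(arr[csl])
    layout = "XYZ_with_context" if context_dims is not None else "XYZ"
    if not patches:
        raise ValueError("no patch position fits the given dims/stride/context")
    return PatchSet(
        layout=layout,
        patches=patches,
        sources=sources,
        patch_dims=tuple(patch_dims),
        stride=tuple(stride),
        context_patches=contexts,
    )


def stitch_volume_patches(
    patches: list[np.ndarray],
    sources: list[tuple],
    out_shape: tuple[int, int, int],
) -> np.ndarray:
    """Place non-overlapping volumetric patches back at their origins."""
    out = np.zeros(out_shape, dtype=np.asarray(patches[0]).dtype)
    for patch, src in zip(patches, sources):
        origin = src[1:]
        sl = tuple(slice(o, o + s) for o, s in zip(origin, patch.shape))
        out[sl] = patch
    return out


def split_cohort(subject_ids: list[str], seed: int = 0, test_fraction: float = 0.2) -> SplitPlan:
    """Hold out ~20% of subjects for testing (seeded); the rest split 3:1 at patch level."""
    if len(subject_ids) < 5:
        raise ValueError("need at least 5 subjects for a subject-wise split")
    rng = np.random.default_rng(seed)
    ids = list(subject_ids)
    n_test = max(1, int(round(len(ids) * test_fraction)))
    test = sorted(rng.choice(len(ids), size=n_test, replace=False).tolist())
    test_ids = [ids[i] for i in test]
    train_ids = [s for s in ids if s not in test_ids]
    return SplitPlan(train_subjects=train_ids, test_subjects=test_ids, seed=seed)


def temporal_resample(volume: Volume4D, mode: str, target_t: int = 24) -> Volume4D:
    """Match a volume's time axis to the training frame count.

    ``pad_zero_end`` appends zero frames; ``average_down`` averages groups
    of consecutive frames (the source count must be an integer multiple of
    the target); ``linear_up`` interpolates linearly on the frame index grid
    so that original samples are reproduced at coinciding time points.
    Frame-duration metadata is rescaled accordingly (padding keeps it).
    """
    data = volume.data
    t_src = data.shape[-1]
    if mode == "pad_zero_end":
        if t_src > target_t:
            raise ValueError("source already longer than target; nothing to pad")
        pad = target_t - t_src
        out = np.concatenate([data, np.zeros(data.shape[:-1] + (pad,), dtype=data.dtype)], axis=-1)
        return volume.with_data(out)
    if mode == "average_down":
        if t_src % target_t != 0:
            raise ValueError(f"cannot average {t_src} frames down to {target_t}: not an integer multiple")
        factor = t_src // target_t
        out = data.reshape(data.shape[:-1] + (target_t, factor)).mean(axis=-1)
        return Volume4D(out.astype(data.dtype), volume.spacing, volume.frame_duration * factor)
    if mode == "linear_up":
        if t_src > target_t:
            raise ValueError("linear_up expects fewer source frames than target")
        scale = t_src / target_t
        coords = np.minimum(np.arange(target_t) * scale, t_src - 1)
        lo = np.floor(coords).astype(int)
        hi = np.minimum(lo + 1, t_src - 1)
        w = (coords - lo).astype(np.float64)
        out = data[..., lo] * (1 - w) + data[..., hi] * w
        return Volume4D(out.astype(np.float32), volume.spacing, volume.frame_duration * scale)
    raise ValueError("mode must be one of pad_zero_end, average_down, linear_up")


def frames_from_spokes(
    n_spokes: int, spokes_per_frame: int = 20, tr_ms: float = 5.0
) -> tuple[int, float]:
    """Radial-acquisition arithmetic: spokes binned into frames.

    Returns ``(n_frames, frame_duration_ms)`` where each frame collects
    ``spokes_per_frame`` in-plane spokes at repetition time ``tr_ms``:
    500 spokes at TR 5 ms binned 20 per frame give 25 frames of 100 ms.
    """
    if n_spokes < spokes_per_frame:
        raise ValueError("need at least one frame's worth of spokes")
    return n_spokes // spokes_per_frame, spokes_per_frame * tr_ms
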