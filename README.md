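# angio4d

Vessel segmentation for non-contrast, ASL-based time-resolved MR
angiography (4D MRA), built around spatio-temporal U-Nets that consume the
bolus-passage dynamics directly instead of a temporal projection.

Pulsed arterial spin labeling tags inflowing blood as an endogenous tracer;
a cine readout then records the labeled bolus washing through the
intracranial arteries as a 4D volume `[X, Y, Z, T]` (1 × 1 × 1.5 mm voxels,
100 ms frames). A vessel voxel carries a transient pulse — arrival at its
arterial transit time (ATT), T1 decay, washout — while background is
static. This package implements the full workflow for researchers studying
such data:

* **`angio4d.phantom`** — synthetic 4D MRA subjects: seeded tortuous
  branching vessel trees rasterized onto the anisotropic grid, with known
  truth masks and ATT maps, driven by the signal model
  `s(t) = A · e^{−t/T1}` inside the bolus window `[ATT, ATT + τ)`.
* **`angio4d.groundtruth`** — level-crossing-count (LCC) segmentation: a
  bolus crosses an intensity level set above the noise exactly twice
  (wash-in and wash-out), static signal at most once, so `LCC > 1`
  separates flowing blood from background.
* **`angio4d.preprocess`** — temporal smoothing, cropping, z-score
  normalization, temporal maximum-intensity projection (tMIP), the four
  patch layouts (full slices, slice+time, 3-slice windows, volumetric
  blocks with optional context), subject-wise splits, and temporal
  resampling for other frame rates.
* **`angio4d.models`** — the U-Net family: 2D and 3D spatial nets, the
  spatio-temporal `st3d` (one slice's XY + time, temporal kernels 3,3,5 /
  7 / 5,3,3, time collapsed by an unpadded (1,1,T) convolution), and
  `st4d` — three weight-shared `st3d` arms over adjacent slices fused by a
  refinement module (plain / residual / dense / residual-dense) with a
  deep-supervision head on the middle arm. Runs on a self-contained
  numpy autodiff engine (`angio4d.nn`); no GPU or deep-learning framework
  required.
* **`angio4d.training`** — the combined loss
  `L = ½·BCE + ½·(1 − DSC)` with squared-denominator soft Dice, 30:70
  deep-supervision weighting for `st4d`, Adam with plateau-driven learning
  rate reduction (×0.1, patience 8) and early stopping (patience 20), and
  full-volume inference restitching.
* **`angio4d.evaluation`** — Dice, centerline Dice (clDice), Hausdorff
  distance, tolerance-1 confusion scores, skeleton-graph statistics (total
  vessel length, branch points, endpoints), SNR and ATT maps, and
  sensitivity binned by SNR (1–10, 11–20, ≥21) and ATT (100–400, 500–800,
  ≥900 ms).

Conventions: 0-based voxel indices, axis order X, Y, Z, T; NIfTI-1 on disk
with the frame duration in a JSON sidecar.

## Worked example

```python
import numpy as np
from angio4d.core import SignalParams
from angio4d.phantom import make_cohort
from angio4d.groundtruth import auto_level, lcc_mask
from angio4d.pipeline import background_roi_for, prepare_subject
from angio4d.preprocess import temporal_moving_average, extract_xy_slices
from angio4d.models import build_st3d
from angio4d.training import TrainConfig, train, predict_volume
from angio4d.evaluation import dice_binary

# nine synthetic participants; the last is held out
subjects = make_cohort(9, dims=(64, 64, 16), params=SignalParams(), seed=42)

# level-crossing ground truth for one subject
sub = subjects[0]
roi = background_roi_for(sub.truth_mask)
level = auto_level(sub.volume, roi, k=3.0)
mask = lcc_mask(temporal_moving_average(sub.volume, 3), level)
print("LCC vs truth Dice:", round(dice_binary(mask, sub.truth_mask), 3))

# train the spatio-temporal net on full-slice patches
prepared = {s.subject_id: prepare_subject(s.volume) for s in subjects}
patches = extract_xy_slices({s.subject_id: prepared[s.subject_id].data
                             for s in subjects[:8]})
x = np.stack(patches.patches)
y = np.stack([subjects[int(sid[-2:])].truth_mask[:, :, z]
              for sid, z in patches.sources])
model = build_st3d(base_channels=8, seed=1)
train(model, x[32:], y[32:], x[:32], y[:32],
      TrainConfig(max_epochs=2, batch_size=2, seed=0))

prob, pred = predict_volume(model, prepared[subjects[8].subject_id])
print("held-out Dice:", round(dice_binary(pred, subjects[8].truth_mask), 3))
```

Output from this exact script:

```
LCC vs truth Dice: 0.995
held-out Dice: 0.877
```

The first number says the level-crossing rule recovers 99 % of the phantom's
vessel voxels (the misses are boluses arriving before the second frame or
washing out after the last); the second says two epochs of the scaled-down
spatio-temporal net already segment an unseen phantom at Dice 0.88.

A command-line interface wraps the same workflow:

```bash
angio4d simulate --n-subjects 4 --dims 64 64 16 --seed 1 --out-dir cohort/
angio4d groundtruth --in cohort/sub-00_4d.nii.gz --level auto --out mask.nii.gz
angio4d run-all --model st3d --seed 1 --out-dir artifacts/
```

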