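# Methods

`angio4d` re-implements, end to end, a deep-learning pipeline for segmenting
intracranial vessels from non-contrast, arterial-spin-labeling (ASL) based
time-resolved MR angiography (4D MRA): synthetic dynamic-angiography
phantoms, level-crossing-count ground truth, a family of spatial and
spatio-temporal U-Nets trained with a combined Dice + cross-entropy loss,
and a vascular evaluation suite. This note records the model assumptions,
the parameters that matter, and the design choices made where the design was
genuinely open.

## The imaging problem

Pulsed ASL magnetically labels inflowing blood below the imaging volume; a
cine readout then captures the labeled bolus washing through the arterial
tree. The result is a 4D volume `[X, Y, Z, T]` (here 1 × 1 × 1.5 mm voxels,
100 ms frames, ~24 frames). A vessel voxel shows a transient pulse — signal
arriving at its arterial transit time (ATT), decaying with the longitudinal
relaxation of blood, and washing out — while background tissue is static.
Segmentation must exploit exactly this temporal signature, because distal
vessels are faint in any single frame.

## Synthetic phantoms (`angio4d.phantom`)

Real scanner cohorts cannot be redistributed, so a generative phantom is the
canonical input for every test in this package.

* **Geometry.** Tortuous branching centerline trees grown by a seeded random
  walk (step 1.5 mm, per-step turn bounded by 0.3 rad), bifurcating with
  probability 0.85 per generation up to depth 4, with radius tapering by
  0.72 per generation from 2.5 mm. With branch probability 1 the tree is a
  complete binary tree — the closed-form segment count used in tests.
* **Rasterization.** A voxel is vessel iff its center lies within the local
  radius of a centerline segment (exact point-to-segment distance in mm on
  the anisotropic grid), or contains a centerline point — the latter keeps
  sub-voxel-radius distal branches connected, mirroring how thin vessels
  still occupy whole voxels through partial volume.
* **Dynamics.** Per vessel voxel, a rectangular bolus window of 700 ms
  delayed by the voxel's ATT, with amplitude decaying as `exp(-t/T1)`
  (T1 of arterial blood 1650 ms at 3 T), sampled at frame centers. ATT is
  `200 ms + path_length / 0.05 mm·ms⁻¹`: the offset models the
  labeling-plane-to-volume transit delay of pulsed ASL (arrival earlier than
  the second frame would be unobservable after temporal smoothing, and
  reported ATT ranges start at 100 ms). An optional Gaussian temporal blur
  models bolus dispersion and is off by default.
* **Background and noise.** Static tissue at 0.02 plus white Gaussian noise
  with σ = 0.05 everywhere. ASL angiograms are control−label subtractions,
  so residual static signal realistically sits below the noise floor; the
  nonzero level still exercises the level-crossing rationale (static signal
  crosses a level at most once). These defaults put vessel SNR in the
  5–20 range, matching the low-SNR regime the method targets; the phantom
  does not model partial-volume fading of distal vessels, coil profiles, or
  reconstruction artifacts, so passing tests show correct mechanics on
  idealized bolus dynamics, not clinical-grade performance.
* Default grid 64 × 64 × 16 × 24 keeps every suite runnable on one CPU.

## Level-crossing-count ground truth (`angio4d.groundtruth`)

A voxel's level crossing count (LCC) is the number of sign changes of
`series − level` between consecutive samples; samples equal to the level
inherit the previous sign (leading ties count as below). A bolus passage
crosses a level strictly between baseline and peak exactly twice; static
background — above, below, or drifting once through the level — at most
once. The mask rule is `LCC > 1`.

The per-participant manual level choice is automated as `k × σ_background`
(default k = 3, the same multiplier used for bolus-arrival detection), with
an epsilon floor for noise-free data. The level is best estimated on the
*unsmoothed* data while the LCC runs on the temporally smoothed data
(window 3): smoothing shrinks the noise by √3 but not the level, which
pushes the threshold to ≈5σ of the smoothed noise and suppresses false
crossings. On default phantoms this reproduces truth masks with Dice ≥ 0.95;
the residual misses are boluses whose arrival or washout falls outside the
acquisition window. Manual editing of the masks is out of scope — phantom
truth is the reference standard instead.

## Preparation (`angio4d.preprocess`)

Temporal moving average (window 3, centered, truncated at the boundaries),
center crop (X, Y divisible by 8 for three 2× down-samplings; leading frames
kept), global per-subject z-score, and temporal maximum intensity projection
(tMIP) for the spatial-only models. Four patch layouts with exact origin
arithmetic: full slices (XY / XYT), sliding 3-slice windows (stride one
slice over the cohort-concatenated slice sequence for training; per-volume
with edge replication at inference so every slice receives exactly one
prediction), and volumetric patches on a stride grid with optional
concentric context patches that must also fit inside the volume. Cohorts
split subject-wise with a 20 % test holdout and a seeded 3:1 train:validation
split at the patch level. External-validation utilities: zero-padding the
tail of short acquisitions, pairwise frame averaging, and linear
interpolation on the frame-index grid. Radial-acquisition arithmetic: frames
= spokes / spokes-per-frame, frame duration = spokes-per-frame × TR (20
spokes × 5 ms = 100 ms).

## Networks (`angio4d.models`, `angio4d.nn`)

Four variants, all with three encoder/decoder stages, stride-1 zero-padded
convolutions, instance normalization after each convolution and before the
ReLU, max-pool down-sampling and transposed-convolution up-sampling
(kernel = stride), and a sigmoid head:

* `unet2d` / `unet3d`: plain U-Nets on tMIP slices / volumetric patches.
  Width plan 64 → 512 for the 2D net (7.70 M parameters, matching the
  published ≈7.8 M within 2 %). The 3D net defaults to the same widths; at
  width 32 it lands on ≈5.6 M, which is the only reading consistent with
  the published ≈5.8 M figure for the 3D variant.
* `st3d`: consumes one full (X, Y, T) slice. The first pool and last
  up-sampling act on XY only (pool plan (2,2,1), (2,2,2), (2,2,2), so 24
  frames → 6 at the bottleneck); temporal kernel sizes 3, 3, 5 through the
  encoder, 7 at the bottleneck, 5, 3, 3 through the decoder (mirrored); the
  input passes a learnable instance normalization; an unpadded (1, 1, 24)
  convolution collapses time before the head, so the output is a 2D slice.
  Base width 32 gives 10.5 M parameters (published ≈1.1 × 10⁷ within 5 %).
* `st4d`: three `st3d` arms with one shared weight set, one arm per slice of
  a 3-adjacent-slice window. The arms are tapped *before* their temporal
  collapse, so the refinement module fuses full spatio-temporal features —
  the published description taps "before the final 1×1 convolution" yet
  still passes a (1,1,24) collapse afterwards, which is only coherent with
  the pre-collapse reading. The input's tMIP (max over slices and time),
  instance-normalized and replicated along T, is concatenated as a skip —
  the normalization matters: the raw tMIP lives on the input scale (up to
  ~20 after z-scoring) and otherwise dominates the refinement module's
  input, starving the main head while the deep-supervision path trains. Four refinement topologies,
  three 3×3×3 convolutions each: plain chain, residual (long skip from the
  first block), dense (each block sees all previous outputs), and
  residual-dense (dense chain plus the long skip). A deep-supervision head
  (its own collapse + sigmoid) on the middle arm is the second output; its
  target is the center slice's 2D mask.

Initialization is He-normal for convolution weights, with the sigmoid heads
starting at a class-prior bias of −3 (vessels occupy a few percent of
voxels): starting the output near the foreground prior instead of 0.5
removes the early epochs a sparse-segmentation network otherwise spends
learning "mostly background".

No deep-learning framework is assumed: the networks run on a compact
reverse-mode automatic-differentiation engine written for this package
(`angio4d.nn`), with every operator's gradient verified against central
finite differences in the test suite. The 3D convolutions dispatch between
two implementations — a JIT-compiled direct convolution for the
full-resolution stages (small channel counts, where im2col is memory-bound)
and an im2col + BLAS path for the deep stages — chosen by output size; both
are cross-checked against each other and against tensor-contraction
references.

## Training (`angio4d.training`)

Loss: `L = ½·BCE + ½·(1 − DSC)` with the squared-denominator soft Dice
(smoothing ε = 1e−6 in numerator and denominator) and probability clipping
at 1e−7 for the cross entropy. For `st4d`, deep supervision mixes the
middle-arm and final-layer losses at 30:70 by default (weights must be
non-negative and sum to one). Adam at 5e−4, batch size 2; learning-rate
reduction by 0.1 after 8 epochs without validation improvement; early
stopping after 20, restoring the best-validation weights (monitoring
validation loss; the alternative of monitoring validation Dice is not
implemented). Everything is seeded: batch order, initialization, and the
phantom cohort, so identical configurations reproduce identical histories.

Inference restitches per-layout: slices for the 2D and `st3d` models,
replicate-padded 3-slice windows for `st4d` (one output slice per input
slice), non-overlapping blocks for the 3D net; binarization at 0.5.

Scaled-down protocol used by the tests and the acceptance script: 8 training
subjects of 64 × 64 × 16 × 24 voxels plus one held-out subject, 8 base
channels, two epochs (well inside the schedule's early-stopping horizon).
Held-out Dice reaches ≈0.8 for both spatio-temporal variants — the problem
sizes are chosen so the whole suite runs on a single CPU; the published
cohort numbers (e.g. DSC 0.876 for the full-scale 4DST on real scanner
data) are not reproducible without that data and are replaced by these
property checks.

## Evaluation (`angio4d.evaluation`)

Binary Dice (defined as 1 for two empty masks); clDice as the harmonic mean
of skeleton precision and sensitivity with 3D thinning; full symmetric
Hausdorff distance between voxel sets (index-grid Euclidean by default —
the units of the published values are unstated — with physical-unit
distances via the `spacing` argument). Tolerance-based confusion counts
realize "within one voxel" by dilating the reference set with the full
26-neighborhood before counting mismatches; tolerance 0 reduces to the
strict confusion matrix, and sensitivity is non-decreasing in the
tolerance by construction.

Skeleton-graph analysis removes false positives by multiplying with the
ground truth, binarizes at 0.5, resamples to an isotropic grid by
nearest-neighbor upsampling of the coarse axes, thins to a 3D skeleton, and
builds a minimum-spanning forest over 26-adjacent skeleton voxels (the
spanning forest removes the spurious triangle chords that diagonal steps
would otherwise add to the length). Total length is the sum of edge lengths
in mm; endpoints are degree-1 nodes; adjacent degree-≥3 voxels collapse to
a single branch point so thick junctions are not over-counted. The
published order (skeletonize, then resize) breaks skeleton thinness under
interpolation; the default here resamples first, with `skeletonize_first=True`
reproducing the stated order.

Dynamics maps: SNR is tMIP / σ_background, with σ taken from the *dynamic*
background samples (the std of the tMIP image itself underestimates frame
noise, since a maximum over frames compresses the noise distribution); ATT
is the first frame exceeding 3σ, reported in ms on a 1-based frame
convention (first-frame arrival ≡ 100 ms), NaN where never exceeded.
Sensitivity is binned by SNR (1–10, 11–20, ≥21; half-open integer bins) and
ATT (100–400, 500–800, ≥900 ms) over truth voxels, with the same voxel
tolerance as the global scores (whether the published binned sensitivities
used the tolerance is unstated; it is configurable here).

## Known limitations

* The phantom's bolus is a rectangular window: no dispersion by default, no
  partial-volume dimming of thin vessels, no pulsatility — so SNR bins are
  narrower than in vivo.
* The LCC fidelity bound excludes boluses arriving before the second frame
  or washing out after the last.
* The training demonstrations are at desk scale (8 channels, minutes of
  CPU); they establish that the architectures learn the temporal signature,
  not clinical accuracy.
* The skeleton graph is built from voxel adjacency; tightly parallel or
  touching branches can merge, as they would in any thinning-based method.
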