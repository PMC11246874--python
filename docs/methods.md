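# Methods

This note records the model, the numerical conventions, and the design
choices behind `sarcoseg`, in the spirit of the methods documentation of
mature scientific packages: enough detail that every computed number in
the tests and the acceptance script can be traced to a definition.

## Problem setting and assumptions

The task is pixelwise binary segmentation (tumor vs background) of
soft-tissue sarcoma in three co-registered MRI sequences per patient
(T1WI, T2WI, STIR) of the thigh.  The pipeline assumes:

- the three sequences of a patient are acquired aligned; no registration
  is performed;
- tumor annotation is an axis-aligned rectangle per scan plane, shared by
  the three sequences of that plane; the training ground truth is the
  filled rectangle, not a hand-drawn contour;
- one tumor per patient; planes where the tumor has no cross-section get
  an empty ground-truth mask and an image-centered crop window.

## Preprocessing conventions

- **Grid.** Axis order is (slice, row, col), 0-based everywhere; boxes are
  half-open with x = column, y = row, recorded in the dataset sidecar.
- **Resampling.** Grid-of-points convention: output index *i* sits at
  physical coordinate *i* · target_spacing, and the output length along an
  axis is `round((n_in − 1) · s_in / s_out) + 1`, which preserves both
  endpoint planes exactly and keeps the physical extent within one target
  spacing of the input extent.  Images are interpolated linearly (exact
  for intensity fields affine in physical coordinates), labels with
  nearest-neighbour.  In-plane axes are then symmetrically center-cropped
  or zero-padded to the standard plane size.  Each modality is resampled
  independently to the same target grid.
- **Normalization.** Per slice and per modality, before cropping:
  S_min/S_max are the 5th/95th percentiles (numpy's linear-interpolation
  convention, pinned by a brute-force oracle in the tests), and
  `S' = clip((S − S_min)/(S_max − S_min), 0, 1)`.  The clip handles the
  10% of pixels outside the trimmed range; a constant slice is a
  degenerate-input error.  The rule is invariant under affine intensity
  rescaling a·S + b (a > 0), which is the point: MRI signal intensity has
  no absolute scale.
- **Cropping.** The crop window is centered on the box center
  (`(min + max − crop) // 2` per axis) and translated the minimum
  distance needed to stay inside the plane; a box larger than the crop is
  an annotation error naming the patient/slice.  Box pixel content is
  preserved bit-for-bit (tested on 200 random boxes).
- **Slice selection.** The central n slices `[⌊(L−n)/2⌋, ⌊(L−n)/2⌋+n)`;
  a volume with fewer than n slices after resampling is a hard error
  rather than being padded, because silent padding would corrupt the
  cross-modality plane alignment.
- **Non-finite intensities** are rejected at both read and write time.

## Architecture

All variants share the UNet skeleton: 4 encoder levels of two 3×3
convolutions (+ batch normalization, ReLU) followed by 2×2 max-pooling,
channel counts doubling from `base_channels` (default 64 → 512), a
bottleneck of two 3×3 convolutions at twice the deepest width (1024 at
default width — continuing the doubling pattern), a decoder of 2×2
transposed convolutions (halving channels) and two 3×3 convolutions per
level, and a 1×1 convolution + per-pixel softmax head over 2 classes.
Inputs must be divisible by 16 in each spatial dimension.

- **sunet** — one encoder on the M modalities stacked as input channels.
- **munet** — M encoders; skip features concatenated along channels.
- **ours** — M encoders; at every skip level and at the bottleneck input
  the concatenated feature map F is fused by F_f = F_c + F_s:
  - channel gate: global average pool to Z ∈ R^C, two fully connected
    layers W₁ ∈ R^{C/2×C}, W₂ ∈ R^{C×C/2} (reduction ratio fixed at 2,
    from the stated weight shapes) with ReLU between and sigmoid output,
    multiplied per channel;
  - spatial gate: sigmoid of (channel-wise max + a 1×1 convolution
    projection W_s ∈ R^{1×1×C×1}), multiplied per position.
  The fused skip (M·C_l channels) is concatenated with the upsampled
  decoder feature and reduced to C_l by the level's double convolution.

Choices where the design was genuinely open: the bottleneck operates on
the fused/concatenated deepest pooled features (the only reading that is
shape-consistent with the decoder's first transposed convolution); batch
normalization is included and config-toggleable; an optional residual
flag adds identity shortcuts around each double convolution and is off
by default (no residual block is part of the core design); weights are
Kaiming-uniform with zero biases, fixed by the model seed; the model is
2D, operating on M×256×256 slices (or any /16 size — it is fully
convolutional).  Both attention gates lie strictly in (0,1), so
‖F_c‖∞ ≤ ‖F‖∞, ‖F_s‖∞ ≤ ‖F‖∞ and ‖F_f‖∞ ≤ 2‖F‖∞; these bounds and a
dense-loop oracle equivalence are property-tested.

## Self-supervised pretraining

Each modality encoder is pretrained on its own slices.  Per step, one
30×30 patch centered on a uniformly drawn tumor-boundary pixel (boundary
= mask pixels 4-adjacent to non-mask, window clamped inside the slice)
is filled with 0 — the post-normalization background level.  One patch
per slice per step, resampled every step.  The clean slice runs through
the full single-path network; the corrupted slice runs through the same
encoder object, so weight sharing is exact by construction.  Feature
vectors are the flattened deepest post-pool encoder activations.  The
loss is `L = L_similarity + L_dice` with `L_similarity = 1 − cos(F⃗, G⃗)`:
minimizing the raw cosine would *decorrelate* the clean and corrupted
features, the opposite of robust feature extraction, so the trainable
default is 1 − cos and the raw form is kept behind `mode="literal_cos"`
for fidelity experiments.  The corrupted branch contributes no Dice
term.  Weight transfer copies every encoder tensor into the matching
path of the multi-encoder model and verifies exact equality.

`L_dice = −(2Σ y_p y_t + ε)/(Σ y_p + Σ y_t + ε)` with ε = 1e-5, a value
in [−1, 0]; the smoothing defines the empty-vs-empty case as −1.

## Training and evaluation protocol

Adam with learning rate 1e-5 (default; reduced-scale runs in the tests
and the acceptance script use 1e-3 to converge within their small step
budgets), batch size 4, at most 100 epochs, early stopping after 10
epochs without validation-loss improvement.  Validation patients are
carved from the training patients (10%, at least one) since the protocol
needs a loss to verify but the test set must stay untouched.  The split
is at patient granularity: `round(0.8·N)` training patients from a
seeded permutation (45 patients → 36/9).  The supervised loss is the
soft Dice loss on the foreground probability; pixelwise cross-entropy
can be added by config flag.

Metrics from the pixel confusion counts: accuracy, Dice
2TP/(2TP+FN+FP), sensitivity TP/(TP+FN) and specificity TN/(TN+FP) (the
standard definitions, which are the ones bounded in [0,1]), plus the
Hausdorff distance between foreground pixel coordinate sets: directed
distance at percentile p (95 by default; 100 recovers the classic
maximum) computed from an exact Euclidean distance transform, scaled to
mm by the pixel spacing, symmetrized by the maximum.  Undefined values
(zero denominators, empty masks) are flagged, excluded from means, and
counted in the report.  Aggregation is the mean over test slices, with a
per-patient breakdown alongside, and the comparison table has columns
Model / Acc / Dice / Sensitivity / Specificity / Hausdorff95.

## Phantom cohort

Each subject is a cylindrical thigh (muscle) with a small cortical-bone
cylinder and one ellipsoidal tumor, rendered into three modality
volumes.  Default contrast table (arbitrary units; mean, noise sd):
background 5, muscle 100/80/60, tumor 55/150/165, sd 5 for
T1WI/T2WI/STIR — enforcing tumor < muscle on T1WI and tumor > muscle on
T2WI/STIR.  Cortical bone takes the background mean (bone is dark on all
three sequences).  Noise is Gaussian; Rician noise physics, bias fields,
partial-volume effects and k-space artifacts are deliberately out of
scope, so the phantoms probe the pipeline's contracts, not clinical
difficulty.  Tumor geometry is analytic: the voxel mask is exactly the
set of voxel centers inside the ellipsoid, evaluated before noise, so
boxes and masks are exact ground truth.  The tumor center is constrained
to the central third of the slice axis (guaranteeing tumor-bearing
central slices), fully inside the muscle and away from the bone.
Per-subject seeds derive from the master seed via a seed sequence and
are recorded in the cohort manifest.

Cohort defaults mirror the study conditions: 45 subjects, 3 modalities,
raw grids with a 9 mm slice gap vs 1.5 mm in-plane (strongly
anisotropic, so resampling is genuinely exercised), tumor semi-axes
15–45 mm.

## Problem sizes used by tests and the acceptance script

Tests and the acceptance script run the identical code paths at a
reduced geometry chosen as the package's fast configuration: raw
volumes 12×96×96 at (6, 2, 2) mm, resampled to (1, 2, 2) mm on a 96×96
plane (67 slices, central 64 kept), 96×96 crops, and narrower models
(base_channels 4–16).  Reduced-scale supervised runs use learning rate
1e-3.  The counting contract (45 subjects × 3 modalities × 64 slices =
8,640 aligned slice images) is exercised at this geometry; it is purely
structural, so the reduced plane size does not change it.  The
acceptance script trains on 4 tumor-bearing slices per training patient
for 6 epochs and evaluates on the held-out patients' tumor slices.

Because phantom tumors are high-contrast ellipsoids, segmentation
quality on them is near-ceiling for all three variants; passing runs
demonstrate that the pipeline, the architectures, the pretraining and
the metrics are implemented correctly, not that the fused model would
outperform the baselines on clinical data.

## Numerical choices and degenerate inputs

- float32 throughout the network stack; percentiles and resampling in
  float64.
- Prediction ties (p_fg = p_bg = 0.5) resolve to background.
- Max-pool/channel-max gradients split equally among tied maxima.
- Dice smoothing ε = 1e-5; cosine loss raises on zero-norm features;
  constant slices, empty masks, non-binary masks, oversized boxes and
  mismatched shapes raise typed errors.
- Batch norm: momentum 0.1, eps 1e-5, running statistics stored in
  checkpoints; evaluation always uses running statistics.
- All RNG flows through `numpy.random.default_rng` seeded per run;
  repeated runs are bit-identical on the same platform.

## Known limitations

- The autodiff core is single-threaded numpy; at the full 512×512
  clinical geometry with base width 64 it is orders of magnitude slower
  than a GPU framework.  The architecture is width- and size-agnostic,
  so the same code runs the full configuration given the compute.
- Rectangle ground truth means reported Dice measures box overlap, not
  contour accuracy.
- Multi-tumor subjects, missing modalities and modality completion are
  out of scope.
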