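# Methods

## Problem setting

The package segments sagittal lumbar-spine MR slices into K = 12 classes
(eleven anatomical structures — vertebral bodies, sacrum, intervertebral
discs, spinal cavity, subcutaneous tissue, epidural fat, intramuscular fat,
retroperitoneal fat, nerve roots, blood vessels, muscle — plus background).
Each input is a pixel-aligned two-channel image: channel 0 the T2-weighted
slice (anatomy silhouettes), channel 1 the T1-weighted slice (fat contrast
used to resolve ambiguities). The ground truth is one class label per pixel,
trained against as a one-hot H×W×K tensor.

## Preprocessing and patching

Channels are z-score normalized independently per slice (population standard
deviation; constant channels map to zeros via a 1e-8 std floor, so degenerate
inputs never produce non-finite values). Slices of arbitrary size are never
resized: they are cut into D×D windows shifted by a stride S, with the final
window start clamped to `dim − D` whenever the regular stride would leave a
border uncovered. This clamp is our operationalization of a "roughly S"
shift: it guarantees full coverage without padding, and with the production
values D = 256, S = 192 every pixel of a square slice is covered by exactly
1, 2 or 4 windows. Per-patch softmax outputs are reassembled into one
slice-level score map by arithmetic-mean averaging over the covering
windows, which preserves per-pixel normalization. All evaluation happens on
reconstructed slices, never on patches.

## Network family

All networks are four-level encoder/decoder graphs joined by a bottleneck,
built from interchangeable blocks and identified by letter codes (U1 = plain
U-Net, UMD = U-Net + multi-kernel input + DS.v3, ...; 13 registered
configurations including an FCN-8 baseline). The building blocks:

* **U block** — [conv 3×3 → batch norm → activation] twice.
* **V block** — two or three conv 3×3 each followed by PReLU, with the
  VGG16 level depths (2, 2, 3, 3, 3). Encoder-only; the decoder falls back
  to U blocks.
* **Q block** — three densely connected [BN → ReLU → conv] units with
  kernels 5×5 / 3×3 / 1×1, 64 channels per unit at every level regardless
  of the base width m.
* **Multi-kernel input (M)** — four parallel convolutions with kernels
  1/3/5/7, each of width m/4, concatenated to width m. The per-path width is
  our choice; only the concatenation principle is fixed by the design.
* **Attention gate (A)** — encoder features and the decoder signal from one
  level below are projected by 1×1 convolutions to an intermediate width
  (half the encoder width — our choice), added, passed through ReLU, a
  second 1×1 convolution and a sigmoid; the resulting one-channel [0, 1]
  mask multiplies the encoder features.
* **Deep supervision** — three signal graphs of 1×1 convolutions of width m:
  DS.v1 (S_n = conv(C_n) + up(S_{n+1})) and DS.v2 (a bottom-up `prevS` pass
  followed by a top-down pass adding max-pooled signals from the level
  above) replace the skip connections; DS.v3 (Z_n = conv(T_n) + up(Z_{n+1}))
  aggregates decoder outputs into the classification-block input.

Channel schedule: m·2^(n−1) per level (bottleneck m·16), m = 64 in
production and configurable (desk scale uses m = 8). The decoder input at
level n is concat(S_n, transposed_conv(T_{n+1})) with 2×2/stride-2
transposed convolutions; the classification block is a 1×1 convolution to K
channels followed by per-pixel softmax.

Conventions we fixed where the design is open: nearest-neighbour ×2
upsampling inside DS graphs and attention gates; He-uniform weight init with
PReLU slopes at 0.25; DS.v2 shares its per-level 1×1 convolution between the
bottom-up and top-down passes (the two printed recursions name the identical
term, so a second independent convolution would be redundant); dense blocks
cannot be combined with DS.v1/DS.v2 (no registered configuration does, and
the channel contract would be ambiguous).

## Compute backend

No GPU framework is assumed: `spineseg.nn` is a compact reverse-mode
autodiff engine on NumPy (NHWC layout) providing exactly the operations the
networks need — stride-1 same-padding convolutions evaluated as sums of
kernel-offset matrix products (bounding peak memory to one shifted input
copy, which matters for 130-channel dense-block inputs on full slices),
2×2/stride-2 transposed convolutions, max pooling, nearest upsampling,
batch normalization with running statistics, ReLU/PReLU/sigmoid/softmax, a
fused softmax cross-entropy, and Adam/RMSprop/Adadelta. Every operation's
gradient is verified against central finite differences in the test suite.
Float32 is the working precision; batch-norm running statistics are part of
checkpoint state.

## Training protocol

Patients are split 20% test (shared across folds; floor rounding), with the
remaining 80% divided round-robin into three validation thirds for
three-fold cross-validation (per fold: one third validation, two thirds
training — the 53%/27%/20% patient fractions). Training minimises
categorical cross-entropy on patches with on-the-fly augmentation (rotation
up to ±20°, zoom 0.5–1.5, shifts up to 10%, horizontal flip with p = 1/2;
composed into a single affine, bilinear for images and nearest for labels,
fill value 0). Checkpoint selection keeps the weights of the epoch with the
highest validation pixel accuracy — "accuracy" here is per-pixel categorical
accuracy over validation patches, our concrete reading of an underspecified
rule. Optimizer and learning rate come from the topology registry (U1:
Adadelta/1.0; UAD: RMSprop/0.001; all others Adam/0.00033).

## Ensembling

Model averaging merges R member score maps by the arithmetic mean (exactly
normalized) or the geometric mean. The bare geometric mean is not a
probability vector, so member scores are floored at 1e-12 and the result is
renormalized per pixel; a zero member score remains absorbing. Stacking
feeds frozen members' outputs — softmax scores (N) or the width-m
pre-classification tensor (T) — through average (A) or concatenation (C)
merging, a per-pixel dense ReLU meta-learner (64 units, our choice; dense
layers act per pixel as 1×1 convolutions, the only shape-consistent
reading) and a dense softmax prediction layer; named configurations NAD and
TCD train for 50 epochs with Adam/0.00033. Add-merging is implemented but
not registered. T-mode stacking is refused for FCN members, which expose no
width-m pre-classification tensor. The registered ensemble compositions
E4–E13 include FCN only in E8 and E13.

## Labeling criteria

MAP assigns the argmax class (ties toward the lowest index). TH visits
classes in descending score order and accepts the first whose score is ≥
its threshold (we use ≥ throughout; the source alternates between strict and
non-strict wording); background has threshold 0 and is the fallback.
Thresholds are tuned per class independently by maximising one-vs-rest IoU
over the grid 0.05…0.95 (step 0.05, 19 values; ties take the lowest value);
a joint search over the 19^11 cascade combinations would be infeasible.
Classes absent from the validation set get 0.05 with a warning.

## Metrics

Per class: IoU = TP/(TP+FP+FN), precision, recall, F1 from pooled pixel
counts. The headline mean IoU averages the target classes only (background
excluded). A class absent from both prediction and ground truth is scored 1
and excluded from means (0/0 convention). Model comparisons use the
two-sided Wilcoxon signed-rank test on paired per-image IoU vectors at
α = 0.05, delegated to scipy; the all-equal degenerate case reports p = 1.

## Phantom generator

`spineseg.synthdata` renders parametric lumbar-like cartoons so the whole
chain runs without any data download: a vertical column of vertebral bodies
with thin intervertebral bands, a spinal-cavity band, subcutaneous/muscle/
fat compartments, vessel lines, a sacral block, and a rare thin class of
small nerve-root blobs (well under 1% of pixels, emulating the hardest real
class). The same mask is rendered into both channels with per-class mean
intensities plus Gaussian noise (default σ = 0.05 against a minimum
class-mean separation of 0.2); the disc and cavity classes share their
channel-0 intensity and are separable only through channel 1, so models
must genuinely combine both channels. On noiseless phantoms a per-pixel
nearest-class-mean classifier recovers the ground truth exactly — the
separability sanity check. Cohort "patients" are groups of 8–14 slices (the
default, mirroring real scanning sessions) of one in-plane size drawn from
a configurable list.

What the phantoms do **not** emulate: MR physics (bias fields, partial
volume, coil inhomogeneity), anatomical variability beyond position jitter,
pathology, or inter-rater ambiguity in ground truth. Passing desk-scale
tests therefore demonstrates that the machinery — blocks, training,
reconstruction, labeling, ensembling, metrics — is correct and trainable,
not that production accuracy on clinical data is reproduced.

## Desk-scale problem sizes

Training-dependent tests and `scripts/acceptance.py` run a reduced profile
chosen to keep full runs in the minutes range on one CPU: 128-px phantoms,
patch 64 / stride 48 (preserving the 1/2/4 overlap structure of 256/192 on
the production sizes), m = 8, 4 classes, 10 patients with 3–5 slices each,
and 15–20 training epochs. Under this profile the plain U-Net reaches ≈1.0
mean foreground IoU on held-out patients, and a three-member arithmetic
ensemble (U1, UD, UA) matches or exceeds its best member — the qualitative
ensemble property at desk scale.

## Known limitations

* 2D only; no 3D context across slices (slice spacing in the target data
  makes isotropic resampling impossible anyway).
* The engine is single-CPU NumPy: production-scale training (m = 64,
  256-px patches, 300 epochs) is out of reach; correctness at that scale is
  covered by structural contracts (shapes, parameter counts, normalization,
  gradient flow) rather than by reproducing clinical accuracy figures.
* Patch-level validation accuracy drives checkpoint selection; slice-level
  accuracy could differ near patch borders.
* The threshold cascade is tuned one-vs-rest, which ignores interactions
  between class thresholds.
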