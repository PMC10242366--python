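# spineseg

Modular U-Net variants, classifier ensembling and evaluation for semantic
segmentation of multi-parametric lumbar-spine MR slices.

## The problem

Radiologists reading lumbar MR studies delineate vertebrae, intervertebral
discs, the spinal cavity, nerve roots, fat compartments, muscle and vessels
slice by slice — slow, repetitive work whose consistency depends on the
reader. This package implements an automatic alternative: every pixel of a
sagittal slice is assigned one of K = 12 classes (11 structures +
background). Inputs are two pixel-aligned channels per slice — T2-weighted
(channel 0, anatomy silhouettes) and T1-weighted (channel 1, fat contrast) —
because several structures are only separable by combining both weightings.

## What is inside

* **A family of U-Net variants** assembled from interchangeable blocks:
  three convolutional block types (original U-Net `U`, VGG16-style `V`,
  densely connected `Q`), a multi-kernel input stage `M` (parallel 1/3/5/7
  kernels), attention gates `A`, and three deep-supervision graphs
  (DS.v1/DS.v2 replacing skip connections, DS.v3 enriching the
  classification input). Thirteen registered configurations (`U1`, `UA`,
  `UD`, `UAD`, `UMD`, `UAMD`, `UVMD`, `UVDD`, `UQD`, `UDD`, `UMDD`, `UDD2`,
  `FCN`) with their optimizers and learning rates.
* **Patch pipeline**: per-channel z-score normalization, overlapping D×D /
  stride-S windows (256/192 in production) with a clamped final window for
  full coverage, and slice-level reconstruction by overlap averaging of the
  per-patch softmax maps.
* **Training**: patient-level 53/27/20 splits with a shared test set and
  three-fold cross-validation, on-the-fly augmentation (±20° rotation,
  0.5–1.5 zoom, 10% shifts, horizontal flips), categorical cross-entropy,
  best-validation-epoch checkpointing.
* **Ensembles**: arithmetic/geometric model averaging (Z̄ = (1/R)ΣZ_r and
  Z̄ = (ΠZ_r)^(1/R), the latter renormalized per pixel) and trainable
  stacking heads over frozen members (`NAD`, `TCD`), plus the registered
  ensemble compositions E4–E13 and leave-one-out ablation.
* **Evaluation**: MAP (argmax) and TH (per-class threshold cascade with
  background fallback) pixel labeling, threshold tuning by one-vs-rest IoU
  maximisation over a 19-value grid, IoU_c = TP_c/(TP_c+FP_c+FN_c) with
  precision/recall/F1, mean IoU excluding background, and Wilcoxon
  signed-rank model comparison.
* **Phantom cohorts** (`spineseg.synthdata`): parametric two-channel
  lumbar-like cartoons with a rare thin nerve-root-like class, so the whole
  chain — training included — runs with no data download.
* **A NumPy autodiff engine** (`spineseg.nn`): the networks run on a
  compact reverse-mode differentiation core (convolutions, transposed
  convolutions, pooling, batch norm, attention arithmetic,
  Adam/RMSprop/Adadelta) with every gradient finite-difference-tested.

Networks consume NIfTI volumes (`<patient>/<session>/{T1w,T2w,mask}.nii.gz`)
or in-memory arrays; label masks are stored as single-channel integer NIfTI.

## Worked example

Train two topologies on a small phantom cohort and evaluate single models
and their ensemble (about 70 seconds on one CPU):

```python
from spineseg.workflow import ExperimentConfig, run_experiment

result = run_experiment(ExperimentConfig(
    topology_ids=("U1", "UD"), epochs=20, seed=1, output_dir="runs/demo",
    n_patients=8, slices_per_patient=(2, 3), image_sizes=(96,),
    num_classes=4, patch_size=48, patch_stride=36,
))
print(result["report"][["model", "mean_iou_without_bg"]].to_string(index=False))
```

```
             model  mean_iou_without_bg
            U1+MAP             0.988945
             U1+TH             0.994940
            UD+MAP             0.867217
             UD+TH             0.869265
ensemble-arith+MAP             0.969253
```

Each row is one labeling criterion on the held-out test patients: `U1+MAP`
is the plain U-Net with argmax labeling, `+TH` the threshold cascade tuned
on the validation patients, and the last row the two-member arithmetic
ensemble. `mean_iou_without_bg` averages per-class IoU over the foreground
classes only — the headline number throughout. Per-class IoU columns,
tuned thresholds, checkpoints and a provenance record are written under
`runs/demo/`.

The same pipeline is scriptable from the shell:

```bash
spineseg synth --patients 10 --classes 4 --size 128 --seed 42 --out data/
spineseg train --topology UMD --data data/ --epochs 15 --out runs/umd
spineseg evaluate --topology UMD --checkpoints runs/umd --data data/
```

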