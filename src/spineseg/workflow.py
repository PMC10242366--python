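"""End-to-end orchestration: synth -> split -> train -> ensemble -> tune ->
evaluate -> report.

The prediction chain for one slice is: z-score normalize, cut into
overlapping patches, forward through the network(s), reconstruct the
slice-level score map by overlap averaging, then label each pixel by MAP or
the threshold cascade. Evaluation always happens on reconstructed full
slices, never on patches.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import LabelMask, ScoreMap, SlicePair
from .ensembles import average_ensemble
from .evaluation import (
    ThresholdVector,
    confusion,
    map_label,
    metrics,
    th_label,
    tune_thresholds,
)
from .preprocess import compute_patch_grid, extract_patches, reconstruct_scores, zscore_normalize
from .synthdata import PhantomConfig, PhantomPatient, generate_cohort
from .topologies import build_topology
from .training import TrainConfig, load_checkpoint, make_patient_splits, save_checkpoint, train_model


class DependencyError(RuntimeError):
    """A required artifact (e.g. a member checkpoint) is missing."""


def score_slice(model, slice_pair: SlicePair, patch_size: int, stride: int,
                batch_size: int = 8) -> ScoreMap:
    """Normalize, patch, forward and reconstruct one slice's score map."""
    norm = zscore_normalize(slice_pair)
    h, w = norm.shape
    if patch_size > h or patch_size > w:
        raise ValueError(
            f"image {h}x{w} smaller than patch size {patch_size}; use a smaller patch"
        )
    grid = compute_patch_grid(h, w, patch_size, stride)
    pset = extract_patches(norm.pixels, grid)
    probs = model.predict_scores(np.stack(pset.patches), batch_size)
    pset.patches = list(probs)
    return reconstruct_scores(pset, grid)


def predict_slice(models, slice_pair: SlicePair, patch_size: int, stride: int,
                  criterion: str = "map", thresholds: ThresholdVector | None = None,
                  mode: str = "arith") -> tuple[LabelMask, ScoreMap]:
    """Label one slice with a single model or an averaged ensemble."""
    if not isinstance(models, (list, tuple)):
        models = [models]
    maps = [score_slice(m, slice_pair, patch_size, stride) for m in models]
    scores = maps[0] if len(maps) == 1 else average_ensemble(maps, mode)
    if criterion == "map":
        return map_label(scores), scores
    if criterion == "th":
        if thresholds is None:
            raise ValueError("th criterion requires a ThresholdVector")
        return th_label(scores, thresholds), scores
    raise ValueError(f"unknown labeling criterion {criterion!r}")


def evaluate_on_slices(models, slices, patch_size, stride, criterion="map",
                       thresholds=None, mode="arith"):
    """Pooled confusion-based metrics over reconstructed slices."""
    total = None
    for img, truth in slices:
        pred, _ = predict_slice(models, img, patch_size, stride, criterion,
                                thresholds, mode)
        c = confusion(pred, truth, truth.num_classes)
        total = c if total is None else total + c
    return metrics(total)


@dataclass
class ExperimentConfig:
    topology_ids: tuple[str, ...] = ("U1",)
    ensemble: bool = True
    folds: tuple[int, ...] = (1,)
    epochs: int = 10
    batch_size: int = 8
    criterion: str = "both"  # map | th | both
    seed: int = 0
    output_dir: str = "runs/experiment"
    # desk profile: small phantoms, small patches, narrow networks
    m: int = 8
    num_classes: int = 4
    patch_size: int = 64
    patch_stride: int = 48
    n_patients: int = 10
    slices_per_patient: tuple[int, int] = (3, 5)
    image_sizes: tuple[int, ...] = (128,)
    noise_sigma: float = 0.05

    def phantom_config(self) -> PhantomConfig:
        return PhantomConfig(
            n_patients=self.n_patients,
            slices_per_patient=self.slices_per_patient,
            image_sizes=self.image_sizes,
            num_classes=self.num_classes,
            noise_sigma=self.noise_sigma,
            seed=self.seed,
        )


def _cohort_data(patients: list[PhantomPatient]) -> dict[str, list]:
    return {p.patient_id: p.slices for p in patients}


def checkpoint_path(out_dir, topology_id: str, fold: int) -> Path:
    return Path(out_dir) / "checkpoints" / f"{topology_id}_fold{fold}_best.npz"


def load_member(topology_id: str, fold: int, out_dir, m: int, num_classes: int,
                seed: int = 0):
    path = checkpoint_path(out_dir, topology_id, fold)
    if not path.exists():
        raise DependencyError(
            f"missing checkpoint for member {topology_id} (fold {fold}): {path}"
        )
    model = build_topology(topology_id, m=m, num_classes=num_classes, seed=seed)
    return load_checkpoint(model, path)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Train the configured topologies on a phantom cohort and report metrics.

    Writes per-model and ensemble metric CSVs, tuned thresholds (JSON),
    checkpoints and a provenance record; returns the report as a dict with
    the output paths and the metrics DataFrame.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cfg.phantom_config())
    data = _cohort_data(cohort)
    splits = make_patient_splits(sorted(data), seed=cfg.seed)
    k = cfg.num_classes

    rows = []
    thresholds_out = {}
    trained: dict[tuple[str, int], object] = {}
    for topo in cfg.topology_ids:
        for fold in cfg.folds:
            split = splits[fold - 1]
            model = build_topology(
                topo, m=cfg.m, num_classes=k, seed=cfg.seed * 1000 + fold
            )
            tc = TrainConfig(
                epochs=cfg.epochs,
                batch_size=cfg.batch_size,
                seed=cfg.seed * 1000 + fold,
                patch_size=cfg.patch_size,
                patch_stride=cfg.patch_stride,
            )
            model, log = train_model(model, split, data, tc)
            save_checkpoint(model, checkpoint_path(out, topo, fold))
            (out / f"{topo}_fold{fold}_log.json").write_text(json.dumps(log))
            trained[(topo, fold)] = model

            test_slices = [s for pid in split.test_patients for s in data[pid]]
            val_slices = [s for pid in split.val_patients for s in data[pid]]
            if cfg.criterion in ("th", "both"):
                val_scores = [
                    score_slice(model, img, cfg.patch_size, cfg.patch_stride)
                    for img, _ in val_slices
                ]
                th = tune_thresholds(val_scores, [m for _, m in val_slices])
                thresholds_out[f"{topo}_fold{fold}"] = list(th.thresholds)
            for crit in ("map", "th") if cfg.criterion == "both" else (cfg.criterion,):
                table = evaluate_on_slices(
                    model, test_slices, cfg.patch_size, cfg.patch_stride, crit,
                    th if crit == "th" else None,
                )
                rows.append(_row(f"{topo}+{crit.upper()}", fold, table, k))

    if cfg.ensemble and len(cfg.topology_ids) > 1:
        for fold in cfg.folds:
            split = splits[fold - 1]
            members = [trained[(t, fold)] for t in cfg.topology_ids]
            test_slices = [s for pid in split.test_patients for s in data[pid]]
            table = evaluate_on_slices(
                members, test_slices, cfg.patch_size, cfg.patch_stride, "map"
            )
            rows.append(_row("ensemble-arith+MAP", fold, table, k))

    report = pd.DataFrame(rows)
    report_path = out / "metrics.csv"
    report.to_csv(report_path, index=False)
    (out / "thresholds.json").write_text(json.dumps(thresholds_out, indent=2))
    provenance = {
        "config": asdict(cfg),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.seed,
    }
    (out / "run.json").write_text(json.dumps(provenance, indent=2))
    return {"report": report, "report_path": report_path, "output_dir": out,
            "thresholds": thresholds_out}


def _row(name: str, fold: int, table, k: int) -> dict:
    row = {"model": name, "fold": fold}
    for c in range(k):
        row[f"iou_class_{c}"] = table.iou[c]
    row["mean_iou_without_bg"] = table.mean_iou
    row["mean_iou_with_bg"] = table.mean_iou_with_background
    return row
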