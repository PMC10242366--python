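"""Pixel labeling, per-class threshold tuning, confusion metrics and
statistical comparison.

Two labeling criteria turn a per-pixel score vector into a class:

* MAP — argmax of the softmax scores (ties toward the lowest class index).
* TH — classes are visited in descending score order and the first whose
  score is >= its tuned threshold wins; the background threshold is fixed
  at 0, and a pixel rejecting every class falls back to background.

Thresholds are tuned per class on validation data by maximising the
one-vs-rest IoU over the grid 0.05, 0.10, ..., 0.95 (ties -> lowest value).

Metrics follow the confusion-count definitions IoU_c = TP/(TP+FP+FN),
precision, recall and F1; the reported mean IoU excludes the background
class. A class absent from both prediction and truth is scored 1 and
excluded from means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import IntegrityError, LabelMask, ScoreMap

THRESHOLD_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)  # 19 values


@dataclass(frozen=True)
class ThresholdVector:
    """One threshold per class; background (class 0) is fixed at 0."""

    thresholds: tuple[float, ...]

    def __post_init__(self):
        if self.thresholds[0] != 0.0:
            raise ValueError("background threshold must be 0")
        if any(t < 0 or t > 1 for t in self.thresholds):
            raise ValueError("thresholds must lie in [0, 1]")

    @classmethod
    def zeros(cls, k: int) -> "ThresholdVector":
        return cls((0.0,) * k)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.thresholds, dtype=np.float64)


def map_label(scores: ScoreMap) -> LabelMask:
    """Maximum a-posteriori labeling: per-pixel argmax of the scores."""
    return LabelMask(
        scores.scores.argmax(axis=2).astype(np.int32), scores.num_classes
    )


def th_label(scores: ScoreMap, th: ThresholdVector) -> LabelMask:
    """Descending-score cascade with per-class thresholds.

    Reduces to :func:`map_label` when every threshold is zero.
    """
    s = scores.scores
    k = s.shape[2]
    if len(th.thresholds) != k:
        raise ValueError(f"expected {k} thresholds, got {len(th.thresholds)}")
    tv = th.as_array()
    flat = s.reshape(-1, k)
    # stable sort on -score: ties visit the lower class index first
    order = np.argsort(-flat, axis=1, kind="stable")
    accepted = np.take_along_axis(flat, order, axis=1) >= tv[order]
    any_acc = accepted.any(axis=1)
    first = accepted.argmax(axis=1)
    labels = np.where(
        any_acc, np.take_along_axis(order, first[:, None], axis=1)[:, 0], 0
    )
    return LabelMask(labels.reshape(s.shape[:2]).astype(np.int32), k)


def _binary_iou(pred: np.ndarray, truth: np.ndarray) -> float:
    union = np.logical_or(pred, truth).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred, truth).sum() / union)


def tune_thresholds(
    val_scores: list[ScoreMap], val_masks: list[LabelMask]
) -> ThresholdVector:
    """Per-class one-vs-rest IoU maximisation over the 19-value grid.

    Classes with no ground-truth pixel in the validation set get the lowest
    grid value (0.05) with a warning.
    """
    if not val_scores:
        raise ValueError("empty validation set")
    if len(val_scores) != len(val_masks):
        raise ValueError("scores and masks differ in length")
    k = val_scores[0].num_classes
    score_stack = [sm.scores for sm in val_scores]
    mask_stack = [m.labels for m in val_masks]
    out = [0.0]
    for c in range(1, k):
        truth = [lbl == c for lbl in mask_stack]
        if not any(t.any() for t in truth):
            warnings.warn(f"class {c} absent from validation; threshold set to 0.05")
            out.append(float(THRESHOLD_GRID[0]))
            continue
        best_t, best_iou = None, -1.0
        for t in THRESHOLD_GRID:
            inter = union = 0
            for sc, tr in zip(score_stack, truth):
                pred = sc[:, :, c] >= t
                inter += int(np.logical_and(pred, tr).sum())
                union += int(np.logical_or(pred, tr).sum())
            iou = 1.0 if union == 0 else inter / union
            if iou > best_iou:  # strict: ties keep the lowest threshold
                best_iou, best_t = iou, float(t)
        out.append(best_t)
    return ThresholdVector(tuple(out))


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class pixel counts: matrix[c_true, c_pred]."""

    matrix: np.ndarray

    @property
    def num_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def mcc(self) -> np.ndarray:  # correctly predicted into c
        return np.diagonal(self.matrix)

    @property
    def tc(self) -> np.ndarray:  # ground-truth pixels of c
        return self.matrix.sum(axis=1)

    @property
    def mc(self) -> np.ndarray:  # pixels predicted as c
        return self.matrix.sum(axis=0)

    @property
    def tp(self) -> np.ndarray:
        return self.mcc

    @property
    def fp(self) -> np.ndarray:
        return self.mc - self.mcc

    @property
    def fn(self) -> np.ndarray:
        return self.tc - self.mcc

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.matrix + other.matrix)


def confusion(pred: LabelMask, truth: LabelMask, k: int | None = None) -> ConfusionCounts:
    if pred.shape != truth.shape:
        raise IntegrityError(f"shape mismatch {pred.shape} vs {truth.shape}")
    k = k or max(pred.num_classes, truth.num_classes)
    m = np.bincount(
        truth.labels.ravel().astype(np.int64) * k + pred.labels.ravel(), minlength=k * k
    ).reshape(k, k)
    return ConfusionCounts(m)


@dataclass(frozen=True)
class MetricsTable:
    iou: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    present: np.ndarray  # False where t_c = m_c = 0 (excluded from means)

    def _mean(self, values: np.ndarray, skip_background: bool) -> float:
        sel = self.present.copy()
        if skip_background:
            sel[0] = False
        return float(values[sel].mean()) if sel.any() else float("nan")

    @property
    def mean_iou(self) -> float:
        """Mean IoU over the target classes (background excluded)."""
        return self._mean(self.iou, skip_background=True)

    @property
    def mean_iou_with_background(self) -> float:
        return self._mean(self.iou, skip_background=False)


def metrics(counts: ConfusionCounts) -> MetricsTable:
    tp = counts.tp.astype(np.float64)
    fp = counts.fp.astype(np.float64)
    fn = counts.fn.astype(np.float64)
    absent = (counts.tc == 0) & (counts.mc == 0)

    def safe(num, den):
        out = np.ones_like(num)  # 0/0 -> 1 (class absent everywhere)
        nz = den > 0
        out[nz] = num[nz] / den[nz]
        return out

    return MetricsTable(
        iou=safe(tp, tp + fp + fn),
        precision=safe(tp, tp + fp),
        recall=safe(tp, tp + fn),
        f1=safe(2 * tp, 2 * tp + fp + fn),
        present=~absent,
    )


def wilcoxon_compare(per_image_iou_a, per_image_iou_b, alpha: float = 0.05):
    """Two-sided Wilcoxon signed-rank test on paired per-image IoU vectors.

    Returns (p_value, significant). All-zero differences are degenerate and
    reported as p = 1 (no evidence of a difference).
    """
    a = np.asarray(per_image_iou_a, dtype=np.float64)
    b = np.asarray(per_image_iou_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if np.allclose(a, b):
        return 1.0, False
    p = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    return p, p < alpha
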