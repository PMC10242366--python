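"""Combining trained segmentation models: averaging and stacking.

Model averaging merges R member score maps with the arithmetic mean
(1/R * sum Z_r) or the geometric mean ((prod Z_r)^(1/R)). The arithmetic
mean of normalized members is normalized; the geometric mean is not, so it
is renormalized per pixel after the R-th root (member scores are floored at
1e-12 first so a single zero stays absorbing but the division is safe).

A stacking ensemble feeds the frozen members' outputs — per-pixel softmax
scores (N) or the pre-classification feature tensor (T) — through a merge
stage (average A or concatenate C), a per-pixel dense ReLU meta-learner and
a dense softmax prediction layer. The named configurations are NAD and TCD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .core_io import IntegrityError, ScoreMap
from .evaluation import ConfusionCounts, confusion, map_label, metrics
from .nn import functional as F

_GEO_FLOOR = 1e-12

# member lists per ensemble id; FCN appears only in E8 and E13
ENSEMBLE_MEMBERS: dict[str, tuple[str, ...]] = {
    "E4": ("UAD", "UMD", "UQD", "UDD"),
    "E5": ("UD", "UAD", "UMD", "UAMD", "UDD2"),
    "E6": ("UD", "UAD", "UMD", "UAMD", "UVMD", "UVDD"),
    "E7": ("UD", "UAD", "UMD", "UAMD", "UVMD", "UQD", "UDD2"),
    "E8": ("FCN", "UD", "UAD", "UMD", "UAMD", "UVMD", "UQD", "UDD2"),
    "E9": ("UD", "UAD", "UMD", "UAMD", "UVMD", "UVDD", "UQD", "UDD", "UMDD"),
    "E10": ("UD", "UAD", "UMD", "UAMD", "UVMD", "UVDD", "UQD", "UDD", "UMDD", "UDD2"),
    "E11": ("U1", "UA", "UD", "UAD", "UMD", "UAMD", "UVMD", "UVDD", "UQD", "UDD", "UMDD"),
    "E12": ("U1", "UA", "UD", "UAD", "UMD", "UAMD", "UVMD", "UVDD", "UQD", "UDD",
            "UMDD", "UDD2"),
    "E13": ("FCN", "U1", "UA", "UD", "UAD", "UMD", "UAMD", "UVMD", "UVDD", "UQD",
            "UDD", "UMDD", "UDD2"),
}


@dataclass(frozen=True)
class EnsembleConfig:
    id: str
    member_ids: tuple[str, ...]
    mode: str = "avg_arith"  # avg_arith | avg_geo | stacking

    def __post_init__(self):
        if self.mode not in ("avg_arith", "avg_geo", "stacking"):
            raise ValueError(f"unknown ensemble mode {self.mode!r}")
        if not self.member_ids:
            raise ValueError("ensemble needs at least one member")

    @property
    def r(self) -> int:
        return len(self.member_ids)


def get_ensemble_config(ensemble_id: str, mode: str = "avg_arith") -> EnsembleConfig:
    try:
        members = ENSEMBLE_MEMBERS[ensemble_id]
    except KeyError:
        raise KeyError(f"unknown ensemble id {ensemble_id!r}") from None
    return EnsembleConfig(ensemble_id, members, mode)


def average_ensemble(member_scores: list[ScoreMap], mode: str = "arith") -> ScoreMap:
    """Merge normalized member score maps by arithmetic or geometric mean."""
    if not member_scores:
        raise ValueError("ensemble of zero members")
    shapes = {sm.scores.shape for sm in member_scores}
    if len(shapes) != 1:
        raise IntegrityError(f"member score shapes differ: {shapes}")
    stack = np.stack([sm.scores.astype(np.float64) for sm in member_scores])
    if mode == "arith":
        return ScoreMap(stack.mean(axis=0).astype(np.float32))
    if mode == "geo":
        logs = np.log(np.maximum(stack, _GEO_FLOOR))
        geo = np.exp(logs.mean(axis=0))
        geo[np.any(stack == 0, axis=0)] = 0.0  # a zero member score is absorbing
        norm = geo.sum(axis=2, keepdims=True)
        norm[norm == 0] = 1.0
        return ScoreMap((geo / norm).astype(np.float32))
    raise ValueError(f"unknown averaging mode {mode!r}")


def geometric_mean_raw(member_scores: list[ScoreMap]) -> ScoreMap:
    """(prod Z_r)^(1/R) without renormalization (flagged unnormalized)."""
    stack = np.stack([sm.scores.astype(np.float64) for sm in member_scores])
    geo = np.exp(np.log(np.maximum(stack, _GEO_FLOOR)).mean(axis=0))
    geo[np.any(stack == 0, axis=0)] = 0.0
    return ScoreMap(geo.astype(np.float32), normalized=False)


@dataclass(frozen=True)
class StackingConfig:
    input_kind: str = "N"  # N: softmax scores, T: pre-classification tensors
    merge: str = "A"  # A: average, C: concatenate, S: add (known poor)
    meta_width: int = 64
    optimizer_name: str = "adam"
    learning_rate: float = 0.00033
    epochs: int = 50

    def __post_init__(self):
        if self.input_kind not in ("N", "T"):
            raise ValueError("input kind must be N or T")
        if self.merge not in ("A", "C", "S"):
            raise ValueError("merge must be A (average), C (concat) or S (add)")

    @property
    def name(self) -> str:
        return f"{self.input_kind}{self.merge}D"


NAD = StackingConfig("N", "A")
TCD = StackingConfig("T", "C")


@dataclass(frozen=True)
class _HeadSpec:
    optimizer_name: str
    learning_rate: float


class StackingHead(nn.Module):
    """Per-pixel two-layer head over merged member representations.

    Dense layers act per pixel, implemented as 1x1 convolutions. Members
    stay frozen; only the meta-learner and prediction layers train.
    """

    def __init__(self, members: list, cfg: StackingConfig, num_classes: int = 12,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        if not members:
            raise ValueError("stacking over zero members")
        self.members = members
        self.cfg = cfg
        self.num_classes = num_classes
        if cfg.input_kind == "T":
            widths = [getattr(m, "feature_channels", None) for m in members]
            if any(w is None for w in widths):
                raise ValueError(
                    "T-input stacking requires members exposing a pre-classification "
                    "tensor; FCN members provide none"
                )
            if len(set(widths)) != 1:
                raise ValueError("members expose pre-classification tensors of "
                                 f"different widths: {widths}")
            unit = widths[0]
        else:
            unit = num_classes
        merged = unit * len(members) if cfg.merge == "C" else unit
        self.merged_width = merged
        self.meta = nn.Conv2D(merged, cfg.meta_width, 1, rng)
        self.pred = nn.Conv2D(cfg.meta_width, num_classes, 1, rng)
        # training plumbing mirrors single networks
        self.spec = _HeadSpec(cfg.optimizer_name, cfg.learning_rate)

    def parameters(self):
        # member weights are frozen: only head layers are trainable
        return self.meta.parameters() + self.pred.parameters()

    def named_parameters(self, prefix: str = ""):
        yield from self.meta.named_parameters(f"{prefix}meta.")
        yield from self.pred.named_parameters(f"{prefix}pred.")

    def named_buffers(self, prefix: str = ""):
        yield from self.meta.named_buffers(f"{prefix}meta.")
        yield from self.pred.named_buffers(f"{prefix}pred.")

    def _member_inputs(self, x) -> list[nn.Tensor]:
        xt = nn.Tensor(x.data if isinstance(x, nn.Tensor) else np.asarray(x))
        outs = []
        for m in self.members:
            if self.cfg.input_kind == "T":
                feat = m.features(xt, training=False)
            else:
                feat = F.softmax(m.forward(xt, training=False), axis=-1)
            outs.append(feat.detach())  # cut the graph: members are frozen
        return outs

    def forward(self, x, training=False):
        feats = self._member_inputs(x)
        if self.cfg.merge == "C":
            merged = nn.concat(feats, axis=-1)
        else:
            merged = feats[0]
            for f in feats[1:]:
                merged = nn.add(merged, f)
            if self.cfg.merge == "A":
                merged = nn.scale(merged, 1.0 / len(feats))
        return self.pred(F.relu(self.meta(merged)))

    def predict_scores(self, x, batch_size: int = 8) -> np.ndarray:
        x = np.asarray(x)
        outs = []
        for lo in range(0, x.shape[0], batch_size):
            logits = self.forward(x[lo : lo + batch_size], training=False)
            outs.append(F.softmax(logits, axis=-1).data)
        return np.concatenate(outs, axis=0)


def build_stacking_head(members: list, cfg: StackingConfig, num_classes: int = 12,
                        seed: int | None = None) -> StackingHead:
    return StackingHead(members, cfg, num_classes, np.random.default_rng(seed))


def train_stacking(head: StackingHead, split, data, cfg=None):
    """Train the head with frozen members (delegates to the training loop)."""
    from .training import TrainConfig, train_model

    if cfg is None:
        cfg = TrainConfig(epochs=head.cfg.epochs)
    return train_model(head, split, data, cfg)


def ensemble_class_iou(member_scores_per_slice, truths, mode="arith") -> np.ndarray:
    """Per-class IoU of an averaged ensemble over a list of slices.

    ``member_scores_per_slice``: list over slices of lists over members of
    ScoreMap. Counts are pooled over slices before computing IoU.
    """
    total: ConfusionCounts | None = None
    for member_maps, truth in zip(member_scores_per_slice, truths):
        pred = map_label(average_ensemble(member_maps, mode))
        c = confusion(pred, truth, truth.num_classes)
        total = c if total is None else total + c
    return metrics(total).iou


def ablate_ensemble(member_scores_per_slice, truths, member_index: int,
                    mode: str = "arith") -> dict:
    """Leave-one-out ablation: per-class IoU without one member and the
    signed delta versus the full ensemble."""
    r = len(member_scores_per_slice[0])
    if not 0 <= member_index < r:
        raise ValueError(f"member index {member_index} out of range for R={r}")
    full = ensemble_class_iou(member_scores_per_slice, truths, mode)
    ablated_scores = [
        [sm for i, sm in enumerate(maps) if i != member_index]
        for maps in member_scores_per_slice
    ]
    ablated = ensemble_class_iou(ablated_scores, truths, mode)
    return {"full_iou": full, "ablated_iou": ablated, "delta": ablated - full}
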