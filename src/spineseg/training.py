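"""Patient-level splitting, augmentation, and model training.

Splitting keeps all slices of a patient in exactly one subset: 20% of
patients form a test set shared by all folds; the remaining 80% is divided
into three validation thirds for three-fold cross-validation (per fold:
one third validation, two thirds training — 53%/27%/20% of patients).

Training minimises categorical cross-entropy on overlapping patches with
on-the-fly augmentation, and keeps the weights of the epoch with the
highest validation pixel accuracy (not the last epoch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .core_io import LabelMask, SlicePair, encode_onehot
from .nn import functional as F
from .nn.optim import make_optimizer
from .preprocess import compute_patch_grid, extract_patches, zscore_normalize


class TrainingError(RuntimeError):
    def __init__(self, message, epoch=None):
        super().__init__(message)
        self.epoch = epoch


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_patients: tuple[str, ...]
    val_patients: tuple[str, ...]
    test_patients: tuple[str, ...]

    def __post_init__(self):
        sets = [set(self.train_patients), set(self.val_patients), set(self.test_patients)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("patient subsets must be pairwise disjoint")


def make_patient_splits(patients: list[str], seed: int) -> list[FoldSplit]:
    """Three folds with a shared 20% test set (floor rounding) and the
    remainder divided round-robin into three validation thirds."""
    patients = list(patients)
    if len(patients) < 5:
        raise ValueError("need at least 5 patients to split")
    order = [patients[i] for i in np.random.default_rng(seed).permutation(len(patients))]
    n_test = len(order) // 5
    test = tuple(order[:n_test])
    rest = order[n_test:]
    folds = []
    for k in range(3):
        val = tuple(rest[k::3])
        train = tuple(p for p in rest if p not in val)
        folds.append(FoldSplit(k + 1, train, val, test))
    return folds


@dataclass
class AugmentConfig:
    max_rotation_deg: float = 20.0
    zoom_range: tuple[float, float] = (0.5, 1.5)
    max_shift_frac: float = 0.10
    hflip_prob: float = 0.5


def augment_sample(
    image: np.ndarray, onehot: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One random geometric transform applied identically to image and mask.

    Rotation, zoom and shift are composed into a single affine; the image is
    interpolated bilinearly, the mask as nearest-neighbour labels (so the
    returned mask is exactly one-hot). A horizontal flip is applied last.
    Out-of-view pixels are filled with 0 (image) / background (mask).
    """
    image = np.asarray(image)
    onehot = np.asarray(onehot)
    if image.shape[:2] != onehot.shape[:2]:
        raise ValueError("image and mask extents differ")
    theta = np.deg2rad(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
    zoom = rng.uniform(*cfg.zoom_range)
    h, w = image.shape[:2]
    shift = rng.uniform(-cfg.max_shift_frac, cfg.max_shift_frac, size=2) * (h, w)
    flip = rng.random() < cfg.hflip_prob

    # inverse mapping (output -> input coordinates) about the image centre
    cos, sin = np.cos(theta), np.sin(theta)
    inv = np.array([[cos, -sin], [sin, cos]]) / zoom
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = centre - inv @ (centre + shift)

    identity = theta == 0 and zoom == 1.0 and not shift.any()
    if identity:
        img_out = image.copy()
        labels = onehot.argmax(axis=2)
    else:
        img_out = np.stack(
            [
                ndimage.affine_transform(
                    image[:, :, c], inv, offset=offset, order=1, cval=0.0
                )
                for c in range(image.shape[2])
            ],
            axis=2,
        )
        labels = ndimage.affine_transform(
            onehot.argmax(axis=2).astype(np.int32), inv, offset=offset, order=0, cval=0
        )
    if flip:
        img_out = img_out[:, ::-1].copy()
        labels = labels[:, ::-1].copy()
    eye = np.eye(onehot.shape[2], dtype=onehot.dtype)
    return img_out.astype(image.dtype), eye[labels]


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 8
    seed: int = 0
    patch_size: int = 256
    patch_stride: int = 192
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def slices_to_patches(
    slices: list[tuple[SlicePair, LabelMask]], d: int, s: int, num_classes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize slices and cut image + one-hot mask into aligned patches."""
    xs, ys = [], []
    for img, mask in slices:
        norm = zscore_normalize(img)
        grid = compute_patch_grid(*norm.shape, d, s)
        onehot = encode_onehot(mask).mask.astype(np.float32)
        for px, py in zip(
            extract_patches(norm.pixels, grid).patches,
            extract_patches(onehot, grid).patches,
        ):
            xs.append(px)
            ys.append(py)
    return np.stack(xs), np.stack(ys)


def _gather(data: dict[str, list], patients) -> list:
    out = []
    for pid in patients:
        out.extend(data[pid])
    return out


def pixel_accuracy(model, x: np.ndarray, y_onehot: np.ndarray, batch_size=8) -> float:
    correct = total = 0
    for lo in range(0, x.shape[0], batch_size):
        probs = model.predict_scores(x[lo : lo + batch_size], batch_size)
        pred = probs.argmax(axis=-1)
        truth = y_onehot[lo : lo + batch_size].argmax(axis=-1)
        correct += int((pred == truth).sum())
        total += pred.size
    return correct / total


def train_model(model, split: FoldSplit, data: dict[str, list], cfg: TrainConfig):
    """Train on the split's training patients; return (model, per-epoch log).

    ``data`` maps patient id -> list of (SlicePair, LabelMask). The model is
    left holding the weights of the best-validation-accuracy epoch.
    """
    k = model.num_classes
    x_tr, y_tr = slices_to_patches(
        _gather(data, split.train_patients), cfg.patch_size, cfg.patch_stride, k
    )
    x_va, y_va = slices_to_patches(
        _gather(data, split.val_patients), cfg.patch_size, cfg.patch_stride, k
    )
    opt = make_optimizer(
        model.spec.optimizer_name, model.parameters(), model.spec.learning_rate
    )
    rng = np.random.default_rng(cfg.seed)
    log = []
    best_acc, best_state = -1.0, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(x_tr.shape[0])
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            if cfg.augment is not None:
                pairs = [
                    augment_sample(xb[i], yb[i], cfg.augment, rng)
                    for i in range(xb.shape[0])
                ]
                xb = np.stack([p[0] for p in pairs])
                yb = np.stack([p[1] for p in pairs])
            opt.zero_grad()
            logits = model.forward(nn.Tensor(xb), training=True)
            loss, _ = F.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch}", epoch=epoch)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_acc = pixel_accuracy(model, x_va, y_va, cfg.batch_size)
        log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_accuracy": val_acc}
        )
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return model, log


def save_checkpoint(model, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())


def load_checkpoint(model, path):
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
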