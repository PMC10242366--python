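"""Data model for two-channel MR slices, label masks and score maps.

A slice of a multi-parametric lumbar scan is a two-channel image: channel 0
is the T2-weighted acquisition (anatomy silhouettes), channel 1 the
T1-weighted one (fat contrast, disambiguation). Ground truth is a per-pixel
label over K classes (class 0 = background, default K = 12: eleven anatomical
structures plus background). Images and label masks are persisted as NIfTI;
one-hot encodings are built in memory only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

NUM_CLASSES_DEFAULT = 12

CLASS_NAMES = [
    "Background",
    "Vert",
    "Sacrum",
    "Int-Disc",
    "Spinal-Cavity",
    "SCT",
    "Epi-Fat",
    "IM-Fat",
    "Rper-Fat",
    "Nerve-Root",
    "Blood-Vessels",
    "Muscle",
]


class AlignmentError(ValueError):
    """The two MR sequences do not share a pixel grid."""


class IntegrityError(ValueError):
    """A tensor violates its structural invariant (e.g. not one-hot)."""


@dataclass
class SlicePair:
    """One pixel-aligned two-channel slice; channel 0 = T2w, channel 1 = T1w."""

    pixels: np.ndarray
    patient_id: str = ""
    slice_index: int = 0
    pixel_spacing: tuple[float, float] | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 2:
            raise ValueError("pixels must be H x W x 2")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("empty image")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class LabelMask:
    """Integer per-pixel labels in [0, num_classes)."""

    labels: np.ndarray
    num_classes: int = NUM_CLASSES_DEFAULT

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be rank 2")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("negative label")
        if self.labels.size and self.labels.max() >= self.num_classes:
            raise ValueError(
                f"label {int(self.labels.max())} >= num_classes {self.num_classes}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class OneHotMask:
    """H x W x K binary tensor, exactly one 1 per pixel."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3:
            raise ValueError("mask must be rank 3")
        sums = self.mask.sum(axis=2)
        if not np.array_equal(sums, np.ones_like(sums)):
            raise IntegrityError("mask is not exactly one-hot per pixel")

    @property
    def num_classes(self) -> int:
        return self.mask.shape[2]


@dataclass
class ScoreMap:
    """H x W x K per-pixel class scores in [0, 1].

    Normalized maps sum to 1 per pixel within 1e-5; geometric-mean
    intermediates may be stored unnormalized with ``normalized=False``.
    """

    scores: np.ndarray
    normalized: bool = field(default=True)

    def __post_init__(self):
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 3:
            raise ValueError("scores must be rank 3")
        if self.scores.min() < -1e-6 or self.scores.max() > 1 + 1e-6:
            raise ValueError("scores outside [0, 1]")
        if self.normalized:
            sums = self.scores.sum(axis=2)
            if not np.allclose(sums, 1.0, atol=1e-5):
                raise IntegrityError("score map declared normalized but sums != 1")

    @property
    def num_classes(self) -> int:
        return self.scores.shape[2]


def _load_slice(path, slice_index: int) -> np.ndarray:
    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if vol.ndim == 2:
        vol = vol[:, :, None]
    if vol.ndim != 3:
        raise ValueError(f"{path}: expected a 2D or 3D NIfTI volume")
    if not 0 <= slice_index < vol.shape[2]:
        raise IndexError(
            f"{path}: slice {slice_index} out of range (volume has {vol.shape[2]})"
        )
    return np.asarray(vol[:, :, slice_index], dtype=np.float32)


def read_slice_pair(
    t2_path, t1_path, slice_index: int = 0, patient_id: str = ""
) -> SlicePair:
    """Read one slice from each sequence and stack them T2w-first."""
    t2 = _load_slice(t2_path, slice_index)
    t1 = _load_slice(t1_path, slice_index)
    if t2.shape != t1.shape:
        raise AlignmentError(
            f"sequence shapes differ: T2w {t2.shape} vs T1w {t1.shape}"
        )
    return SlicePair(
        np.stack([t2, t1], axis=2), patient_id=patient_id, slice_index=slice_index
    )


def write_volume(path, volume: np.ndarray):
    """Write a (H, W, S) array as NIfTI with an identity affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(volume), np.eye(4)), str(path))


def read_label_mask(path, slice_index: int = 0, num_classes: int = NUM_CLASSES_DEFAULT) -> LabelMask:
    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if vol.ndim == 2:
        vol = vol[:, :, None]
    if not 0 <= slice_index < vol.shape[2]:
        raise IndexError(f"{path}: slice {slice_index} out of range")
    return LabelMask(np.asarray(vol[:, :, slice_index]).astype(np.int32), num_classes)


def encode_onehot(mask: LabelMask) -> OneHotMask:
    """Expand integer labels into a one-bit channel per class."""
    k = mask.num_classes
    eye = np.eye(k, dtype=np.uint8)
    return OneHotMask(eye[mask.labels])


def decode_onehot(mask: OneHotMask) -> LabelMask:
    """Inverse of :func:`encode_onehot` (argmax over channels)."""
    return LabelMask(
        mask.mask.argmax(axis=2).astype(np.int32), num_classes=mask.num_classes
    )
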