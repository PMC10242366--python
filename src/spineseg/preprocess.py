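"""Normalization, overlapping patch extraction, and overlap-average
reconstruction.

Slices of arbitrary size are never resized; they are cut into fixed D x D
windows shifted by a stride S, with the final window clamped so its end
coincides with the image border. With the production values D=256, S=192
every pixel of a square slice is covered by 1, 2 or 4 windows; score maps
predicted per patch are reassembled by arithmetic-mean averaging over the
covering windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import IntegrityError, ScoreMap, SlicePair

PATCH_SIZE_DEFAULT = 256
PATCH_STRIDE_DEFAULT = 192

_STD_FLOOR = 1e-8


def zscore_normalize(image: SlicePair) -> SlicePair:
    """Normalize each channel independently to zero mean, unit population std.

    A constant channel maps to all zeros (std floored at 1e-8) so degenerate
    inputs never produce non-finite values.
    """
    px = image.pixels.astype(np.float32)
    if px.shape[0] * px.shape[1] < 2:
        raise ValueError("need at least two pixels per channel to normalize")
    mean = px.mean(axis=(0, 1))
    std = px.std(axis=(0, 1))  # population std
    std = np.maximum(std, _STD_FLOOR)
    return SlicePair(
        (px - mean) / std,
        patient_id=image.patient_id,
        slice_index=image.slice_index,
        pixel_spacing=image.pixel_spacing,
    )


def _starts(dim: int, d: int, s: int) -> list[int]:
    starts = list(range(0, dim - d + 1, s))
    if starts[-1] + d < dim:
        starts.append(dim - d)  # clamp: realizes "approximately S"
    return starts


@dataclass(frozen=True)
class PatchGrid:
    """Window origins of a D x D / stride-S tiling of an H x W image."""

    image_h: int
    image_w: int
    patch_size: int
    stride: int
    row_starts: tuple[int, ...]
    col_starts: tuple[int, ...]

    @property
    def num_patches(self) -> int:
        return len(self.row_starts) * len(self.col_starts)

    def origins(self) -> list[tuple[int, int]]:
        return [(r, c) for r in self.row_starts for c in self.col_starts]

    def coverage(self) -> np.ndarray:
        """Per-pixel count of covering windows."""
        cov = np.zeros((self.image_h, self.image_w), dtype=np.int32)
        d = self.patch_size
        for r, c in self.origins():
            cov[r : r + d, c : c + d] += 1
        return cov


def compute_patch_grid(h: int, w: int, d: int, s: int) -> PatchGrid:
    if s < 1:
        raise ValueError("stride must be >= 1")
    if d > h or d > w:
        raise ValueError(f"patch size {d} exceeds image extent ({h}, {w})")
    return PatchGrid(h, w, d, s, tuple(_starts(h, d, s)), tuple(_starts(w, d, s)))


@dataclass
class PatchSet:
    """The windows of one image, each D x D x C, with their origins."""

    patches: list[np.ndarray]
    origins: list[tuple[int, int]]
    grid: PatchGrid

    @property
    def channels(self) -> int:
        return self.patches[0].shape[2]


def extract_patches(image: np.ndarray, grid: PatchGrid) -> PatchSet:
    """Cut an H x W x C array into the grid's windows (bit-exact copies)."""
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError("image must be rank 3 (H x W x C)")
    if image.shape[:2] != (grid.image_h, grid.image_w):
        raise ValueError(
            f"grid is for {(grid.image_h, grid.image_w)}, image is {image.shape[:2]}"
        )
    d = grid.patch_size
    origins = grid.origins()
    patches = [image[r : r + d, c : c + d].copy() for r, c in origins]
    return PatchSet(patches, origins, grid)


def reconstruct_array(patch_set: PatchSet, grid: PatchGrid | None = None) -> np.ndarray:
    """Overlap-average the patches of a :class:`PatchSet` back to H x W x C."""
    grid = grid or patch_set.grid
    if len(patch_set.patches) != grid.num_patches:
        raise IntegrityError(
            f"expected {grid.num_patches} patches, got {len(patch_set.patches)}"
        )
    if set(patch_set.origins) != set(grid.origins()):
        raise IntegrityError("patch origins do not match the grid")
    d = grid.patch_size
    k = patch_set.channels
    acc = np.zeros((grid.image_h, grid.image_w, k), dtype=np.float64)
    for patch, (r, c) in zip(patch_set.patches, patch_set.origins):
        if patch.shape != (d, d, k):
            raise IntegrityError(f"patch at {(r, c)} has shape {patch.shape}")
        acc[r : r + d, c : c + d] += patch
    cov = grid.coverage()
    return acc / cov[:, :, None]


def reconstruct_scores(patch_scores: PatchSet, grid: PatchGrid | None = None) -> ScoreMap:
    """Reassemble per-patch score maps into one slice-level map.

    Overlapping pixels get the arithmetic mean of the covering patches, so a
    normalized input yields a normalized output and the single-window case is
    the identity.
    """
    return ScoreMap(reconstruct_array(patch_scores, grid).astype(np.float32))
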