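"""Two-channel lumbar-like phantom cohorts for end-to-end exercising.

Each phantom slice is a parametric cartoon of a sagittal lumbar view: a
vertical column of rounded vertebral bodies, thin intervertebral bands, a
spinal-cavity band, a subcutaneous-tissue strip, a muscle compartment, fat
strips, and a rare thin class of small nerve-root blobs. The same label
mask is rendered into two intensity channels with different per-class mean
intensities — emulating the T2w/T1w contrast difference — plus additive
Gaussian noise. Two classes (the disc band and the cavity band) share their
channel-0 intensity and are separable only through channel 1, so a model
must actually combine both channels.

Phantoms are 2D per-slice constructs; "patients" are groups of slices of a
shared in-plane size, enabling patient-level splitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import LabelMask, SlicePair, write_volume

# (T2w, T1w) mean intensity per class; all pairs distinct, classes 2 and 3
# coincide in channel 0.
CLASS_MEANS = np.array(
    [
        [0.10, 0.10],  # 0 background
        [0.55, 0.55],  # 1 vertebral bodies
        [0.85, 0.40],  # 2 intervertebral bands ("discs")
        [0.85, 0.20],  # 3 spinal-cavity band
        [0.30, 0.70],  # 4 nerve-root blobs (rare, thin)
        [0.95, 0.90],  # 5 subcutaneous strip
        [0.40, 0.40],  # 6 muscle compartment
        [0.70, 0.80],  # 7 epidural-fat strip
        [0.70, 0.60],  # 8 intramuscular fat blobs
        [0.60, 0.85],  # 9 retroperitoneal-fat strip
        [0.25, 0.45],  # 10 vessel lines
        [0.50, 0.65],  # 11 sacral block
    ],
    dtype=np.float64,
)

RARE_CLASS = 4  # nerve-root blobs


@dataclass
class PhantomConfig:
    n_patients: int = 10
    slices_per_patient: tuple[int, int] = (8, 14)
    image_sizes: tuple[int, ...] = (128, 192, 256)
    num_classes: int = 12
    noise_sigma: float = 0.05
    rare_class_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not 2 <= self.num_classes <= 12:
            raise ValueError("num_classes must be in [2, 12]")
        if self.slices_per_patient[0] < 1:
            raise ValueError("need at least one slice per patient")


def _disk(mask, cy, cx, radius, value):
    h, w = mask.shape
    yy, xx = np.ogrid[:h, :w]
    sel = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    mask[sel] = value


def generate_phantom_slice(
    cfg: PhantomConfig, rng: np.random.Generator, size: int | None = None
) -> tuple[SlicePair, LabelMask]:
    """Render one phantom slice and its ground-truth label mask."""
    h = w = int(size if size is not None else rng.choice(cfg.image_sizes))
    k = cfg.num_classes
    labels = np.zeros((h, w), dtype=np.int32)

    def on(c):
        return c < k

    # large compartments first, finer structures painted on top
    if on(5):
        labels[:, int(0.88 * w) :] = 5
    if on(6):
        labels[:, : int(0.30 * w)] = 6
    if on(9):
        labels[:, int(0.30 * w) : int(0.36 * w)] = 9
    if on(7):
        labels[:, int(0.70 * w) : int(0.74 * w)] = 7
    if on(11):
        labels[int(0.86 * h) :, int(0.36 * w) : int(0.60 * w)] = 11

    # vertebral column with intervertebral bands
    col_cx = 0.45 + rng.uniform(-0.02, 0.02)
    col_half = 0.115
    x0, x1 = int((col_cx - col_half) * w), int((col_cx + col_half) * w)
    n_vert = int(rng.integers(4, 7))
    pitch = h / n_vert
    gap = max(2, int(0.035 * h))
    for i in range(n_vert):
        top = int(i * pitch) + gap
        bot = int((i + 1) * pitch) - gap // 2
        if bot > top and on(1):
            labels[top:bot, x0:x1] = 1
        if i > 0 and on(2):
            band_top = int(i * pitch) - gap // 2
            labels[band_top : int(i * pitch) + gap, x0 + 2 : x1 - 2] = 2

    if on(3):
        labels[:, int(0.62 * w) : int(0.70 * w)] = 3

    if on(8):  # intramuscular fat blobs
        for _ in range(int(rng.integers(2, 5))):
            _disk(
                labels,
                int(rng.uniform(0.1, 0.9) * h),
                int(rng.uniform(0.05, 0.25) * w),
                max(2, int(0.025 * h)),
                8,
            )
    if on(10):  # vessel lines inside the muscle compartment
        for _ in range(int(rng.integers(1, 3))):
            vx = int(rng.uniform(0.26, 0.285) * w)
            labels[int(0.1 * h) : int(0.9 * h), vx : vx + max(1, w // 128)] = 10
    if on(RARE_CLASS):  # rare thin nerve-root blobs at the cavity margin
        r = max(1, int(0.015 * h))
        n_blobs = int(rng.integers(2, 5))
        for _ in range(n_blobs):
            _disk(
                labels,
                int(rng.uniform(0.1, 0.9) * h),
                int(0.615 * w) + int(rng.uniform(-1, 2)),
                r,
                RARE_CLASS,
            )

    means = CLASS_MEANS[labels]  # (H, W, 2)
    noise = (
        rng.normal(0.0, cfg.noise_sigma, size=means.shape)
        if cfg.noise_sigma > 0
        else 0.0
    )
    pixels = (means + noise).astype(np.float32)
    return SlicePair(pixels), LabelMask(labels, num_classes=k)


@dataclass
class PhantomPatient:
    patient_id: str
    slices: list[tuple[SlicePair, LabelMask]] = field(default_factory=list)


def generate_cohort(cfg: PhantomConfig) -> list[PhantomPatient]:
    """Generate an in-memory cohort; deterministic for a given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    patients = []
    lo, hi = cfg.slices_per_patient
    for i in range(cfg.n_patients):
        pid = f"sub-{i + 1:03d}"
        size = int(rng.choice(cfg.image_sizes))
        n_slices = int(rng.integers(lo, hi + 1))
        slices = []
        for s in range(n_slices):
            img, mask = generate_phantom_slice(cfg, rng, size=size)
            img.patient_id = pid
            img.slice_index = s
            slices.append((img, mask))
        patients.append(PhantomPatient(pid, slices))
    return patients


def generate_phantom_cohort(cfg: PhantomConfig, out_dir) -> Path:
    """Write a cohort as a NIfTI tree and return the manifest path.

    Layout: ``<out>/<patient>/ses-01/{T2w,T1w,mask}.nii.gz`` with slices
    stacked along the third axis, plus ``manifest.json`` listing patients.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"num_classes": cfg.num_classes, "seed": cfg.seed, "patients": []}
    for patient in generate_cohort(cfg):
        sess = out_dir / patient.patient_id / "ses-01"
        t2 = np.stack([s.pixels[:, :, 0] for s, _ in patient.slices], axis=2)
        t1 = np.stack([s.pixels[:, :, 1] for s, _ in patient.slices], axis=2)
        msk = np.stack([m.labels for _, m in patient.slices], axis=2).astype(np.int16)
        write_volume(sess / "T2w.nii.gz", t2)
        write_volume(sess / "T1w.nii.gz", t1)
        write_volume(sess / "mask.nii.gz", msk)
        manifest["patients"].append(
            {"id": patient.patient_id, "n_slices": len(patient.slices)}
        )
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_cohort(root) -> list[PhantomPatient]:
    """Read a cohort written by :func:`generate_phantom_cohort`."""
    import nibabel as nib

    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    k = manifest["num_classes"]
    patients = []
    for entry in manifest["patients"]:
        sess = root / entry["id"] / "ses-01"
        t2 = np.asanyarray(nib.load(str(sess / "T2w.nii.gz")).dataobj)
        t1 = np.asanyarray(nib.load(str(sess / "T1w.nii.gz")).dataobj)
        msk = np.asanyarray(nib.load(str(sess / "mask.nii.gz")).dataobj)
        slices = []
        for s in range(t2.shape[2]):
            img = SlicePair(
                np.stack([t2[:, :, s], t1[:, :, s]], axis=2).astype(np.float32),
                patient_id=entry["id"],
                slice_index=s,
            )
            slices.append((img, LabelMask(msk[:, :, s].astype(np.int32), k)))
        patients.append(PhantomPatient(entry["id"], slices))
    return patients
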