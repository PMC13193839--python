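"""Synthetic axial lung-CT phantoms with ground-truth masks.

Each phantom mimics the gross intensity structure of an 8-bit axial chest CT
slice: a dark background, a bright body ellipse, two dark lung fields placed
symmetrically about the vertical midline, and — depending on the class label —
a nodule inside one lung:

* ``Benign``    — a small, well-circumscribed (smooth-margin) blob;
* ``Malignant`` — a larger blob with an irregular margin, modelled by
  perturbing the boundary radius with seeded low-frequency noise;
* ``Normal``    — no nodule.

Every phantom carries its ground-truth lung and nodule masks, which serve as
the oracle for the segmentation and masking stages.  The generator is fully
deterministic for a fixed (spec, label, seed) triple.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .image_core import save_png
from .manifest import CLASS_NAMES, Manifest, ManifestRecord

#: Per-class image counts of the emulated three-class clinical dataset
#: (530 benign, 536 malignant, 534 normal; 1,600 slices total).
CLINICAL_CLASS_COUNTS = {"Benign": 530, "Malignant": 536, "Normal": 534}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the phantom family.

    Intensity means must be ordered background < lung < nodule < body so that
    the fixed thresholds used downstream (binarization at 128, nodule
    candidates below 140) separate the structures by construction.
    """

    image_size: int = 512
    body_intensity: float = 180.0
    lung_intensity: float = 40.0
    background_intensity: float = 10.0
    nodule_intensity: float = 120.0
    noise_sd: float = 8.0
    benign_nodule_radius: tuple[float, float] = (6.0, 12.0)
    malignant_nodule_radius: tuple[float, float] = (14.0, 28.0)
    #: peak relative radial perturbation of the malignant margin
    malignant_irregularity: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if not (
            self.background_intensity
            < self.lung_intensity
            < self.nodule_intensity
            < self.body_intensity
        ):
            raise ValidationError(
                "intensity means must be ordered background < lung < nodule < body"
            )
        if self.image_size < 64:
            raise ValidationError("image_size must be at least 64 pixels")
        for lo, hi in (self.benign_nodule_radius, self.malignant_nodule_radius):
            if not (0 < lo <= hi):
                raise ValidationError("nodule radius ranges must satisfy 0 < lo <= hi")


@dataclass
class PhantomRecord:
    """A rendered phantom plus its ground truth."""

    image: np.ndarray
    label: str
    lung_mask: np.ndarray
    nodule_mask: np.ndarray


def _ellipse_mask(shape, center, semi_axes, angle_rad=0.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    y = yy - center[0]
    x = xx - center[1]
    if angle_rad:
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        x, y = c * x + s * y, -s * x + c * y
    return (x / semi_axes[1]) ** 2 + (y / semi_axes[0]) ** 2 <= 1.0


def _nodule_mask(shape, center, radius, irregularity, rng):
    """Blob mask via radial-function boundary; irregularity=0 gives a circle."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    dy = yy - center[0]
    dx = xx - center[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    if irregularity > 0:
        # low-frequency harmonic perturbation of the margin radius
        n_harm = 5
        amps = rng.uniform(-1.0, 1.0, n_harm) / np.arange(2, 2 + n_harm)
        phases = rng.uniform(0, 2 * np.pi, n_harm)
        pert = np.zeros_like(theta)
        for k in range(n_harm):
            pert += amps[k] * np.cos((k + 2) * theta + phases[k])
        pert *= irregularity / (np.max(np.abs(pert)) + 1e-12)
        boundary = radius * (1.0 + pert)
    else:
        boundary = np.full_like(theta, radius)
    return r <= boundary


def lung_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Seeded body/lung ellipse parameters (centers, semi-axes) with jitter."""
    n = spec.image_size
    cy, cx = n / 2.0, n / 2.0
    body_axes = (0.38 * n, 0.45 * n)  # (semi-y, semi-x)
    lung_axes = (0.26 * n, 0.13 * n)
    offset_x = 0.20 * n + rng.uniform(-0.01, 0.01) * n
    jitter_y = rng.uniform(-0.01, 0.01) * n
    left_center = (cy + jitter_y, cx - offset_x)
    right_center = (cy + jitter_y, cx + offset_x)
    return (cy, cx), body_axes, [left_center, right_center], lung_axes


def generate_phantom(spec: PhantomSpec, label: str, seed: int) -> PhantomRecord:
    """Render one phantom slice of the given class.

    Deterministic for fixed ``(spec, label, seed)``.  The nodule (if any) is
    placed entirely inside one lung ellipse; its ground-truth mask is a subset
    of the lung mask by construction.
    """
    if label not in CLASS_NAMES:
        raise ValidationError(f"unknown class label {label!r}")
    rng = np.random.default_rng([spec.seed, seed, CLASS_NAMES.index(label)])
    n = spec.image_size
    shape = (n, n)

    body_center, body_axes, lung_centers, lung_axes = lung_geometry(spec, rng)
    body = _ellipse_mask(shape, body_center, body_axes)
    lungs = np.zeros(shape, dtype=bool)
    for c in lung_centers:
        lungs |= _ellipse_mask(shape, c, lung_axes)
    lungs &= body

    image = np.full(shape, spec.background_intensity, dtype=np.float64)
    image[body] = spec.body_intensity
    image[lungs] = spec.lung_intensity

    nodule = np.zeros(shape, dtype=bool)
    if label != "Normal":
        lo, hi = (
            spec.benign_nodule_radius if label == "Benign" else spec.malignant_nodule_radius
        )
        irregularity = 0.0 if label == "Benign" else spec.malignant_irregularity
        radius = rng.uniform(lo, hi)
        # worst-case margin excursion must stay inside the lung ellipse
        reach = radius * (1.0 + (2.0 * irregularity if irregularity else 0.0)) + 2.0
        if reach >= min(lung_axes):
            raise ValidationError(
                f"nodule radius {radius:.1f}px (reach {reach:.1f}) exceeds the lung "
                f"ellipse minor semi-axis {min(lung_axes):.1f}px"
            )
        side = int(rng.integers(0, 2))
        lcy, lcx = lung_centers[side]
        # sample a center such that the whole nodule fits inside the ellipse
        fy = (lung_axes[0] - reach) / lung_axes[0]
        fx = (lung_axes[1] - reach) / lung_axes[1]
        while True:
            u, v = rng.uniform(-1, 1, 2)
            if u * u + v * v <= 1.0:
                break
        center = (lcy + u * fy * lung_axes[0], lcx + v * fx * lung_axes[1])
        nodule = _nodule_mask(shape, center, radius, irregularity, rng)
        nodule &= lungs
        image[nodule] = spec.nodule_intensity

    image += rng.normal(0.0, spec.noise_sd, shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    return PhantomRecord(
        image=image,
        label=label,
        lung_mask=lungs.astype(np.uint8),
        nodule_mask=nodule.astype(np.uint8),
    )


def resolved_counts(n_per_class: int, emulate_clinical_counts: bool) -> dict[str, int]:
    """Per-class counts for a generated dataset.

    With ``emulate_clinical_counts`` the generated composition is exactly the
    emulated clinical one — 530/536/534, 1,600 images — regardless of
    ``n_per_class``.
    """
    if emulate_clinical_counts:
        return dict(CLINICAL_CLASS_COUNTS)
    return {c: n_per_class for c in CLASS_NAMES}


def generate_dataset(
    spec: PhantomSpec,
    n_per_class: int,
    seed: int,
    out_dir: str | os.PathLike,
    emulate_clinical_counts: bool = False,
) -> Manifest:
    """Write a class-foldered phantom dataset with ground-truth masks.

    Layout: ``<out_dir>/<Class>/img_<k>.png`` plus
    ``<out_dir>/truth/<Class>/img_<k>_lung.png`` and ``..._nodule.png``
    (masks stored as {0,255} PNGs).

    With ``emulate_clinical_counts`` the per-class counts follow the emulated
    clinical composition {530, 536, 534} instead of ``n_per_class``.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    out = Path(out_dir)
    records = []
    counts = resolved_counts(n_per_class, emulate_clinical_counts)
    for label in CLASS_NAMES:
        count = counts[label]
        cls_dir = out / label
        truth_dir = out / "truth" / label
        cls_dir.mkdir(parents=True, exist_ok=True)
        truth_dir.mkdir(parents=True, exist_ok=True)
        for k in range(count):
            rec = generate_phantom(spec, label, seed=seed * 1_000_003 + k)
            img_path = cls_dir / f"img_{k:04d}.png"
            save_png(rec.image, img_path)
            save_png(rec.lung_mask * 255, truth_dir / f"img_{k:04d}_lung.png")
            save_png(rec.nodule_mask * 255, truth_dir / f"img_{k:04d}_nodule.png")
            records.append(ManifestRecord(path=str(img_path), label=label))
    return Manifest(records=records, split_tag="unsplit")


def phantom_stream(spec: PhantomSpec, n_per_class: int, seed: int):
    """Yield ``PhantomRecord`` objects in class-major order without touching disk."""
    for label in CLASS_NAMES:
        for k in range(n_per_class):
            yield generate_phantom(spec, label, seed=seed * 1_000_003 + k)
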