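"""Seeded training-time augmentation: mild affine transforms plus flips.

The ranges are deliberately conservative — rotation up to 30 degrees, shifts
up to a quarter of the image side, shear up to 0.5 rad, zoom within 2.5% of
unity — so that lesion morphology and the anatomical layout survive the
transform.  Empty border pixels are filled by nearest-edge replication.
Augmentation applies to the training stream only; the trainer asserts this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

from .errors import ValidationError
from .image_core import validate_gray


@dataclass(frozen=True)
class AugmentConfig:
    """Sampling ranges for one random transform (uniform within each range)."""

    rotation_deg: tuple[float, float] = (0.0, 30.0)
    shift_fraction: float = 0.25
    shear_rad: tuple[float, float] = (0.0, 0.5)
    zoom: tuple[float, float] = (0.975, 1.025)
    hflip: bool = True
    vflip: bool = True
    fill_mode: str = "nearest"
    seed: int = 0

    def __post_init__(self):
        if not self.zoom[0] <= 1.0 <= self.zoom[1]:
            raise ValidationError("zoom range must contain 1.0")
        if not 0.0 <= self.shift_fraction < 1.0:
            raise ValidationError("shift_fraction must lie in [0,1)")


@dataclass(frozen=True)
class TransformSample:
    """One concrete draw from the configured ranges."""

    angle: float
    dx: float
    dy: float
    shear: float
    scale: float
    do_hflip: bool
    do_vflip: bool

    @property
    def is_identity(self) -> bool:
        return (
            self.angle == 0.0
            and self.dx == 0.0
            and self.dy == 0.0
            and self.shear == 0.0
            and self.scale == 1.0
            and not self.do_hflip
            and not self.do_vflip
        )


def sample_transform(config: AugmentConfig, rng: np.random.Generator) -> TransformSample:
    """Draw one transform: each parameter uniform over its range, flips are
    independent fair coins (when enabled).  Shifts are signed, up to
    ``shift_fraction`` of the corresponding image side (resolved at apply
    time, so the sample stores fractions of the side as dx/dy)."""
    return TransformSample(
        angle=float(rng.uniform(*config.rotation_deg)),
        dx=float(rng.uniform(-config.shift_fraction, config.shift_fraction)),
        dy=float(rng.uniform(-config.shift_fraction, config.shift_fraction)),
        shear=float(rng.uniform(*config.shear_rad)),
        scale=float(rng.uniform(*config.zoom)),
        do_hflip=bool(config.hflip and rng.random() < 0.5),
        do_vflip=bool(config.vflip and rng.random() < 0.5),
    )


def transform_matrix(t: TransformSample, shape: tuple[int, int]) -> AffineTransform:
    """Center-anchored affine: rotate, x-shear, zoom, then shift."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    to_center = AffineTransform(translation=(-cx, -cy))
    core = (
        AffineTransform(rotation=np.deg2rad(t.angle))
        + AffineTransform(shear=t.shear)
        + AffineTransform(scale=(t.scale, t.scale))
    )
    back = AffineTransform(translation=(cx + t.dx * w, cy + t.dy * h))
    return to_center + core + back


def apply_transform(
    image: np.ndarray,
    t: TransformSample,
    fill_mode: str = "nearest",
    order: int = 1,
) -> np.ndarray:
    """Warp an image by a sampled transform; flips applied last.

    Interpolation is bilinear by default (``order=1``); border fill follows
    ``fill_mode`` (only nearest-edge replication is supported).  Shape and the
    8-bit range are preserved; the identity sample is a bit-exact no-op.
    """
    image = validate_gray(image)
    if fill_mode != "nearest":
        raise ValidationError(f"unsupported fill mode {fill_mode!r}")
    if t.is_identity:
        return image.copy()
    tf = transform_matrix(t, image.shape)
    out = warp(
        image.astype(np.float64),
        tf.inverse,
        order=order,
        mode="edge",
        preserve_range=True,
    )
    out = np.rint(out).clip(0, 255).astype(np.uint8)
    if t.do_hflip:
        out = out[:, ::-1]
    if t.do_vflip:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def apply_inverse_transform(
    image: np.ndarray,
    t: TransformSample,
    fill_mode: str = "nearest",
    order: int = 1,
) -> np.ndarray:
    """Warp by the exact inverse of a flip-free sample (round-trip checks)."""
    image = validate_gray(image)
    if t.do_hflip or t.do_vflip:
        raise ValidationError("cannot invert a sample with flips")
    if fill_mode != "nearest":
        raise ValidationError(f"unsupported fill mode {fill_mode!r}")
    if t.is_identity:
        return image.copy()
    tf = transform_matrix(t, image.shape)
    out = warp(
        image.astype(np.float64),
        tf,  # forward map as the inverse coordinate map
        order=order,
        mode="edge",
        preserve_range=True,
    )
    return np.rint(out).clip(0, 255).astype(np.uint8)


class Augmenter:
    """Seeded stream of random transforms bound to one config."""

    def __init__(self, config: AugmentConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)

    def __call__(self, image: np.ndarray, order: int = 1) -> np.ndarray:
        t = sample_transform(self.config, self.rng)
        return apply_transform(image, t, fill_mode=self.config.fill_mode, order=order)
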