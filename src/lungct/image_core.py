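"""Grayscale image loading, resizing, and backbone-input conversion.

The pipeline's pixel carrier is a plain 2-D ``uint8`` NumPy array ("gray
image"): intensities in [0, 255], strictly positive height and width.  Two
resize conventions are used downstream: 512x512 for segmentation and masking,
and 224x224 replicated to three channels for the classification backbone.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

from .errors import DecodeError, ValidationError

PROCESS_SIZE = 512
BACKBONE_SIZE = 224

#: ITU-R BT.601 luma weights used to collapse RGB inputs to one channel.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def validate_gray(image: np.ndarray, name: str = "image") -> np.ndarray:
    """Check that ``image`` is a valid 2-D uint8 intensity grid and return it."""
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] <= 0 or arr.shape[1] <= 0:
        raise ValidationError(f"{name} has a non-positive dimension: {arr.shape}")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
            arr = arr.astype(np.uint8)
        else:
            raise ValidationError(
                f"{name} must be 8-bit intensities in [0,255], got dtype {arr.dtype}"
            )
    return arr


def load_grayscale(path: str | os.PathLike) -> np.ndarray:
    """Load a JPG/PNG file as a 2-D uint8 grayscale image.

    Color inputs are reduced with BT.601 luma weighting (the same convention
    Pillow uses for ``convert("L")``); single-channel inputs pass through
    unchanged.

    Raises
    ------
    DecodeError
        If the file is missing, unreadable, or decodes to a zero-size image.
    """
    try:
        with Image.open(path) as im:
            if im.mode == "L":
                arr = np.asarray(im)
            elif im.mode in ("LA", "RGBA", "P"):
                arr = np.asarray(im.convert("RGB"))
            else:
                arr = np.asarray(im if im.mode == "RGB" else im.convert("RGB"))
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise DecodeError(f"cannot read image file {os.fspath(path)!r}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"image {os.fspath(path)!r} is zero-size")
    if arr.ndim == 3:
        luma = arr[..., :3].astype(np.float64) @ np.asarray(LUMA_WEIGHTS)
        arr = np.rint(luma).clip(0, 255).astype(np.uint8)
    return validate_gray(arr, name=os.fspath(path))


def save_png(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write a gray image (or {0,1} mask scaled to {0,255}) as lossless PNG."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = validate_gray(arr)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def resize_to(
    image: np.ndarray,
    height: int,
    width: int,
    interpolation: str = "bilinear",
) -> np.ndarray:
    """Resize a gray image to ``height x width``.

    ``interpolation`` is ``"bilinear"`` (default, for intensity images) or
    ``"nearest"`` (for masks — guarantees no values outside the input's value
    set are created).
    """
    image = validate_gray(image)
    if height <= 0 or width <= 0:
        raise ValidationError(f"target dimensions must be positive, got {height}x{width}")
    if image.shape == (height, width):
        return image.copy()
    orders = {"bilinear": 1, "nearest": 0}
    if interpolation not in orders:
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    out = _sk_resize(
        image.astype(np.float64),
        (height, width),
        order=orders[interpolation],
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.rint(out).clip(0, 255).astype(np.uint8)


def to_backbone_input(image: np.ndarray, interpolation: str = "bilinear") -> np.ndarray:
    """Convert a gray image into the 224x224x3 backbone input.

    The grayscale plane is resized to 224x224 and replicated identically
    across the three channels.
    """
    small = resize_to(image, BACKBONE_SIZE, BACKBONE_SIZE, interpolation=interpolation)
    return np.repeat(small[:, :, None], 3, axis=2)
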