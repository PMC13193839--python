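"""Lung-field segmentation: CLAHE, thresholding, morphology, edge-guided fill.

The stage isolates the two air-filled lung fields of an axial slice:

1. CLAHE boosts local contrast so lung boundaries survive thresholding;
2. a fixed intensity threshold binarizes the enhanced image (lungs are dark,
   so foreground = below-threshold by default);
3. the mask is refined by closing (bridge small gaps), erosion (detach
   spurious attachments), and a second closing with a larger disk;
4. Canny edges near the mask are united with it and interior holes filled;
5. up to the two largest non-border components are kept as the lung fields;
6. the final mask gates the image, zeroing everything outside the lungs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, feature, measure, morphology

from .errors import ValidationError
from .image_core import validate_gray


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the lung-field segmentation stage.

    ``clahe_clip_limit`` follows the common contrast-limiting convention of a
    multiple of the mean tile-histogram bin height (2.0 = each bin may hold at
    most twice the uniform share before the excess is redistributed).
    ``close2_radius`` must exceed ``close1_radius``: the second closing uses a
    strictly larger disk to re-seal discontinuities introduced by erosion.
    """

    clahe_clip_limit: float = 2.0
    clahe_tile_grid: int = 8
    binarize_threshold: int = 128
    lungs_are_dark: bool = True
    close1_radius: int = 3
    erode_radius: int = 2
    close2_radius: int = 7
    edge_method: str = "canny"
    canny_low: float = 50.0
    canny_high: float = 150.0
    edge_search_radius: int = 2
    min_component_area: int = 500
    border_exclusion: bool = True
    mask_enhanced: bool = False  # gate the CLAHE image instead of the raw one

    def __post_init__(self):
        if not 0 <= self.binarize_threshold <= 255:
            raise ValidationError("binarize_threshold must lie in [0,255]")
        if self.close2_radius <= self.close1_radius:
            raise ValidationError("close2_radius must exceed close1_radius")
        if self.clahe_clip_limit <= 0:
            raise ValidationError("clahe_clip_limit must be positive")
        if self.edge_method not in ("canny", "sobel"):
            raise ValidationError(f"unknown edge method {self.edge_method!r}")


def validate_mask(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    """Check a {0,1} binary mask and return it as uint8."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError(f"{name} must contain only 0/1 values")
    return arr.astype(np.uint8)


def apply_clahe(image: np.ndarray, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit image.

    The tile grid is ``clahe_tile_grid`` per side; the clip factor is
    converted to the per-bin pixel fraction the underlying implementation
    expects (factor / nbins with 256 bins).
    """
    image = validate_gray(image)
    h, w = image.shape
    if params.clahe_tile_grid > min(h, w):
        raise ValidationError(
            f"tile grid {params.clahe_tile_grid} exceeds image side {min(h, w)}"
        )
    if image.min() == image.max():
        # no contrast to redistribute: constant in, constant out
        return image.copy()
    kernel = (max(h // params.clahe_tile_grid, 1), max(w // params.clahe_tile_grid, 1))
    out = exposure.equalize_adapthist(
        image, kernel_size=kernel, clip_limit=params.clahe_clip_limit / 256.0, nbins=256
    )
    return np.rint(out * 255).clip(0, 255).astype(np.uint8)


def binarize(image: np.ndarray, threshold: int, lungs_are_dark: bool = True) -> np.ndarray:
    """Fixed-threshold binarization.

    With ``lungs_are_dark`` (default) a pixel is foreground iff its intensity
    is strictly below the threshold; otherwise iff at or above it.
    """
    image = validate_gray(image)
    if not 0 <= threshold <= 255:
        raise ValidationError("threshold must lie in [0,255]")
    if lungs_are_dark:
        return (image < threshold).astype(np.uint8)
    return (image >= threshold).astype(np.uint8)


def _check_radius(radius: int, shape, name: str):
    if radius >= min(shape) // 2:
        raise ValidationError(
            f"{name} radius {radius} is >= half the image side {min(shape)}"
        )


def refine_mask(mask: np.ndarray, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Morphological refinement: closing, erosion, then a larger-disk closing."""
    mask = validate_mask(mask)
    for r, name in (
        (params.close1_radius, "close1"),
        (params.erode_radius, "erode"),
        (params.close2_radius, "close2"),
    ):
        _check_radius(r, mask.shape, name)
    out = mask.astype(bool)
    out = morphology.closing(out, morphology.disk(params.close1_radius))
    out = morphology.erosion(out, morphology.disk(params.erode_radius))
    out = morphology.closing(out, morphology.disk(params.close2_radius))
    return out.astype(np.uint8)


def detect_edges(image: np.ndarray, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Boundary map of the (enhanced) image, as a {0,1} mask."""
    image = validate_gray(image)
    if params.edge_method == "canny":
        edges = feature.canny(
            image.astype(np.float64),
            low_threshold=params.canny_low,
            high_threshold=params.canny_high,
        )
    else:
        from skimage import filters

        mag = filters.sobel(image.astype(np.float64) / 255.0)
        edges = mag > (params.canny_high / 255.0) / 4.0
    return edges.astype(np.uint8)


def _fill_enclosed_holes(mask: np.ndarray) -> np.ndarray:
    """Fill 0-regions enclosed by exactly one foreground component.

    A plain border-connected-complement fill is wrong once the dark free
    background is itself foreground (the dark-mode threshold makes it so):
    the body wall then sits between two foreground regions and would be
    annexed wholesale.  Requiring a unique enclosing component fills genuine
    interior holes (e.g. a bright nodule punched out of a lung field) while
    leaving multi-neighbor gaps such as the body wall alone.
    """
    fg_labels = measure.label(mask, connectivity=2)
    hole_labels, n_holes = ndimage.label(~mask)
    if n_holes == 0:
        return mask.copy()
    border = np.zeros_like(mask, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_holes = set(np.unique(hole_labels[border & ~mask]))
    out = mask.copy()
    for obj_slice, lbl in zip(ndimage.find_objects(hole_labels), range(1, n_holes + 1)):
        if lbl in border_holes or obj_slice is None:
            continue
        sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(obj_slice, mask.shape)
        )
        region = hole_labels[sl] == lbl
        ring = ndimage.binary_dilation(region) & ~region
        neighbors = np.unique(fg_labels[sl][ring])
        neighbors = neighbors[neighbors != 0]
        if len(neighbors) == 1:
            out[sl][region] = True
    return out


def edge_fill(
    mask: np.ndarray,
    image: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
) -> np.ndarray:
    """Unite nearby image edges with the mask and fill interior holes.

    Only edge pixels within ``edge_search_radius`` of the current mask are
    annexed — distant closed contours (e.g. the body outline) must not turn
    into fillable "holes".  The union-and-fill step is iterated to a fixed
    point, which makes the operation extensive (output contains input) and
    idempotent by construction; it converges quickly because the mask grows
    monotonically.
    """
    mask = validate_mask(mask)
    image = validate_gray(image)
    if mask.shape != image.shape:
        raise ValidationError(f"mask shape {mask.shape} != image shape {image.shape}")
    edges = detect_edges(image, params).astype(bool)
    selem = morphology.disk(params.edge_search_radius)
    current = mask.astype(bool)
    for _ in range(64):  # monotone growth: terminates long before this bound
        near = ndimage.binary_dilation(current, structure=selem)
        grown = _fill_enclosed_holes(current | (edges & near))
        if np.array_equal(grown, current):
            break
        current = grown
    return current.astype(np.uint8)


def select_lung_components(
    mask: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> np.ndarray:
    """Keep up to the two largest components, as the two lung fields.

    Components touching the image border are discarded when
    ``border_exclusion`` is on (the background and body wall always touch the
    border in an axial slice); components below ``min_component_area`` are
    noise.  An empty result is allowed and signals segmentation failure to
    the caller.
    """
    mask = validate_mask(mask)
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(mask)
    h, w = mask.shape
    border_labels = set(np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]
    ])))
    candidates = []
    for region in measure.regionprops(labels):
        if params.border_exclusion and region.label in border_labels:
            continue
        if region.area < params.min_component_area:
            continue
        candidates.append((region.area, region.label))
    candidates.sort(reverse=True)
    keep = {lbl for _, lbl in candidates[:2]}
    return np.isin(labels, list(keep)).astype(np.uint8) if keep else np.zeros_like(mask)


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Gate an image with a binary mask: keep pixels where mask=1, else 0."""
    image = validate_gray(image)
    mask = validate_mask(mask)
    if image.shape != mask.shape:
        raise ValidationError(f"image shape {image.shape} != mask shape {mask.shape}")
    return (image * mask).astype(np.uint8)


def segment_lungs(
    image: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Full lung-field segmentation; returns (masked image, final mask).

    The mask is superimposed on the raw input image by default
    (``mask_enhanced`` gates the CLAHE output instead).  An empty final mask
    produces an all-zero image and a warning; the pipeline continues so that
    downstream stages and ablations see the failure rather than an exception.
    """
    image = validate_gray(image)
    enhanced = apply_clahe(image, params)
    mask = binarize(enhanced, params.binarize_threshold, params.lungs_are_dark)
    mask = refine_mask(mask, params)
    mask = edge_fill(mask, enhanced, params)
    mask = select_lung_components(mask, params)
    if mask.sum() == 0:
        warnings.warn("lung segmentation produced an empty mask")
    source = enhanced if params.mask_enhanced else image
    return apply_mask(source, mask), mask
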