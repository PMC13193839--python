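"""Nodule-focused masking: retain low-intensity candidate pixels.

After lung-field segmentation, pixels whose intensity is strictly below a
fixed threshold (default 140) are marked as potential nodule regions and all
other pixels are zeroed.  This does not detect nodules clinically — it biases
the classifier's input toward plausible lesion intensities.

Two guards keep the rule meaningful on a segmented image whose background is
already zeroed: candidates are restricted to the lung-field mask, and exact
zeros (the suppressed background) are excluded even though 0 < 140.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .image_core import validate_gray
from .segmentation import apply_mask, validate_mask


@dataclass(frozen=True)
class NoduleMaskParams:
    candidate_threshold: int = 140
    restrict_to_lung: bool = True
    exclude_zero_background: bool = True

    def __post_init__(self):
        if not 0 < self.candidate_threshold <= 255:
            raise ValidationError("candidate_threshold must lie in (0,255]")


def candidate_mask(
    segmented: np.ndarray,
    lung_mask: np.ndarray | None = None,
    params: NoduleMaskParams = NoduleMaskParams(),
) -> np.ndarray:
    """Binary mask of candidate-nodule pixels.

    A pixel is a candidate iff its intensity is strictly below
    ``candidate_threshold``, it is nonzero (when ``exclude_zero_background``),
    and it lies inside ``lung_mask`` (when ``restrict_to_lung`` and a mask is
    given).
    """
    segmented = validate_gray(segmented)
    out = segmented < params.candidate_threshold
    if params.exclude_zero_background:
        out &= segmented > 0
    if params.restrict_to_lung and lung_mask is not None:
        lung_mask = validate_mask(lung_mask)
        if lung_mask.shape != segmented.shape:
            raise ValidationError(
                f"lung mask shape {lung_mask.shape} != image shape {segmented.shape}"
            )
        out &= lung_mask.astype(bool)
    return out.astype(np.uint8)


def apply_candidate_mask(segmented: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero all pixels outside the candidate mask (elementwise gate)."""
    return apply_mask(segmented, mask)


def nodule_focus(
    segmented: np.ndarray,
    lung_mask: np.ndarray | None = None,
    params: NoduleMaskParams = NoduleMaskParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience composition: candidate mask + gating; returns (image, mask)."""
    mask = candidate_mask(segmented, lung_mask, params)
    return apply_candidate_mask(segmented, mask), mask
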