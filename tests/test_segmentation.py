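import numpy as np
import pytest
from scipy import ndimage
from skimage import morphology

from lungct.errors import ValidationError
from lungct.segmentation import (
    SegmentationParams,
    apply_clahe,
    apply_mask,
    binarize,
    edge_fill,
    refine_mask,
    segment_lungs,
    select_lung_components,
)

PARAMS = SegmentationParams()


def iou(a, b):
    a, b = a.astype(bool), b.astype(bool)
    return (a & b).sum() / max((a | b).sum(), 1)


class TestClahe:
    def test_constant_image_stays_constant(self):
        out = apply_clahe(np.full((64, 64), 100, dtype=np.uint8), PARAMS)
        assert out.min() == out.max()

    def test_two_region_intensity_gap_does_not_shrink(self):
        img = np.full((128, 128), 40, dtype=np.uint8)
        img[:, 64:] = 60
        out = apply_clahe(img, PARAMS)
        gap_before = 20
        gap_after = float(out[:, 96:].mean() - out[:, :32].mean())
        assert gap_after >= gap_before

    def test_lung_interior_contrast_increases(self, oracle_phantoms):
        rec = oracle_phantoms[0]
        out = apply_clahe(rec.image, PARAMS)
        lung = rec.lung_mask.astype(bool)
        assert out[lung].std() > rec.image[lung].std()

    def test_tile_grid_larger_than_image_rejected(self):
        with pytest.raises(ValidationError):
            apply_clahe(np.zeros((4, 4), dtype=np.uint8), SegmentationParams(clahe_tile_grid=8))


class TestBinarize:
    def test_strict_inequality_at_threshold(self):
        img = np.array([[10, 200], [128, 127]], dtype=np.uint8)
        assert np.array_equal(binarize(img, 128, True), [[1, 0], [0, 1]])

    def test_bright_constant_gives_empty_dark_mask(self):
        img = np.full((8, 8), 255, dtype=np.uint8)
        assert binarize(img, 255, True).sum() == 0

    def test_polarity_flip(self):
        img = np.array([[10, 200]], dtype=np.uint8)
        assert np.array_equal(binarize(img, 128, False), [[0, 1]])

    def test_most_lung_pixels_foreground_after_enhancement(self, oracle_phantoms):
        rec = oracle_phantoms[0]
        enhanced = apply_clahe(rec.image, PARAMS)
        mask = binarize(enhanced, PARAMS.binarize_threshold, True)
        lung = rec.lung_mask.astype(bool)
        assert (mask.astype(bool) & lung).sum() / lung.sum() >= 0.95


class TestRefineMask:
    def test_empty_mask_stays_empty(self):
        assert refine_mask(np.zeros((64, 64), dtype=np.uint8), PARAMS).sum() == 0

    def test_cracked_disk_is_healed(self):
        mask = np.zeros((128, 128), dtype=np.uint8)
        yy, xx = np.mgrid[0:128, 0:128]
        mask[(yy - 64) ** 2 + (xx - 64) ** 2 <= 50**2] = 1
        mask[:, 64] = 0  # 1-px crack splits the disk
        assert ndimage.label(mask)[1] == 2
        out = refine_mask(mask, PARAMS)
        assert ndimage.label(out)[1] == 1

    def test_area_shrinks_by_erosion_ring_only(self):
        mask = np.zeros((128, 128), dtype=np.uint8)
        yy, xx = np.mgrid[0:128, 0:128]
        mask[(yy - 64) ** 2 + (xx - 64) ** 2 <= 50**2] = 1
        out = refine_mask(mask, PARAMS)
        oracle = morphology.erosion(mask.astype(bool), morphology.disk(PARAMS.erode_radius))
        # closings are no-ops on a solid disk, so refinement equals the erosion
        assert np.array_equal(out.astype(bool), oracle)

    def test_closing_is_idempotent(self):
        rng = np.random.default_rng(0)
        mask = (rng.random((96, 96)) < 0.4).astype(bool)
        selem = morphology.disk(3)
        once = morphology.closing(mask, selem)
        twice = morphology.closing(once, selem)
        assert np.array_equal(once, twice)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValidationError):
            refine_mask(np.zeros((10, 10), dtype=np.uint8), PARAMS)


class TestEdgeFill:
    def test_interior_hole_filled_exactly(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[10:50, 10:50] = 1
        mask[20:25, 20:25] = 0
        image = np.full((64, 64), 77, dtype=np.uint8)  # no edges
        out = edge_fill(mask, image, PARAMS)
        assert out.sum() == mask.sum() + 25

    def test_extensive_and_hole_free(self):
        rng = np.random.default_rng(1)
        mask = (rng.random((64, 64)) < 0.3).astype(np.uint8)
        image = np.full((64, 64), 10, dtype=np.uint8)
        out = edge_fill(mask, image, PARAMS)
        assert np.all(out >= mask)

    def test_all_ones_is_fixed_point(self):
        mask = np.ones((32, 32), dtype=np.uint8)
        image = np.zeros((32, 32), dtype=np.uint8)
        assert np.array_equal(edge_fill(mask, image, PARAMS), mask)

    def test_idempotent_on_phantom(self, oracle_phantoms):
        rec = oracle_phantoms[1]
        enhanced = apply_clahe(rec.image, PARAMS)
        mask = refine_mask(binarize(enhanced, 128, True), PARAMS)
        once = edge_fill(mask, enhanced, PARAMS)
        twice = edge_fill(once, enhanced, PARAMS)
        assert np.array_equal(once, twice)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            edge_fill(np.zeros((4, 4), dtype=np.uint8), np.zeros((5, 5), dtype=np.uint8))


class TestSelectComponents:
    @staticmethod
    def _blob(mask, cy, cx, r):
        yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 1

    def test_two_largest_interior_blobs_retained(self):
        mask = np.zeros((256, 256), dtype=np.uint8)
        self._blob(mask, 64, 64, 40)   # ~5000 px
        self._blob(mask, 64, 192, 36)  # ~4000 px
        self._blob(mask, 192, 128, 14) # ~600 px
        out = select_lung_components(mask, PARAMS)
        assert ndimage.label(out)[1] == 2
        assert out[192, 128] == 0 and out[64, 64] == 1 and out[64, 192] == 1

    def test_border_touching_frame_removed(self):
        mask = np.zeros((256, 256), dtype=np.uint8)
        mask[0:4, :] = 1  # frame strip touching the border
        self._blob(mask, 128, 80, 30)
        self._blob(mask, 128, 176, 30)
        out = select_lung_components(mask, PARAMS)
        assert out[0, 0] == 0
        assert ndimage.label(out)[1] == 2

    def test_empty_input_allowed(self):
        out = select_lung_components(np.zeros((32, 32), dtype=np.uint8), PARAMS)
        assert out.sum() == 0


class TestApplyMask:
    def test_all_ones_identity_and_all_zero_annihilation(self):
        img = np.array([[50, 60], [70, 80]], dtype=np.uint8)
        assert np.array_equal(apply_mask(img, np.ones((2, 2), dtype=np.uint8)), img)
        assert apply_mask(img, np.zeros((2, 2), dtype=np.uint8)).sum() == 0

    def test_elementwise_gate(self):
        img = np.array([[50, 60], [70, 80]], dtype=np.uint8)
        mask = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        assert np.array_equal(apply_mask(img, mask), [[50, 0], [0, 80]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            apply_mask(np.zeros((2, 2), dtype=np.uint8), np.zeros((3, 3), dtype=np.uint8))


class TestSegmentLungs:
    def test_phantom_mask_recovers_ground_truth(self, phantom_spec):
        from lungct.phantom import generate_phantom

        rec = generate_phantom(phantom_spec, "Malignant", seed=3)
        _, mask = segment_lungs(rec.image, PARAMS)
        assert iou(mask, rec.lung_mask) >= 0.80

    def test_structureless_image_gives_empty_output(self):
        img = np.full((512, 512), 90, dtype=np.uint8)
        with pytest.warns(UserWarning, match="empty mask"):
            masked, mask = segment_lungs(img, PARAMS)
        assert mask.sum() == 0 and masked.sum() == 0

    def test_output_zero_outside_mask(self, oracle_phantoms):
        rec = oracle_phantoms[2]
        masked, mask = segment_lungs(rec.image, PARAMS)
        assert not masked[mask == 0].any()
        assert set(np.unique(mask)) <= {0, 1}
        assert mask.shape == rec.image.shape
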