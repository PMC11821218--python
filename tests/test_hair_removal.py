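"""Morphology pipeline: closing properties, mask contracts, repainting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dermocad import hair_removal as hr
from dermocad.segmentation import dice_coefficient

random_gray = arrays(np.uint8, (32, 32), elements=st.integers(0, 255))


class TestRgbToGray:
    @pytest.mark.parametrize("pixel,expected", [
        ((255, 255, 255), 255),
        ((0, 0, 0), 0),
        ((255, 0, 0), 76),  # round(255 * 0.299)
    ])
    def test_closed_form_values(self, pixel, expected):
        img = np.full((2, 2, 3), pixel, dtype=np.uint8)
        assert np.all(hr.rgb_to_gray(img) == expected)

    def test_weights_must_sum_to_one(self, smooth_lesion):
        img, _, _ = smooth_lesion
        with pytest.raises(ValueError, match="sum to 1"):
            hr.rgb_to_gray(img, (0.5, 0.5, 0.5))


class TestMorphologicalClose:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(random_gray)
    def test_extensive_and_idempotent(self, gray):
        for se in (hr.StructuringElement("line", 15, 45.0),
                   hr.StructuringElement("disk", 2)):
            closed = hr.morphological_close(gray, se)
            assert np.all(closed >= gray)
            assert np.array_equal(hr.morphological_close(closed, se), closed)

    def test_constant_image_unchanged(self):
        gray = np.full((24, 24), 120, dtype=np.uint8)
        se = hr.StructuringElement("line", 15, 0.0)
        assert np.array_equal(hr.morphological_close(gray, se), gray)

    def test_thin_dark_line_raised_to_background(self):
        gray = np.full((40, 40), 200, dtype=np.uint8)
        gray[20, :] = 40  # 1-px dark horizontal line
        se = hr.StructuringElement("line", 15, 90.0)  # vertical SE crosses it
        closed = hr.morphological_close(gray, se)
        assert np.all(closed[20, :] == 200)

    @settings(max_examples=5, deadline=None, derandomize=True)
    @given(random_gray)
    def test_matches_bruteforce_two_pass_oracle(self, gray):
        """Dilation then erosion computed by explicit loops over the SE."""
        se = hr.StructuringElement("line", 7, 45.0)
        fp = se.footprint()
        offsets = [(r - fp.shape[0] // 2, c - fp.shape[1] // 2)
                   for r, c in np.argwhere(fp)]
        h, w = gray.shape

        def sweep(img, agg, pad):
            out = np.empty_like(img)
            for r in range(h):
                for c in range(w):
                    vals = [img[r + dr, c + dc]
                            if 0 <= r + dr < h and 0 <= c + dc < w else pad
                            for dr, dc in offsets]
                    out[r, c] = agg(vals)
            return out

        # the line SE is 180-degree symmetric, so dilation's reflected
        # footprint equals the footprint itself
        dil = sweep(gray, max, 0)
        oracle = sweep(dil, min, 255)
        assert np.array_equal(hr.morphological_close(gray, se), oracle)

    def test_se_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="larger than the image"):
            hr.morphological_close(np.zeros((8, 8), dtype=np.uint8),
                                   hr.StructuringElement("line", 15, 0.0))


class TestHairDifference:
    def test_constant_image_gives_zero_and_nonnegativity(self, rng):
        gray = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        se = hr.StructuringElement("line", 15, 0.0)
        diff = hr.hair_difference(hr.morphological_close(gray, se), gray)
        assert diff.min() >= 0
        flat = np.full((16, 16), 99, dtype=np.uint8)
        assert np.all(hr.hair_difference(flat, flat) == 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            hr.hair_difference(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_difference_covers_true_hair_pixels(self, hairy_lesion):
        hairy, hair_mask = hairy_lesion
        gray = hr.rgb_to_gray(hairy)
        closed = np.zeros_like(gray)
        for se in hr.HairRemovalConfig().closing_elements:
            np.maximum(closed, hr.morphological_close(gray, se), out=closed)
        diff = hr.hair_difference(closed, gray)
        covered = (diff[hair_mask] > 0).mean()
        assert covered >= 0.7


class TestBinarizeAndDilate:
    def test_zero_diff_gives_empty_mask(self):
        cfg = hr.HairRemovalConfig()
        assert not hr.binarize_and_dilate(np.zeros((16, 16), dtype=np.int16), cfg).any()

    def test_single_pixel_becomes_dilated_footprint(self):
        cfg = hr.HairRemovalConfig()
        diff = np.zeros((16, 16), dtype=np.int16)
        diff[8, 8] = 30  # above T = 25
        mask = hr.binarize_and_dilate(diff, cfg)
        fp = cfg.dilation_element.footprint()
        expected = np.zeros_like(mask)
        expected[8 - 2:8 + 3, 8 - 2:8 + 3] = fp
        assert np.array_equal(mask, expected)

    def test_dilation_never_shrinks_support(self, rng):
        cfg = hr.HairRemovalConfig()
        diff = rng.integers(0, 60, size=(32, 32)).astype(np.int16)
        before = diff > cfg.threshold_T
        after = hr.binarize_and_dilate(diff, cfg)
        assert np.all(after[before])


class TestInpaintHairs:
    def test_empty_mask_is_identity(self, smooth_lesion):
        img, _, _ = smooth_lesion
        out = hr.inpaint_hairs(img, np.zeros(img.shape[:2], dtype=bool))
        assert np.array_equal(out, img)

    def test_constant_image_any_mask_unchanged(self, rng):
        img = np.full((24, 24, 3), 140, dtype=np.uint8)
        mask = rng.random((24, 24)) < 0.3
        assert np.array_equal(hr.inpaint_hairs(img, mask), img)

    def test_full_mask_rejected(self, smooth_lesion):
        img, _, _ = smooth_lesion
        with pytest.raises(ValueError, match="no donor pixels"):
            hr.inpaint_hairs(img, np.ones(img.shape[:2], dtype=bool))

    def test_repaint_close_to_hair_free_original(self, smooth_lesion, hairy_lesion):
        clean, _, _ = smooth_lesion
        hairy, hair_mask = hairy_lesion
        out = hr.inpaint_hairs(hairy, hair_mask)
        err = np.abs(out[hair_mask].astype(float) - clean[hair_mask].astype(float))
        assert err.mean() < 10


class TestRemoveHairlines:
    def test_hair_free_image_keeps_mask_sparse(self, smooth_lesion):
        img, _, _ = smooth_lesion
        _, mask = hr.remove_hairlines(img)
        assert mask.mean() < 0.01

    def test_unmasked_pixels_bit_identical(self, hairy_lesion):
        hairy, _ = hairy_lesion
        out, mask = hr.remove_hairlines(hairy)
        assert np.array_equal(out[~mask], hairy[~mask])

    def test_detection_dice_against_ground_truth(self, hairy_lesion):
        hairy, truth = hairy_lesion
        _, det = hr.remove_hairlines(hairy)
        assert dice_coefficient(det, truth) >= 0.7
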