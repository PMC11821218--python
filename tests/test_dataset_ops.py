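"""Dedup, stratified split, oversampling and augmentation contracts."""

import numpy as np
import pandas as pd
import pytest

from dermocad import dataset_ops as dops
from dermocad import synthetic


@pytest.fixture(scope="module")
def dup_dataset():
    return synthetic.generate_dataset(6, 6, 0.25, seed=9, image_size=(96, 96))


class TestPearsonCorrelation:
    def test_identical_and_inverted_images(self, smooth_lesion):
        img, _, _ = smooth_lesion
        assert dops.pearson_correlation(img, img) == pytest.approx(1.0)
        assert dops.pearson_correlation(img, 255 - img) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        a = rng.integers(0, 256, size=(256, 256)).astype(np.uint8)
        b = rng.integers(0, 256, size=(256, 256)).astype(np.uint8)
        x, y = a.astype(float).ravel(), b.astype(float).ravel()
        oracle = (((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std()))
        assert dops.pearson_correlation(a, b) == pytest.approx(oracle, abs=1e-10)

    def test_constant_image_warns_and_returns_zero(self):
        const = np.full((64, 64), 7, dtype=np.uint8)
        other = (np.arange(64 * 64).reshape(64, 64) % 256).astype(np.uint8)
        with pytest.warns(RuntimeWarning, match="constant image"):
            assert dops.pearson_correlation(const, other) == 0.0


class TestDeduplicate:
    def test_flagged_duplicates_removed_originals_kept(self, dup_dataset):
        images, index, _ = dup_dataset
        n_dup = (index["is_duplicate_of"] != "").sum()
        assert n_dup == 3  # round(0.25 * 12)
        out = dops.deduplicate(index, images)
        assert len(out) == len(index) - n_dup
        # every original of a flagged duplicate survives
        sources = set(index.loc[index["is_duplicate_of"] != "", "is_duplicate_of"])
        assert sources <= set(out["path"])

    def test_duplicate_free_set_unchanged(self):
        images, index, _ = synthetic.generate_dataset(4, 4, 0.0, seed=1)
        out = dops.deduplicate(index, images)
        pd.testing.assert_frame_equal(out, index)

    def test_transitive_group_keeps_single_representative(self, smooth_lesion):
        img, _, _ = smooth_lesion
        trio = {
            "a.png": img,
            "b.png": synthetic.make_near_duplicate(img, 1.0, seed=1),
            "c.png": synthetic.make_near_duplicate(img, 1.0, seed=2),
        }
        index = pd.DataFrame({"path": list(trio), "label": ["MEL"] * 3,
                              "patient_id": ["p"] * 3, "is_duplicate_of": [""] * 3})
        out = dops.deduplicate(index, trio)
        assert out["path"].tolist() == ["a.png"]

    def test_idempotent(self, dup_dataset):
        images, index, _ = dup_dataset
        once = dops.deduplicate(index, images)
        twice = dops.deduplicate(once, images)
        pd.testing.assert_frame_equal(once, twice)


class TestStratifiedSplit:
    @pytest.mark.parametrize("total,expected", [
        (5789, (4052, 579, 1158)),   # published MEL row
        (7093, (4965, 709, 1419)),   # published BEN row
        (10, (7, 1, 2)),
    ])
    def test_largest_remainder_counts(self, total, expected):
        assert tuple(dops._largest_remainder(total, (0.7, 0.1, 0.2))) == expected

    def test_assignment_counts_and_conservation(self):
        index = pd.DataFrame({
            "path": [f"{i}.png" for i in range(50)],
            "label": ["MEL"] * 23 + ["BEN"] * 27,
            "patient_id": [""] * 50, "is_duplicate_of": [""] * 50})
        out = dops.stratified_split(index, seed=4)
        for label, n in (("MEL", 23), ("BEN", 27)):
            counts = out[out["label"] == label]["split"].value_counts()
            assert counts.sum() == n
            expected = dops._largest_remainder(n, (0.7, 0.1, 0.2))
            assert [counts.get(s, 0) for s in ("train", "val", "test")] == expected

    def test_tiny_class_rejected_and_fraction_check(self):
        index = pd.DataFrame({"path": ["a", "b"], "label": ["MEL", "MEL"],
                              "patient_id": ["", ""], "is_duplicate_of": ["", ""]})
        with pytest.raises(ValueError, match="fewer than 3"):
            dops.stratified_split(index)
        with pytest.raises(ValueError, match="sum to 1"):
            dops.stratified_split(index, fractions=(0.5, 0.2, 0.2))


class TestRandomOversample:
    def test_published_training_counts(self):
        train = pd.DataFrame({
            "path": [f"{i}" for i in range(9017)],
            "label": ["MEL"] * 4052 + ["BEN"] * 4965,
            "split": ["train"] * 9017})
        out = dops.random_oversample(train, seed=0)
        assert (out["label"] == "MEL").sum() == 4965
        assert len(out) == 9930

    def test_balanced_input_unchanged_and_toy_counts(self):
        train = pd.DataFrame({"path": list("abcdefgh"),
                              "label": ["MEL"] * 4 + ["BEN"] * 4,
                              "split": ["train"] * 8})
        pd.testing.assert_frame_equal(dops.random_oversample(train), train)
        toy = pd.DataFrame({"path": list("abcdefgh"),
                            "label": ["MEL"] * 3 + ["BEN"] * 5,
                            "split": ["train"] * 8})
        out = dops.random_oversample(toy, seed=1)
        assert (out["label"] == "MEL").sum() == 5 and len(out) == 10

    def test_rejects_validation_or_test_rows(self):
        df = pd.DataFrame({"path": ["a", "b"], "label": ["MEL", "BEN"],
                           "split": ["train", "val"]})
        with pytest.raises(ValueError, match="train-only"):
            dops.random_oversample(df)


class TestAugment:
    def test_identity_configuration_returns_input(self, smooth_lesion):
        img, _, _ = smooth_lesion
        cfg = dops.AugmentationConfig(rotation_range=(0, 0), scale_x=1.0,
                                      translate_y=(0, 0), seed=0)
        assert np.array_equal(dops.augment(img, cfg), img)

    def test_pure_translation_shifts_impulse(self):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        img[10, 16] = 255
        cfg = dops.AugmentationConfig(rotation_range=(0, 0), scale_x=1.0,
                                      translate_y=(5, 5), seed=0)
        out = dops.augment(img, cfg)
        assert out[15, 16, 0] > 200
        assert out[10, 16, 0] < 50

    def test_same_seed_reproduces(self, smooth_lesion):
        img, _, _ = smooth_lesion
        cfg = dops.AugmentationConfig(seed=5)
        assert np.array_equal(dops.augment(img, cfg), dops.augment(img, cfg))
        cfg2 = dops.AugmentationConfig(seed=6)
        assert not np.array_equal(dops.augment(img, cfg), dops.augment(img, cfg2))

    def test_shape_preserved(self, smooth_lesion):
        img, _, _ = smooth_lesion
        out = dops.augment(img, dops.AugmentationConfig(seed=2))
        assert out.shape == img.shape and out.dtype == img.dtype
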