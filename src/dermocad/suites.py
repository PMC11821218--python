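"""Seeded evaluation suites.

Each function runs one self-contained, deterministic experiment at desk
scale and returns plain numbers.  The test suite and the reproduction
script both call these, so the reported quantities always come from the
same protocol.
"""

from __future__ import annotations

import numpy as np

from . import classification as cls
from . import contrast, hair_removal, pipeline, segmentation, synthetic
from .synthetic import BEN, MEL


def hair_detection_suite(seed: int = 0, n_images: int = 20,
                         image_size: tuple[int, int] = (128, 128)) -> dict:
    """Hair-mask quality over a seeded hairy suite (thickness 1-3 px).

    Returns the per-image Dice scores against the generator's ground-truth
    masks, the median Dice, and the mean absolute repaint error on the
    true hair pixels (vs the hair-free original).
    """
    rng = np.random.default_rng(seed)
    dices, mask_errors = [], []
    for i in range(n_images):
        label = MEL if i % 2 == 0 else BEN
        spec = synthetic.random_lesion_spec(rng, label, image_size)
        clean, _, _ = synthetic.generate_lesion_image(spec)
        hspec = synthetic.HairOverlaySpec(
            n_hairs=12, thickness_px=(1, 3), seed=int(rng.integers(0, 2 ** 31 - 1)))
        hairy, truth_mask = synthetic.add_hairs(clean, hspec)
        restored, det_mask = hair_removal.remove_hairlines(hairy)
        dices.append(segmentation.dice_coefficient(det_mask, truth_mask))
        err = np.abs(restored[truth_mask].astype(float)
                     - clean[truth_mask].astype(float))
        mask_errors.append(float(err.mean()))
    return {"dice": dices, "median_dice": float(np.median(dices)),
            "mean_inpaint_error": float(np.mean(mask_errors)), "n": n_images}


def atrous_oracle_suite(seed: int = 0, n_instances: int = 50) -> dict:
    """Dilated convolution vs a direct triple-loop summation oracle.

    Random small instances spanning rates {1, 2, 4, 8}; returns the
    maximum relative error.
    """
    rng = np.random.default_rng(seed)
    max_rel = 0.0
    for _ in range(n_instances):
        r = int(rng.choice([1, 2, 4, 8]))
        h, w = int(rng.integers(6, 17)), int(rng.integers(6, 17))
        cin, cout = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        fm = rng.normal(size=(h, w, cin))
        k = rng.normal(size=(3, 3, cin, cout))
        spec = segmentation.AtrousConvSpec(3, 3, cin, cout, r)
        got = segmentation.atrous_conv2d(fm, spec, k)
        want = _atrous_bruteforce(fm, k, r)
        scale = max(np.abs(want).max(), 1e-12)
        max_rel = max(max_rel, float(np.abs(got - want).max() / scale))
    return {"max_relative_error": max_rel, "n": n_instances}


def _atrous_bruteforce(fm: np.ndarray, kernel: np.ndarray, rate: int) -> np.ndarray:
    """Direct summation oracle: out(x,y,o) = sum I(x+i*r, y+j*r, k) K(i,j,k,o)
    with out-of-range taps reading zero."""
    h, w, cin = fm.shape
    kh, kw, _, cout = kernel.shape
    out = np.zeros((h, w, cout))
    for x in range(h):
        for y in range(w):
            for i in range(kh):
                for j in range(kw):
                    xi = x + (i - kh // 2) * rate
                    yj = y + (j - kw // 2) * rate
                    if 0 <= xi < h and 0 <= yj < w:
                        for k in range(cin):
                            out[x, y, :] += fm[xi, yj, k] * kernel[i, j, k, :]
    return out


def classifier_tiny_training_suite(seed: int = 0, n_train: int = 60,
                                   n_test: int = 20, epochs: int = 15) -> dict:
    """Train the default classifier on separable synthetics.

    60 clean training images (30/30) and 20 held-out images at the
    64x64 desk scale; returns train and held-out accuracy.
    """
    rng = np.random.default_rng(seed)
    def batch(n):
        imgs, labels = [], []
        for i in range(n):
            label = MEL if i % 2 == 0 else BEN
            spec = synthetic.random_lesion_spec(rng, label, (64, 64))
            img, _, _ = synthetic.generate_lesion_image(spec)
            imgs.append(img)
            labels.append(label)
        return imgs, labels

    train_imgs, train_labels = batch(n_train)
    test_imgs, test_labels = batch(n_test)
    model = cls.build_ndcnn(cls.NDCNNSpec(input_shape=(64, 64, 3)), seed=seed)
    cfg = cls.NDCNNTrainConfig(epochs=epochs, batch_size=16)
    history = cls.train_ndcnn(model, train_imgs, train_labels, cfg, seed=seed)
    _, train_pred = cls.predict_batch(model, train_imgs)
    _, test_pred = cls.predict_batch(model, test_imgs)
    train_acc = float(np.mean([p == t for p, t in zip(train_pred, train_labels)]))
    test_acc = float(np.mean([p == t for p, t in zip(test_pred, test_labels)]))
    return {"train_accuracy": train_acc, "test_accuracy": test_acc,
            "history": history, "n": n_train + n_test}


def segmentation_tiny_training_suite(seed: int = 0, n_train: int = 20,
                                     n_test: int = 10, epochs: int = 20) -> dict:
    """Train the default-width ACNN at 48x64 scale; held-out median Dice."""
    rng = np.random.default_rng(seed)
    def batch(n):
        imgs, masks = [], []
        for i in range(n):
            label = MEL if i % 2 == 0 else BEN
            spec = synthetic.random_lesion_spec(rng, label, (48, 64))
            img, mask, _ = synthetic.generate_lesion_image(spec)
            imgs.append(img)
            masks.append(mask.astype(np.uint8))
        return imgs, masks

    train_imgs, train_masks = batch(n_train)
    test_imgs, test_masks = batch(n_test)
    spec = segmentation.ACNNSpec(input_shape=(48, 64, 3))
    model = segmentation.build_acnn(spec, seed=seed)
    cfg = segmentation.ACNNTrainConfig(epochs=epochs, batch_size=4)
    history = segmentation.train_acnn(model, train_imgs, train_masks, cfg, seed=seed)
    dices = [segmentation.dice_coefficient(segmentation.segment(model, img), truth)
             for img, truth in zip(test_imgs, test_masks)]
    return {"median_dice": float(np.median(dices)), "dice": dices,
            "history": history, "n": n_train + n_test}


def contrast_tiny_training_suite(seed: int = 0, n_train: int = 30,
                                 n_test: int = 20, epochs: int = 12,
                                 patch: int = 32) -> dict:
    """Train the contrast network on degraded/clean pairs; count the
    fraction of held-out images whose RMSE to the clean original improves
    after enhancement."""
    rng = np.random.default_rng(seed)

    def make_clean(n, size):
        out = []
        for i in range(n):
            label = MEL if i % 2 == 0 else BEN
            spec = synthetic.random_lesion_spec(rng, label, size)
            img, _, _ = synthetic.generate_lesion_image(spec)
            out.append(img)
        return out

    def sampler(im, rng_):
        return synthetic.degrade_contrast(
            im, rng_.uniform(*synthetic.DEGRADE_GAMMA),
            rng_.uniform(*synthetic.DEGRADE_GAIN))

    train = make_clean(n_train, (patch, patch))
    model = contrast.build_mcan(contrast.MCANSpec(patch_size=patch), seed=seed)
    history = contrast.train_mcan(model, train, sampler, epochs=epochs, seed=seed)

    test_clean = make_clean(n_test, (64, 64))
    improved = 0
    rmse_pairs = []
    for img in test_clean:
        degraded = sampler(img, rng)
        enhanced = contrast.enhance(model, degraded)
        rmse_deg = float(np.sqrt(np.mean(
            (degraded.astype(float) - img.astype(float)) ** 2)))
        rmse_enh = float(np.sqrt(np.mean(
            (enhanced.astype(float) - img.astype(float)) ** 2)))
        rmse_pairs.append((rmse_deg, rmse_enh))
        improved += rmse_enh < rmse_deg
    return {"improved_fraction": improved / n_test, "rmse_pairs": rmse_pairs,
            "history": history, "n": n_test}


def two_arm_suite(seeds=(0, 1, 2), n_mel: int = 30, n_ben: int = 30) -> dict:
    """Raw vs preprocessed arm accuracy over several seeds."""
    rows = []
    for seed in seeds:
        raw, pre, table = pipeline.run_two_arm_experiment(
            seed=seed, n_mel=n_mel, n_ben=n_ben)
        rows.append({"seed": seed, "raw_acc": raw.report.acc,
                     "pre_acc": pre.report.acc})
    wins = sum(1 for r in rows if r["pre_acc"] >= r["raw_acc"])
    return {"rows": rows, "preprocessed_wins": wins, "n_seeds": len(rows)}
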