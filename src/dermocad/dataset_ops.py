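"""Dataset preparation: dedup by correlation, stratified split, oversampling
and training-set augmentation.

Near-duplicates (re-captures of the same lesion) are found by Pearson
correlation of grayscale images; pairs above 0.99 are grouped by transitive
closure and one representative per group (first by path order) is kept.
Splitting is stratified per class with largest-remainder apportionment of
the 70/10/20 fractions, so per-class counts are exact and sum to the class
total.  Random oversampling duplicates minority-class training records
(sampled with replacement) until the classes balance; validation and test
sets are never altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.transform import AffineTransform, resize, warp

from .hair_removal import rgb_to_gray

DEFAULT_FRACTIONS = (0.7, 0.1, 0.2)
DEFAULT_DUP_THRESHOLD = 0.99
CORRELATION_SIZE = (256, 256)


def pearson_correlation(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Pearson coefficient over flattened grayscale intensities.

    Images are converted to grayscale and resized to a common 256x256
    raster before comparison; a constant image (zero variance) yields 0
    with a warning.
    """
    def prep(img: np.ndarray) -> np.ndarray:
        if img.ndim == 3:
            img = rgb_to_gray(img)
        if img.shape != CORRELATION_SIZE:
            img = resize(img.astype(np.float64), CORRELATION_SIZE,
                         order=1, anti_aliasing=True)
        return img.astype(np.float64).ravel()

    x, y = prep(image_a), prep(image_b)
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant image in correlation; returning 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def deduplicate(index: pd.DataFrame, images: dict[str, np.ndarray],
                threshold: float = DEFAULT_DUP_THRESHOLD) -> pd.DataFrame:
    """Drop all but one representative of each correlated duplicate group.

    Pairs are compared within the same class label; duplicate groups are
    the connected components of the >threshold graph, and the first path
    (by original index order) in each group is kept.
    """
    paths = index["path"].tolist()
    n = len(paths)
    rows, cols = [], []
    for label in index["label"].unique():
        members = [i for i, (_, rec) in enumerate(index.iterrows())
                   if rec["label"] == label]
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                if pearson_correlation(images[paths[i]], images[paths[j]]) > threshold:
                    rows.append(i)
                    cols.append(j)
    if not rows:
        return index.copy()
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, comp = connected_components(adj, directed=False)
    keep = np.zeros(n, dtype=bool)
    seen: set[int] = set()
    for i in range(n):
        if comp[i] not in seen:
            seen.add(comp[i])
            keep[i] = True
    return index.iloc[keep].reset_index(drop=True)


def _largest_remainder(total: int, fractions: tuple[float, ...]) -> list[int]:
    """Integer apportionment of ``total`` by fractions, preserving the sum."""
    shares = [total * f for f in fractions]
    counts = [int(np.floor(s)) for s in shares]
    short = total - sum(counts)
    order = np.argsort([c - s for c, s in zip(counts, shares)])  # largest remainder first
    for i in order[:short]:
        counts[i] += 1
    return counts


def stratified_split(index: pd.DataFrame,
                     fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
                     seed: int = 0) -> pd.DataFrame:
    """Assign train/val/test per class with largest-remainder counts.

    Within each class the assignment of records to splits is randomized by
    ``seed``; counts follow the exact apportionment (e.g. a class of 5789
    images yields 4052/579/1158 at 70/10/20).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    out = index.copy()
    out["split"] = "none"
    for label, group in index.groupby("label", sort=True):
        n = len(group)
        if n < 3:
            raise ValueError(f"class {label!r} has fewer than 3 images; cannot split")
        n_train, n_val, n_test = _largest_remainder(n, fractions)
        perm = rng.permutation(n)
        pos = group.index.to_numpy()[perm]
        out.loc[pos[:n_train], "split"] = "train"
        out.loc[pos[n_train:n_train + n_val], "split"] = "val"
        out.loc[pos[n_train + n_val:], "split"] = "test"
    return out


def random_oversample(train_index: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Balance classes by duplicating minority records with replacement.

    Must be applied to the training split only; validation/test keep their
    original distribution.
    """
    if "split" in train_index.columns:
        bad = set(train_index["split"].unique()) - {"train"}
        if bad:
            raise ValueError(f"oversampling is train-only; found splits {sorted(bad)}")
    counts = train_index["label"].value_counts()
    if len(counts) < 2 or counts.iloc[0] == counts.iloc[-1]:
        return train_index.copy()
    rng = np.random.default_rng(seed)
    majority = int(counts.max())
    parts = [train_index]
    for label, c in counts.items():
        deficit = majority - int(c)
        if deficit > 0:
            pool = train_index[train_index["label"] == label]
            picks = rng.integers(0, len(pool), size=deficit)
            parts.append(pool.iloc[picks])
    return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class AugmentationConfig:
    """Training-time augmentation ranges.

    Rotation is drawn uniformly from ``rotation_range`` degrees, the image
    is scaled by ``scale_x`` along x, and translated by an integer drawn
    from ``translate_y`` pixels along y (rows).  Applied to the training
    split only.
    """

    rotation_range: tuple[float, float] = (-30.0, 30.0)
    scale_x: float = 0.8
    translate_y: tuple[int, int] = (-5, 5)
    seed: int = 0


def augment(image: np.ndarray, cfg: AugmentationConfig,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Seeded random rotate/scale/translate with reflect padding.

    The output has the input's shape and dtype.  An identity configuration
    (0 degrees, scale 1, translate 0) returns the input unchanged.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    angle = rng.uniform(*cfg.rotation_range)
    ty = int(rng.integers(cfg.translate_y[0], cfg.translate_y[1] + 1))
    if angle == 0.0 and cfg.scale_x == 1.0 and ty == 0:
        return image.copy()
    h, w = image.shape[:2]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tf = (AffineTransform(translation=-center)
          + AffineTransform(rotation=np.deg2rad(angle), scale=(cfg.scale_x, 1.0))
          + AffineTransform(translation=center)
          + AffineTransform(translation=(0, ty)))
    warped = warp(image.astype(np.float64), tf.inverse, mode="reflect",
                  order=1, preserve_range=True)
    return np.floor(np.clip(warped, 0, 255) + 0.5).astype(image.dtype)


def read_index(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def write_index(index: pd.DataFrame, path) -> None:
    index.to_csv(path, index=False)
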