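"""Hairline detection and occlusion by grayscale morphology.

Dark curvilinear hairs are detected as the difference between a grayscale
morphological closing and the original image: closing fills dark structures
thinner than the structuring element, so the difference is large exactly on
hairs.  The difference is thresholded (T = 25 on the 0-255 scale), the
binary mask is dilated to bridge gaps, refined, and the masked pixels are
repainted from their nearest unmasked neighbors.

The closing uses a bank of line structuring elements (length 15 at 0, 45,
90 and 135 degrees) combined by a per-pixel maximum, so hairs of any
orientation are straddled by at least one element (DullRazor-style).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

DEFAULT_THRESHOLD = 25.0
DEFAULT_GRAY_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class StructuringElement:
    """Line or disk footprint for grayscale morphology.

    ``length_or_radius`` is the line length (odd, so the anchor is
    centered) or the disk radius; ``orientation`` applies to lines only.
    """

    shape: str = "line"
    length_or_radius: int = 15
    orientation: float = 0.0

    def footprint(self) -> np.ndarray:
        if self.shape == "disk":
            r = int(self.length_or_radius)
            y, x = np.mgrid[-r:r + 1, -r:r + 1]
            return (x * x + y * y) <= r * r
        if self.shape == "line":
            length = int(self.length_or_radius)
            if length % 2 == 0:
                raise ValueError("line length must be odd so the anchor is centered")
            half = length // 2
            theta = np.deg2rad(self.orientation)
            fp = np.zeros((length, length), dtype=bool)
            for t in range(-half, half + 1):
                r = half + int(round(-t * np.sin(theta)))
                c = half + int(round(t * np.cos(theta)))
                fp[r, c] = True
            # trim all-zero borders so the footprint is as tight as possible
            rows = np.flatnonzero(fp.any(axis=1))
            cols = np.flatnonzero(fp.any(axis=0))
            fp = fp[rows.min():rows.max() + 1, cols.min():cols.max() + 1]
            if fp.shape[0] % 2 == 0:
                fp = np.pad(fp, ((0, 1), (0, 0)))
            if fp.shape[1] % 2 == 0:
                fp = np.pad(fp, ((0, 0), (0, 1)))
            return fp
        raise ValueError(f"unknown structuring element shape {self.shape!r}")


def _default_closing_bank() -> list[StructuringElement]:
    return [StructuringElement("line", 15, angle) for angle in (0.0, 45.0, 90.0, 135.0)]


@dataclass(frozen=True)
class HairRemovalConfig:
    closing_elements: tuple[StructuringElement, ...] = None  # type: ignore[assignment]
    threshold_T: float = DEFAULT_THRESHOLD
    dilation_element: StructuringElement = StructuringElement("disk", 2)
    grayscale_weights: tuple[float, float, float] = DEFAULT_GRAY_WEIGHTS

    def __post_init__(self):
        if self.closing_elements is None:
            object.__setattr__(self, "closing_elements",
                               tuple(_default_closing_bank()))
        if not 0 < self.threshold_T < 255:
            raise ValueError("threshold_T must lie strictly between 0 and 255")


def rgb_to_gray(image: np.ndarray,
                weights: tuple[float, float, float] = DEFAULT_GRAY_WEIGHTS) -> np.ndarray:
    """Weighted luma conversion to single-channel uint8 (round half-up)."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    w = np.asarray(weights, dtype=np.float64)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("grayscale weights must sum to 1")
    gray = image.astype(np.float64) @ w
    return np.floor(np.clip(gray, 0, 255) + 0.5).astype(np.uint8)


def morphological_close(gray: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Grayscale closing: dilation then erosion with the same footprint."""
    if gray.ndim != 2:
        raise ValueError("expected a single-channel image")
    fp = se.footprint()
    if fp.shape[0] > gray.shape[0] or fp.shape[1] > gray.shape[1]:
        raise ValueError("structuring element larger than the image")
    # adjoint dilation/erosion pair on the finite frame: pad with the
    # neutral element of each operation so closing stays extensive and
    # idempotent up to the border
    dilated = ndimage.maximum_filter(gray, footprint=fp[::-1, ::-1],
                                     mode="constant", cval=0)
    return ndimage.minimum_filter(dilated, footprint=fp,
                                  mode="constant", cval=255)


def hair_difference(close_img: np.ndarray, gray: np.ndarray) -> np.ndarray:
    """Closing minus original; nonnegative by extensivity of closing."""
    if close_img.shape != gray.shape:
        raise ValueError("shape mismatch between closed and original image")
    return close_img.astype(np.int16) - gray.astype(np.int16)


def binarize_and_dilate(diff: np.ndarray, cfg: HairRemovalConfig) -> np.ndarray:
    """Threshold the difference image and dilate to bridge gaps."""
    binary = diff > cfg.threshold_T
    if not binary.any():
        return binary
    return ndimage.binary_dilation(binary, structure=cfg.dilation_element.footprint())


def _refine_mask(binary: np.ndarray, dilated: np.ndarray,
                 se: StructuringElement) -> np.ndarray:
    """Erode the bridged mask back to hair width.

    Dilation followed by this erosion is a binary closing: gaps between
    detected hair fragments are bridged without a net widening of the
    mask, which keeps the detection close to the true (1-4 px) hair
    support.
    """
    eroded = ndimage.binary_erosion(dilated, structure=se.footprint())
    return eroded | binary


def inpaint_hairs(image: np.ndarray, mask: np.ndarray, k: int = 8) -> np.ndarray:
    """Repaint masked pixels from their nearest unmasked neighbors.

    Each masked pixel receives, per channel, the inverse-distance-weighted
    average of its ``k`` nearest unmasked pixels.  Unmasked pixels are
    returned bit-identical to the input.
    """
    if mask.shape != image.shape[:2]:
        raise ValueError("mask must align with the image")
    if not mask.any():
        return image.copy()
    if mask.all():
        raise ValueError("mask covers the entire image: no donor pixels")
    donors = np.argwhere(~mask)
    targets = np.argwhere(mask)
    tree = cKDTree(donors)
    k_eff = min(k, len(donors))
    dist, idx = tree.query(targets, k=k_eff)
    dist = np.atleast_2d(dist.T).T.astype(np.float64)
    idx = np.atleast_2d(idx.T).T
    wgt = 1.0 / np.maximum(dist, 1e-9)
    wgt /= wgt.sum(axis=1, keepdims=True)
    donor_vals = image[donors[:, 0], donors[:, 1], :].astype(np.float64)
    filled = np.einsum("tk,tkc->tc", wgt, donor_vals[idx])
    out = image.copy()
    out[targets[:, 0], targets[:, 1], :] = np.floor(filled + 0.5).astype(np.uint8)
    return out


def remove_hairlines(image: np.ndarray,
                     cfg: HairRemovalConfig | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Full pipeline: detect dark hairs, build a mask, repaint them.

    Returns ``(clean_image, hair_mask)``.  Pixels outside the mask are
    bit-identical to the input.  Detection runs once (not iteratively) and
    only finds hairs darker than their surroundings.
    """
    cfg = cfg or HairRemovalConfig()
    gray = rgb_to_gray(image, cfg.grayscale_weights)
    closed = np.zeros_like(gray)
    for se in cfg.closing_elements:
        np.maximum(closed, morphological_close(gray, se), out=closed)
    diff = hair_difference(closed, gray)
    binary = diff > cfg.threshold_T
    dilated = binarize_and_dilate(diff, cfg)
    mask = _refine_mask(binary, dilated, cfg.dilation_element)
    if mask.all():
        # pathological frame-wide detection; treat as no hairs
        mask = np.zeros_like(mask)
    return inpaint_hairs(image, mask), mask
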