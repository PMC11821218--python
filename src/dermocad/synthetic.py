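"""Seeded synthetic dermoscopic-like image generation.

Images emulate the structure of dermoscopic lesion photographs at desk
scale: a roughly uniform skin background, one elliptical lesion with a
sinusoidally perturbed (irregular) border, optional dark curvilinear hair
overlays with pixel-exact ground-truth masks, gamma/gain contrast
degradation, and near-duplicate copies.  Malignant (MEL) specs are darker,
multi-tone and more border-irregular than benign (BEN) specs, so the two
classes are separable by design — a property the classification tests rely
on.

Everything is a pure function of (spec, seed): identical inputs give
bit-identical uint8 images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MEL, BEN = "MEL", "BEN"

# Study-condition defaults (fixed; see docs/methods.md)
SKIN_COLOR = (205, 165, 145)
BEN_COLOR = (150, 110, 90)
MEL_COLOR = (70, 45, 40)
HAIR_COLOR = (20, 18, 16)
TEXTURE_NOISE_SD = 4.0
BEN_IRREGULARITY = (0.03, 0.12)
MEL_IRREGULARITY = (0.25, 0.45)
DEGRADE_GAMMA = (1.5, 2.2)
DEGRADE_GAIN = (0.85, 1.0)
DUPLICATE_NOISE_SD = 2.0


def _to_uint8(x: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round half-up to uint8."""
    return np.floor(np.clip(x, 0, 255) + 0.5).astype(np.uint8)


@dataclass(frozen=True)
class SynthLesionSpec:
    """Parameters of one synthetic lesion image.

    ``lesion_axes`` are the ellipse semi-axes (a, b) in pixels;
    ``border_irregularity`` in [0, 1] is the amplitude of a sinusoidal
    radial perturbation of the ellipse border (0 gives an exact ellipse).
    """

    image_height: int = 128
    image_width: int = 128
    lesion_center: tuple[float, float] = (64.0, 64.0)
    lesion_axes: tuple[float, float] = (30.0, 24.0)
    lesion_rotation: float = 0.0
    lesion_color: tuple[int, int, int] = BEN_COLOR
    skin_color: tuple[int, int, int] = SKIN_COLOR
    texture_noise_sd: float = TEXTURE_NOISE_SD
    border_irregularity: float = 0.08
    class_label: str = BEN
    seed: int = 0

    def validate(self) -> None:
        a, b = self.lesion_axes
        if a <= 0 or b <= 0:
            raise ValueError("lesion axes must be positive")
        if not 0 <= self.border_irregularity <= 1:
            raise ValueError("border_irregularity must lie in [0, 1]")
        if self.class_label not in (MEL, BEN):
            raise ValueError(f"class_label must be MEL or BEN, got {self.class_label!r}")
        r, c = self.lesion_center
        reach = max(a, b) * (1 + self.border_irregularity)
        if (r - reach < 0 or c - reach < 0
                or r + reach > self.image_height or c + reach > self.image_width):
            raise ValueError(
                "lesion ellipse (with border perturbation) extends outside the frame: "
                f"center={self.lesion_center}, axes={self.lesion_axes}, "
                f"frame={(self.image_height, self.image_width)}")


@dataclass(frozen=True)
class HairOverlaySpec:
    """Parameters of a drawn hair overlay."""

    n_hairs: int = 12
    thickness_px: tuple[int, int] = (1, 3)
    hair_color: tuple[int, int, int] = HAIR_COLOR
    curvature: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.thickness_px
        if not (1 <= lo <= hi <= 4):
            raise ValueError("thickness_px must be within 1..4")
        if self.n_hairs < 0:
            raise ValueError("n_hairs must be nonnegative")


def generate_lesion_image(spec: SynthLesionSpec
                          ) -> tuple[np.ndarray, np.ndarray, str]:
    """Render one lesion image.

    Returns ``(image, lesion_mask, label)``: an (H, W, 3) uint8 image, a
    pixel-exact boolean ground-truth mask, and the class label.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    cy, cx = spec.lesion_center
    a, b = spec.lesion_axes
    theta = np.deg2rad(spec.lesion_rotation)

    rows, cols = np.mgrid[0:h, 0:w]
    dy, dx = rows - cy, cols - cx
    # rotate into the ellipse frame
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)  # 1.0 on the unperturbed border

    # sinusoidal radial border perturbation: a few seeded harmonics
    ang = np.arctan2(v / b, u / a)
    boundary = np.ones_like(rho)
    if spec.border_irregularity > 0:
        n_harm = 3
        ks = rng.integers(3, 9, size=n_harm)
        phases = rng.uniform(0, 2 * np.pi, size=n_harm)
        amps = rng.dirichlet(np.ones(n_harm)) * spec.border_irregularity
        for k, ph, amp in zip(ks, phases, amps):
            boundary = boundary + amp * np.sin(k * ang + ph)
    inside = rho <= boundary

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(spec.skin_color, dtype=np.float64)
    lesion_col = np.asarray(spec.lesion_color, dtype=np.float64)
    img[inside] = lesion_col

    if spec.class_label == MEL:
        # multi-tone interior: darker off-center patch, emulating pigment
        # network variation malignant lesions show
        pcy = cy + rng.uniform(-0.3, 0.3) * a
        pcx = cx + rng.uniform(-0.3, 0.3) * b
        pr = 0.45 * min(a, b)
        patch = ((rows - pcy) ** 2 + (cols - pcx) ** 2 <= pr ** 2) & inside
        img[patch] = lesion_col * 0.6

    img += rng.normal(0.0, spec.texture_noise_sd, size=img.shape)
    return _to_uint8(img), inside, spec.class_label


def _draw_hair(shape: tuple[int, int], rng: np.random.Generator,
               curvature: float, thickness: int) -> np.ndarray:
    """Rasterize one quadratic Bezier stroke as a boolean mask."""
    from scipy.ndimage import binary_dilation
    from skimage.draw import line

    h, w = shape
    margin = 2
    p0 = rng.uniform([margin, margin], [h - margin, w - margin])
    angle = rng.uniform(0, 2 * np.pi)
    length = rng.uniform(0.5, 1.1) * min(h, w)
    p2 = p0 + length * np.array([np.sin(angle), np.cos(angle)])
    mid = (p0 + p2) / 2
    normal = np.array([np.cos(angle), -np.sin(angle)])
    p1 = mid + rng.uniform(-curvature, curvature) * length * normal

    t = np.linspace(0, 1, 4 * int(length) + 8)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
    pts = np.clip(np.rint(pts).astype(int), [0, 0], [h - 1, w - 1])

    mask = np.zeros(shape, dtype=bool)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = line(r0, c0, r1, c1)
        mask[rr, cc] = True
    if thickness > 1:
        foot = np.ones((thickness, thickness), dtype=bool)
        mask = binary_dilation(mask, structure=foot)
    return mask


def add_hairs(image: np.ndarray, spec: HairOverlaySpec
              ) -> tuple[np.ndarray, np.ndarray]:
    """Overlay dark hair strokes; returns (image, ground-truth hair mask).

    The output differs from the input exactly on the mask pixels (a masked
    pixel that would coincide with the hair color is nudged by one level).
    """
    spec.validate()
    if image.ndim != 3 or image.dtype != np.uint8:
        raise ValueError("image must be 8-bit RGB (H, W, 3)")
    mask = np.zeros(image.shape[:2], dtype=bool)
    if spec.n_hairs == 0:
        return image.copy(), mask
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.thickness_px
    for _ in range(spec.n_hairs):
        thickness = int(rng.integers(lo, hi + 1))
        mask |= _draw_hair(image.shape[:2], rng, spec.curvature, thickness)
    out = image.copy()
    out[mask] = np.asarray(spec.hair_color, dtype=np.uint8)
    # guarantee every mask pixel actually changed
    unchanged = mask & np.all(out == image, axis=-1)
    if unchanged.any():
        ch0 = out[..., 0]
        ch0[unchanged] = np.where(ch0[unchanged] > 0, ch0[unchanged] - 1,
                                  ch0[unchanged] + 1)
    return out, mask


def degrade_contrast(image: np.ndarray, gamma: float, gain: float) -> np.ndarray:
    """Monotone per-channel remap ``255 * gain * (I/255)**gamma``, clipped.

    gamma > 1 darkens and compresses shadows; gain < 1 compresses the
    dynamic range — together they emulate the washed-out, low-contrast
    captures the enhancement network is trained to undo.
    """
    if gamma <= 0 or gain <= 0:
        raise ValueError("gamma and gain must be positive")
    x = image.astype(np.float64) / 255.0
    return _to_uint8(255.0 * gain * x ** gamma)


def pearson_image_correlation(a: np.ndarray, b: np.ndarray) -> float:
    x = a.astype(np.float64).ravel()
    y = b.astype(np.float64).ravel()
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def make_near_duplicate(image: np.ndarray, noise_sd: float, seed: int) -> np.ndarray:
    """Additive seeded Gaussian noise copy (a re-captured 'duplicate')."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if noise_sd == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    return _to_uint8(image.astype(np.float64)
                     + rng.normal(0.0, noise_sd, size=image.shape))


def random_lesion_spec(rng: np.random.Generator, label: str,
                       image_size: tuple[int, int] = (128, 128)) -> SynthLesionSpec:
    """Draw a randomized per-image spec under the study-condition defaults."""
    h, w = image_size
    short = min(h, w)
    a = rng.uniform(0.16, 0.27) * short
    b = rng.uniform(0.16, 0.27) * short
    if label == MEL:
        irr = rng.uniform(*MEL_IRREGULARITY)
        base = np.asarray(MEL_COLOR, dtype=np.float64)
    else:
        irr = rng.uniform(*BEN_IRREGULARITY)
        base = np.asarray(BEN_COLOR, dtype=np.float64)
    color = tuple(int(c) for c in np.clip(base + rng.normal(0, 8, 3), 0, 255))
    skin = tuple(int(c) for c in
                 np.clip(np.asarray(SKIN_COLOR, float) + rng.normal(0, 6, 3), 0, 255))
    reach = max(a, b) * (1 + irr) + 2
    cy = rng.uniform(reach, h - reach)
    cx = rng.uniform(reach, w - reach)
    return SynthLesionSpec(
        image_height=h, image_width=w, lesion_center=(cy, cx),
        lesion_axes=(a, b), lesion_rotation=rng.uniform(0, 180),
        lesion_color=color, skin_color=skin, border_irregularity=irr,
        class_label=label, seed=int(rng.integers(0, 2 ** 31 - 1)))


def generate_dataset(n_mel: int, n_ben: int, dup_fraction: float, seed: int,
                     image_size: tuple[int, int] = (128, 128)
                     ) -> tuple[dict[str, np.ndarray], pd.DataFrame, dict[str, np.ndarray]]:
    """Generate a labeled two-class dataset with flagged near-duplicates.

    Returns ``(images, index, masks)``: dicts keyed by path and an index
    DataFrame with columns ``path, label, patient_id, is_duplicate_of``.
    The number of appended duplicates is ``round(dup_fraction * (n_mel +
    n_ben))``, each a noisy copy of a randomly chosen original (same label)
    and flagged with its source path in ``is_duplicate_of``.
    """
    if n_mel < 0 or n_ben < 0:
        raise ValueError("counts must be nonnegative")
    if not 0 <= dup_fraction < 1:
        raise ValueError("dup_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    images: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    records = []
    labels = [MEL] * n_mel + [BEN] * n_ben
    for i, label in enumerate(labels):
        spec = random_lesion_spec(rng, label, image_size)
        img, mask, _ = generate_lesion_image(spec)
        path = f"img_{i:04d}.png"
        images[path] = img
        masks[path] = mask
        records.append({"path": path, "label": label,
                        "patient_id": f"P{i % max(1, (n_mel + n_ben) // 4):03d}",
                        "is_duplicate_of": ""})
    n_dup = int(round(dup_fraction * (n_mel + n_ben)))
    if n_dup and records:
        src_idx = rng.choice(len(records), size=n_dup, replace=False)
        for j, si in enumerate(sorted(int(s) for s in src_idx)):
            src = records[si]
            path = f"img_dup_{j:04d}.png"
            images[path] = make_near_duplicate(
                images[src["path"]], DUPLICATE_NOISE_SD,
                seed=int(rng.integers(0, 2 ** 31 - 1)))
            masks[path] = masks[src["path"]].copy()
            records.append({"path": path, "label": src["label"],
                            "patient_id": src["patient_id"],
                            "is_duplicate_of": src["path"]})
    index = pd.DataFrame.from_records(
        records, columns=["path", "label", "patient_id", "is_duplicate_of"])
    return images, index, masks
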