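"""Atrous-convolution lesion segmentation network (ACNN).

Atrous (dilated) convolution spaces the kernel taps ``r`` pixels apart:

    FM(x, y) = sum_i sum_j sum_k  I(x + i*r, y + j*r, k) * K(i, j, k)

which enlarges the receptive field without pooling or extra parameters, so
the output keeps the input's spatial resolution (stride 1 throughout, no
pooling).  The network has 16 feature-extraction conv layers grouped into
5 blocks with a doubling dilation schedule (1, 2, 4, 8, 16 per block),
each conv followed by batch normalization and leaky ReLU (slope 0.3).  A
1x1 head maps to two classes (lesion / background) with a per-pixel
softmax; training uses weighted cross-entropy (inverse pixel-frequency
class weights) under SGDM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn


@dataclass(frozen=True)
class AtrousConvSpec:
    kernel_height: int = 3
    kernel_width: int = 3
    in_channels: int = 1
    out_channels: int = 1
    dilation_rate: int = 1

    def __post_init__(self):
        if self.dilation_rate < 1:
            raise ValueError("dilation rate must be >= 1")
        if self.kernel_height % 2 == 0 or self.kernel_width % 2 == 0:
            raise ValueError("kernel dimensions must be odd")


def atrous_conv2d(feature_map: np.ndarray, spec: AtrousConvSpec,
                  kernel_values: np.ndarray) -> np.ndarray:
    """Single dilated convolution on an (H, W, C) feature map.

    ``kernel_values`` has shape (kh, kw, in_channels, out_channels); the
    output is (H, W, out_channels), stride 1, zero padding preserving the
    spatial size.  Rate 1 is the standard convolution (sliding-window sum
    of products); rate r >= 2 reads taps r pixels apart.
    """
    fm = np.asarray(feature_map, dtype=np.float64)
    if fm.ndim == 2:
        fm = fm[:, :, None]
    if fm.shape[2] != spec.in_channels:
        raise ValueError(
            f"channel mismatch: feature map has {fm.shape[2]} channels, "
            f"spec expects {spec.in_channels}")
    k = np.asarray(kernel_values, dtype=np.float64)
    expected = (spec.kernel_height, spec.kernel_width, spec.in_channels, spec.out_channels)
    if k.shape != expected:
        raise ValueError(f"kernel shape {k.shape} != spec shape {expected}")
    h, w, _ = fm.shape
    r = spec.dilation_rate
    ph = (spec.kernel_height - 1) // 2 * r
    pw = (spec.kernel_width - 1) // 2 * r
    padded = np.pad(fm, ((ph, ph), (pw, pw), (0, 0)))
    out = np.zeros((h, w, spec.out_channels), dtype=np.float64)
    for i in range(spec.kernel_height):
        for j in range(spec.kernel_width):
            s = padded[i * r:i * r + h, j * r:j * r + w, :]
            out += np.einsum("hwc,co->hwo", s, k[i, j])
    return out


@dataclass(frozen=True)
class ACNNSpec:
    """Architecture of the segmentation network.

    16 conv layers are partitioned into 5 blocks (``layers_per_block``);
    all layers of block b share dilation rate ``dilation_schedule[b]`` and
    width ``channels[b]``.
    """

    input_shape: tuple[int, int, int] = (192, 256, 3)
    n_blocks: int = 5
    n_feature_layers: int = 16
    layers_per_block: tuple[int, ...] = (3, 3, 3, 3, 4)
    dilation_schedule: tuple[int, ...] = (1, 2, 4, 8, 16)
    channels: tuple[int, ...] = (16, 32, 48, 64, 64)
    activation_slope: float = 0.3
    n_classes: int = 2

    def __post_init__(self):
        if len(self.layers_per_block) != self.n_blocks:
            raise ValueError("layers_per_block must list one count per block")
        if sum(self.layers_per_block) != self.n_feature_layers:
            raise ValueError("blocks must partition the feature layers exactly")
        if len(self.dilation_schedule) != self.n_blocks:
            raise ValueError("dilation_schedule must list one rate per block")
        if any(b > a for a, b in zip(self.dilation_schedule[1:],
                                     self.dilation_schedule[:-1])):
            raise ValueError("dilation schedule must be monotone nondecreasing")
        if len(self.channels) != self.n_blocks:
            raise ValueError("channels must list one width per block")


@dataclass(frozen=True)
class ACNNTrainConfig:
    batch_size: int = 16
    learning_rate: float = 0.01
    l2: float = 0.005
    momentum: float = 0.9
    epochs: int = 30


def build_acnn(spec: ACNNSpec | None = None, seed: int = 0) -> nn.Sequential:
    spec = spec or ACNNSpec()
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = spec.input_shape[2]
    li = 0
    for b in range(spec.n_blocks):
        rate = spec.dilation_schedule[b]
        width = spec.channels[b]
        for _ in range(spec.layers_per_block[b]):
            layers.append(nn.Conv2d(in_ch, width, 3, dilation=rate, rng=rng,
                                    name=f"block{b + 1}.conv{li + 1}"))
            layers.append(nn.BatchNorm2d(width, name=f"block{b + 1}.bn{li + 1}"))
            layers.append(nn.LeakyReLU(spec.activation_slope,
                                       name=f"block{b + 1}.lrelu{li + 1}"))
            in_ch = width
            li += 1
    layers.append(nn.Conv2d(in_ch, spec.n_classes, 1, rng=rng, name="head"))
    model = nn.Sequential(layers, input_shape=spec.input_shape)
    model.acnn_spec = spec
    return model


def inverse_frequency_weights(masks: list[np.ndarray], n_classes: int = 2) -> np.ndarray:
    """Class weights proportional to inverse pixel frequency.

    A 90/10 background/lesion training set yields a lesion weight 9x the
    background weight; weights are scaled to mean 1.
    """
    counts = np.zeros(n_classes, dtype=np.float64)
    for m in masks:
        for c in range(n_classes):
            counts[c] += np.count_nonzero(np.asarray(m) == c)
    if np.any(counts == 0):
        raise ValueError("every class must appear in the training masks")
    w = counts.sum() / counts
    return w / w.mean()


def _prep_images(images: list[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    out = []
    for im in images:
        x = im.astype(np.float32) / 255.0
        if x.shape[:2] != shape:
            x = resize(x, shape, order=1, anti_aliasing=True).astype(np.float32)
        out.append(x.transpose(2, 0, 1))
    return np.stack(out)


def _prep_masks(masks: list[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    out = []
    for m in masks:
        m = np.asarray(m)
        vals = np.unique(m)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"mask values outside {{0, 1}}: {vals}")
        if m.shape != shape:
            m = resize(m.astype(np.float64), shape, order=0,
                       anti_aliasing=False) > 0.5
        out.append(m.astype(np.int64))
    return np.stack(out)


def train_acnn(model: nn.Sequential, images: list[np.ndarray],
               masks: list[np.ndarray], cfg: ACNNTrainConfig | None = None,
               seed: int = 0) -> list[float]:
    """Weighted cross-entropy training; returns per-epoch mean losses."""
    cfg = cfg or ACNNTrainConfig()
    if len(images) != len(masks) or not images:
        raise ValueError("need equally many images and masks (nonempty)")
    shape = model.input_shape[:2]
    x = _prep_images(images, shape)
    y = _prep_masks(masks, shape)
    weights = inverse_frequency_weights(list(y))
    rng = np.random.default_rng(seed)
    opt = nn.SGDM(model.params(), cfg.learning_rate, cfg.momentum, l2=cfg.l2)
    n = len(images)
    history: list[float] = []
    for _ in range(int(cfg.epochs)):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.forward(x[idx], train=True)  # (B, 2, H, W)
            b, k, h, w = logits.shape
            flat = logits.transpose(0, 2, 3, 1).reshape(-1, k)
            t = np.eye(k, dtype=np.float32)[y[idx].reshape(-1)]
            loss, grad = nn.softmax_cross_entropy_with_grad(flat, t, weights)
            dlogits = grad.reshape(b, h, w, k).transpose(0, 3, 1, 2)
            model.backward(np.ascontiguousarray(dlogits))
            opt.step()
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)
    if cfg.epochs > 0:
        calib = rng.permutation(n)[:min(n, 16)]
        model.recalibrate_batchnorm(x[calib])
        model.trained = True
    return history


def segment(model: nn.Sequential, image: np.ndarray,
            keep_size: bool = True) -> np.ndarray:
    """Binary lesion mask by per-pixel argmax of the softmax head.

    The image is resized to the model's input shape for inference; with
    ``keep_size`` the mask is resized back (nearest neighbor) to the
    image's own resolution.
    """
    shape = model.input_shape[:2]
    x = _prep_images([image], shape)
    logits = model.forward(x, train=False)[0]
    mask = (logits.argmax(axis=0) == 1)
    if keep_size and mask.shape != image.shape[:2]:
        mask = resize(mask.astype(np.float64), image.shape[:2], order=0,
                      anti_aliasing=False) > 0.5
    return mask


def crop_roi(image: np.ndarray, mask: np.ndarray, margin: int = 0) -> np.ndarray:
    """Crop to the mask's bounding box (expanded by ``margin``, clipped to
    the frame) and zero the background outside the mask."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        warnings.warn("empty mask: returning the full image", RuntimeWarning,
                      stacklevel=2)
        return image.copy()
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0 = max(0, rows.min() - margin)
    r1 = min(image.shape[0], rows.max() + 1 + margin)
    c0 = max(0, cols.min() - margin)
    c1 = min(image.shape[1], cols.max() + 1 + margin)
    out = image[r0:r1, c0:c1].copy()
    sub = mask[r0:r1, c0:c1]
    out[~sub] = 0
    return out


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); defined as 1.0 when both masks are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
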