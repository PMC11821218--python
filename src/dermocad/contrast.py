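"""Multiscale context aggregation network (MCAN) for contrast restoration.

The network is a chain of multiscale residual aggregation blocks (MRABs).
Each MRAB applies a dilated 3x3 convolution (32 filters), batch
normalization and a leaky ReLU, then combines the normalized branch with
the identity branch through two learnable adaptive-normalization scalars:

    out = mu * x + lambda * leakyReLU(BN(conv_r(x)))

The eight blocks use dilation rates 2, 4, 6, 8, 16, 32, 64 and 128, so the
receptive field grows with depth and the deepest block aggregates context
across the whole 256x256 patch.  A 3x3 stem lifts the RGB input to 32
channels and a 1x1 regression head maps back to 3 channels.  Training is
mean-squared-error regression of clean patches from synthetically degraded
ones; at inference the trained model restores contrast of hair-occluded,
low-contrast images patch by patch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .synthetic import _to_uint8

ALLOWED_DILATION_RATES = (2, 4, 6, 8, 16, 32, 64, 128)


@dataclass(frozen=True)
class MRABSpec:
    dilation_rate: int
    n_filters: int = 32
    kernel: tuple[int, int] = (3, 3)

    def __post_init__(self):
        if self.dilation_rate not in ALLOWED_DILATION_RATES:
            raise ValueError(
                f"dilation rate {self.dilation_rate} not in {ALLOWED_DILATION_RATES}")
        if self.n_filters <= 0:
            raise ValueError("n_filters must be positive")


def _default_mrabs() -> tuple[MRABSpec, ...]:
    return tuple(MRABSpec(r) for r in ALLOWED_DILATION_RATES)


@dataclass(frozen=True)
class MCANSpec:
    n_mrab: int = 8
    patch_size: int = 256
    mrabs: tuple[MRABSpec, ...] = field(default_factory=_default_mrabs)

    def __post_init__(self):
        if len(self.mrabs) != self.n_mrab:
            raise ValueError("one MRABSpec per context module is required")


class MRAB(nn.Layer):
    """One context module with adaptive-normalization residual combination.

    ``mu`` (identity branch) starts at 1 and ``lambda`` (normalized
    branch) at 0, so the block is initialized as an identity map and the
    dilated branch is blended in during training.
    """

    def __init__(self, spec: MRABSpec, in_channels: int,
                 rng: np.random.Generator, name: str):
        self.conv = nn.Conv2d(in_channels, spec.n_filters, spec.kernel,
                              dilation=spec.dilation_rate, rng=rng, name=f"{name}.conv")
        self.bn = nn.BatchNorm2d(spec.n_filters, name=f"{name}.bn")
        self.act = nn.LeakyReLU(0.3, name=f"{name}.lrelu")
        self.mu = nn.Param(f"{name}.mu", np.array([1.0]), weight_decay=False)
        self.lam = nn.Param(f"{name}.lambda", np.array([0.0]), weight_decay=False)
        self.name = name

    def forward(self, x, train=True):
        h = self.act.forward(self.bn.forward(self.conv.forward(x, train), train), train)
        self._x, self._h = x, h
        return (self.mu.value[0] * x + self.lam.value[0] * h).astype(np.float32)

    def backward(self, dout):
        self.mu.grad[...] = float((dout * self._x).sum())
        self.lam.grad[...] = float((dout * self._h).sum())
        dh = self.lam.value[0] * dout
        dx_branch = self.conv.backward(self.bn.backward(self.act.backward(dh)))
        return (self.mu.value[0] * dout + dx_branch).astype(np.float32)

    def params(self):
        return self.conv.params() + self.bn.params() + [self.mu, self.lam]

    def layer_specs(self):
        return (self.conv.layer_specs() + self.bn.layer_specs()
                + self.act.layer_specs())


def build_mcan(spec: MCANSpec | None = None, seed: int = 0) -> nn.Sequential:
    """Instantiate the MCAN; layer descriptions via ``to_network_spec()``."""
    spec = spec or MCANSpec()
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [
        nn.Conv2d(3, spec.mrabs[0].n_filters, 3, dilation=1, rng=rng, name="stem"),
        nn.LeakyReLU(0.3, name="stem.lrelu"),
    ]
    ch = spec.mrabs[0].n_filters
    for i, mrab_spec in enumerate(spec.mrabs):
        if mrab_spec.n_filters != ch:
            raise ValueError("MRAB filter counts must match along the chain")
        layers.append(MRAB(mrab_spec, ch, rng, name=f"mrab{i}"))
    layers.append(nn.Conv2d(ch, 3, 1, dilation=1, rng=rng, name="regression"))
    model = nn.Sequential(layers, input_shape=(spec.patch_size, spec.patch_size, 3))
    model.mcan_spec = spec
    return model


def mrab_blocks(model: nn.Sequential) -> list[MRAB]:
    return [l for l in model.layers if isinstance(l, MRAB)]


# -- patching ------------------------------------------------------------


def extract_patches(image: np.ndarray, patch_size: int
                    ) -> tuple[list[np.ndarray], dict]:
    """Tile an image into patch_size x patch_size tiles, edge-padding the
    bottom/right remainder.  Returns (patches, layout) for stitching."""
    h, w = image.shape[:2]
    ph = int(np.ceil(h / patch_size)) * patch_size
    pw = int(np.ceil(w / patch_size)) * patch_size
    pad = [(0, ph - h), (0, pw - w)] + [(0, 0)] * (image.ndim - 2)
    padded = np.pad(image, pad, mode="edge")
    patches = []
    for r in range(0, ph, patch_size):
        for c in range(0, pw, patch_size):
            patches.append(padded[r:r + patch_size, c:c + patch_size].copy())
    layout = {"shape": (h, w), "grid": (ph // patch_size, pw // patch_size),
              "patch_size": patch_size}
    return patches, layout


def stitch_patches(patches: list[np.ndarray], layout: dict) -> np.ndarray:
    gr, gc = layout["grid"]
    ps = layout["patch_size"]
    h, w = layout["shape"]
    rows = [np.concatenate(patches[r * gc:(r + 1) * gc], axis=1) for r in range(gr)]
    full = np.concatenate(rows, axis=0)
    return full[:h, :w]


# -- training / inference ------------------------------------------------


def train_mcan(model: nn.Sequential, clean_images: list[np.ndarray],
               degradation_sampler, epochs: int = 20, learning_rate: float = 0.02,
               momentum: float = 0.9, batch_size: int = 8, seed: int = 0
               ) -> list[float]:
    """MSE-train on (degraded, clean) pairs; returns per-epoch losses.

    ``degradation_sampler(image, rng) -> image`` produces the degraded
    input for each clean patch (fresh draw every epoch).  Zero epochs
    leave the model untouched.
    """
    if not clean_images:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    clean = np.stack([im.astype(np.float32) / 255.0 for im in clean_images])
    clean = clean.transpose(0, 3, 1, 2)
    opt = nn.SGDM(model.params(), learning_rate, momentum)
    history: list[float] = []
    n = len(clean_images)
    for _ in range(int(epochs)):
        degraded = np.stack([
            degradation_sampler(im, rng).astype(np.float32) / 255.0
            for im in clean_images]).transpose(0, 3, 1, 2)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            pred = model.forward(degraded[idx], train=True)
            loss, grad = nn.mse_loss_with_grad(pred, clean[idx])
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)
    if epochs > 0:
        calib = rng.permutation(n)[:min(n, 16)]
        model.recalibrate_batchnorm(degraded[calib])
        model.trained = True
    return history


def enhance(model: nn.Sequential, image: np.ndarray) -> np.ndarray:
    """Restore contrast; output uint8, clipped to [0, 255], same shape."""
    if not getattr(model, "trained", False):
        warnings.warn("enhancing with an untrained model", RuntimeWarning,
                      stacklevel=2)
    patch_size = model.input_shape[0] if model.input_shape else 256
    h, w = image.shape[:2]
    if h <= patch_size and w <= patch_size:
        x = image.astype(np.float32)[None].transpose(0, 3, 1, 2) / 255.0
        out = model.forward(x, train=False)[0].transpose(1, 2, 0)
        return _to_uint8(out * 255.0)
    patches, layout = extract_patches(image, patch_size)
    out_patches = []
    for p in patches:
        x = p.astype(np.float32)[None].transpose(0, 3, 1, 2) / 255.0
        out_patches.append(model.forward(x, train=False)[0].transpose(1, 2, 0))
    stitched = stitch_patches(out_patches, layout)
    return _to_uint8(stitched * 255.0)
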