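"""Compact benign/melanoma CNN classifier (N-DCNN).

Eleven conv blocks (conv -> batch norm -> leaky ReLU, slope 0.3), with the
middle groups repeated 2, 4 and 2 times and max pooling at group
boundaries.  The first layer slides 8 kernels of 3x3 over a 128x128 RGB
input; the channel schedule

    8 | 16,16 | 32,32,64,64 | 128,128 | 128 | 2560

ends in a wide 3x3 feature-expansion block before global average pooling
and a 2-way dense softmax head.  The expansion block carries most of the
learnable weights, putting the default network at 3,405,202 parameters and
3,176 kernels — within the [3.0M, 3.6M] / [2.8K, 3.4K] design budget that
keeps the model an order of magnitude smaller than transfer-learned
baselines.  Training is weighted cross-entropy under SGDM with L2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .metrics import count_kernels, count_parameters
from .synthetic import BEN, MEL

PARAM_BUDGET = (3_000_000, 3_600_000)
KERNEL_BUDGET = (2_800, 3_400)

# (channels, pool_after) per block; groups of repeats 2 / 4 / 2
DEFAULT_BLOCKS = (
    (8, True),                                       # stem
    (16, False), (16, True),                         # group A (x2)
    (32, False), (32, False), (64, False), (64, True),  # group B (x4)
    (128, False), (128, True),                       # group C (x2)
    (128, True),                                     # deep block
    (2560, False),                                   # feature expansion
)


@dataclass(frozen=True)
class NDCNNSpec:
    input_shape: tuple[int, int, int] = (128, 128, 3)
    blocks: tuple[tuple[int, bool], ...] = DEFAULT_BLOCKS
    block_repeats: tuple[int, int, int] = (2, 4, 2)
    activation_slope: float = 0.3
    n_classes: int = 2

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def __post_init__(self):
        if self.blocks[0][0] != 8:
            raise ValueError("the first conv block must slide 8 kernels")
        h, w, _ = self.input_shape
        n_pools = sum(1 for _, p in self.blocks if p)
        if h % (2 ** n_pools) or w % (2 ** n_pools):
            raise ValueError("input size must be divisible by the pooling chain")


@dataclass(frozen=True)
class NDCNNTrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 100
    momentum: float = 0.99
    l2: float = 0.0005


@dataclass(frozen=True)
class Prediction:
    class_probabilities: dict[str, float]
    predicted_label: str


def leaky_relu(x, s: float = 0.3):
    """x*s for x < 0, x otherwise."""
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x < 0, x * s, x)
    return float(out) if out.ndim == 0 else out


def build_ndcnn(spec: NDCNNSpec | None = None, seed: int = 0,
                enforce_budget: bool = True) -> nn.Sequential:
    """Build the classifier; raises if the parameter budget is violated."""
    spec = spec or NDCNNSpec()
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = spec.input_shape[2]
    for i, (width, pool_after) in enumerate(spec.blocks):
        layers.append(nn.Conv2d(in_ch, width, 3, rng=rng, name=f"block{i + 1}.conv"))
        layers.append(nn.BatchNorm2d(width, name=f"block{i + 1}.bn"))
        layers.append(nn.LeakyReLU(spec.activation_slope, name=f"block{i + 1}.lrelu"))
        if pool_after:
            layers.append(nn.MaxPool2d(2, name=f"block{i + 1}.pool"))
        in_ch = width
    layers.append(nn.GlobalAvgPool())
    layers.append(nn.Dense(in_ch, spec.n_classes, rng=rng, name="fc"))
    model = nn.Sequential(layers, input_shape=spec.input_shape)
    model.ndcnn_spec = spec
    if enforce_budget:
        total, _ = count_parameters(model.to_network_spec())
        if not PARAM_BUDGET[0] <= total <= PARAM_BUDGET[1]:
            raise ValueError(
                f"parameter budget violated: schedule {spec.blocks} has {total} "
                f"parameters, outside {PARAM_BUDGET}")
        kernels = count_kernels(model.to_network_spec())
        if not KERNEL_BUDGET[0] <= kernels <= KERNEL_BUDGET[1]:
            raise ValueError(
                f"kernel budget violated: schedule {spec.blocks} has {kernels} "
                f"kernels, outside {KERNEL_BUDGET}")
    return model


def _prep(images: list[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    out = []
    for im in images:
        x = im.astype(np.float32) / 255.0
        if x.ndim == 2:
            x = np.stack([x] * 3, axis=-1)
        if x.shape[:2] != shape:
            x = resize(x, shape, order=1, anti_aliasing=True).astype(np.float32)
        out.append(x.transpose(2, 0, 1))
    return np.stack(out)


def class_weights_from_labels(labels: list[str]) -> np.ndarray:
    """Inverse class-frequency weights over (BEN, MEL), mean 1."""
    counts = np.array([labels.count(BEN), labels.count(MEL)], dtype=np.float64)
    if np.any(counts == 0):
        raise ValueError("training set must contain both classes")
    w = counts.sum() / counts
    return w / w.mean()


def train_ndcnn(model: nn.Sequential, images: list[np.ndarray],
                labels: list[str], cfg: NDCNNTrainConfig | None = None,
                seed: int = 0) -> list[float]:
    """Train on labeled two-class images; returns per-epoch mean losses."""
    cfg = cfg or NDCNNTrainConfig()
    if len(images) != len(labels) or not images:
        raise ValueError("need equally many images and labels (nonempty)")
    weights = class_weights_from_labels(list(labels))
    shape = model.input_shape[:2]
    x = _prep(images, shape)
    y = np.array([1 if l == MEL else 0 for l in labels])
    t = np.eye(2, dtype=np.float32)[y]
    rng = np.random.default_rng(seed)
    opt = nn.SGDM(model.params(), cfg.learning_rate, cfg.momentum, l2=cfg.l2)
    n = len(images)
    history: list[float] = []
    for _ in range(int(cfg.epochs)):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.forward(x[idx], train=True)
            loss, grad = nn.softmax_cross_entropy_with_grad(logits, t[idx], weights)
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)
    if cfg.epochs > 0:
        calib = rng.permutation(n)[:min(n, 64)]
        model.recalibrate_batchnorm(x[calib])
        model.trained = True
    return history


def predict(model: nn.Sequential, image: np.ndarray) -> Prediction:
    """Class probabilities (softmax) and argmax label for one image."""
    x = _prep([image], model.input_shape[:2])
    logits = model.forward(x, train=False)
    p = nn.softmax(logits, axis=1)[0]
    probs = {BEN: float(p[0]), MEL: float(p[1])}
    label = MEL if p[1] >= p[0] else BEN
    return Prediction(class_probabilities=probs, predicted_label=label)


def predict_batch(model: nn.Sequential, images: list[np.ndarray]
                  ) -> tuple[np.ndarray, list[str]]:
    """MEL probabilities and labels for a list of images."""
    x = _prep(images, model.input_shape[:2])
    logits = model.forward(x, train=False)
    p = nn.softmax(logits, axis=1)
    labels = [MEL if pi[1] >= pi[0] else BEN for pi in p]
    return p[:, 1], labels
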