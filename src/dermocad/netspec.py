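"""Declarative network descriptions.

A :class:`NetworkSpec` is an ordered list of :class:`LayerSpec` records from
which layer-wise parameter counts and receptive fields are computable without
instantiating any weights.  The three model modules export their architectures
in this form so the metrics module can audit them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a network.

    Parameters
    ----------
    kind
        One of ``input``, ``conv``, ``batchnorm``, ``activation``, ``pool``,
        ``globalavgpool``, ``flatten``, ``dense``, ``softmax``.
    kernel
        ``(height, width)`` for conv/pool layers.
    in_channels, out_channels
        Channel counts for conv layers (``in`` is the previous layer's
        kernel count in the counting formulas).
    dilation
        Dilation rate for conv layers; taps are spaced ``dilation`` pixels
        apart.
    units_in, units_out
        Neuron counts for dense layers.
    n_features
        Feature count for batch-normalization layers.
    stride
        Spatial stride (pool layers).
    name
        Optional label, e.g. the block the layer belongs to.
    """

    kind: str
    kernel: tuple[int, int] | None = None
    in_channels: int | None = None
    out_channels: int | None = None
    dilation: int = 1
    units_in: int | None = None
    units_out: int | None = None
    n_features: int | None = None
    stride: int = 1
    name: str = ""


@dataclass
class NetworkSpec:
    """Ordered layer descriptions of a network."""

    layers: list[LayerSpec] = field(default_factory=list)

    def __iter__(self) -> Iterator[LayerSpec]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def convs(self) -> list[LayerSpec]:
        return [l for l in self.layers if l.kind == "conv"]


def receptive_field(spec: NetworkSpec | Sequence[LayerSpec]) -> list[int]:
    """Per-layer receptive field (side length, pixels) of a stride-chain.

    Uses the standard recurrence ``rf' = rf + (k - 1) * r * jump`` where
    ``jump`` is the cumulative stride of all preceding layers.  Only layers
    with a spatial footprint (conv, pool) change the receptive field.
    """
    layers = spec.layers if isinstance(spec, NetworkSpec) else list(spec)
    rf, jump = 1, 1
    out: list[int] = []
    for layer in layers:
        if layer.kind == "conv" and layer.kernel is not None:
            k = max(layer.kernel)
            rf = rf + (k - 1) * layer.dilation * jump
        elif layer.kind == "pool" and layer.kernel is not None:
            k = max(layer.kernel)
            rf = rf + (k - 1) * jump
            jump *= layer.stride
        out.append(rf)
    return out
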