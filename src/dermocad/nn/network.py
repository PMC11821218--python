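"""Sequential container with save/load and NetworkSpec export."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..netspec import LayerSpec, NetworkSpec
from .layers import Layer, Param


class Sequential(Layer):
    def __init__(self, layers: list[Layer], input_shape: tuple[int, int, int] | None = None):
        self.layers = list(layers)
        self.input_shape = input_shape  # (H, W, C) metadata for spec export
        self.trained = False

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def to_network_spec(self) -> NetworkSpec:
        specs: list[LayerSpec] = []
        if self.input_shape is not None:
            specs.append(LayerSpec(kind="input", name=f"input {self.input_shape}"))
        for layer in self.layers:
            specs.extend(layer.layer_specs())
        return NetworkSpec(specs)

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value for p in self.params()}
        for i, layer in enumerate(self.layers):
            rm = getattr(layer, "running_mean", None)
            if rm is not None:
                state[f"__running_mean_{i}"] = rm
                state[f"__running_var_{i}"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for i, layer in enumerate(self.layers):
            if f"__running_mean_{i}" in state:
                layer.running_mean = np.asarray(state[f"__running_mean_{i}"], dtype=np.float32)
                layer.running_var = np.asarray(state[f"__running_var_{i}"], dtype=np.float32)

    def recalibrate_batchnorm(self, x: np.ndarray) -> None:
        """Set batch-norm running statistics from one representative batch.

        After very short trainings the exponentially averaged running
        statistics lag far behind the batch statistics, which makes
        inference-mode outputs inconsistent with training.  A single
        full-momentum forward pass over ``x`` pins the running statistics
        to that batch's statistics.
        """
        saved = []
        for layer in self.layers:
            m = getattr(layer, "momentum", None)
            if m is not None and hasattr(layer, "running_mean"):
                saved.append((layer, m))
                layer.momentum = 1.0
            bn = getattr(layer, "bn", None)  # composite blocks
            if bn is not None and hasattr(bn, "running_mean"):
                saved.append((bn, bn.momentum))
                bn.momentum = 1.0
        try:
            self.forward(x, train=True)
        finally:
            for layer, m in saved:
                layer.momentum = m

    def save(self, path: str | Path) -> None:
        np.savez(path, __trained=np.array(int(self.trained)), **self.state_dict())

    def load(self, path: str | Path) -> None:
        with np.load(path) as data:
            state = {k: data[k] for k in data.files}
        self.trained = bool(state.pop("__trained", np.array(1)))
        self.load_state_dict(state)
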