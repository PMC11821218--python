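"""Stochastic gradient descent with momentum (SGDM).

The update is the classical velocity form

    v' = gamma * v - alpha * grad      theta' = theta + v'

optionally with an L2 penalty folded into the gradient
(``grad += l2 * theta``) for parameters flagged for weight decay.
"""

from __future__ import annotations

import numpy as np

from .layers import Param


def sgdm_step(theta: np.ndarray, grad: np.ndarray, velocity: np.ndarray,
              learning_rate: float, momentum: float) -> tuple[np.ndarray, np.ndarray]:
    """One momentum update on plain arrays; returns (theta', velocity')."""
    velocity = momentum * velocity - learning_rate * grad
    return theta + velocity, velocity


class SGDM:
    def __init__(self, params: list[Param], learning_rate: float,
                 momentum: float = 0.9, l2: float = 0.0):
        self.params = params
        self.learning_rate = float(learning_rate)
        self.momentum = float(momentum)
        self.l2 = float(l2)

    def step(self) -> None:
        for p in self.params:
            g = p.grad
            if self.l2 and p.weight_decay:
                g = g + self.l2 * p.value
            p.velocity *= self.momentum
            p.velocity -= self.learning_rate * g
            p.value += p.velocity
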