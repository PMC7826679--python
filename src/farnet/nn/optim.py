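"""Stochastic gradient descent with momentum, weight decay and exponential decay."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["SGD"]


class SGD:
    """SGD with classical momentum and L2 weight decay.

    ``v ← μ v − lr (g + λ θ)``, ``θ ← θ + v`` — the Caffe-style update implied
    by a momentum/weight-decay hyperparameter pair.
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
    ) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v


class ExponentialDecay:
    """lr(k) = base_lr · γ^k after k decay steps (stepped once per epoch)."""

    def __init__(self, optimizer: SGD, gamma: float) -> None:
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.gamma = gamma
        self.steps = 0

    def step(self) -> None:
        self.steps += 1
        self.optimizer.lr = self.base_lr * self.gamma**self.steps
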