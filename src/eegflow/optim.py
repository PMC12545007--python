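"""AdamW with a cosine-annealing warm-restart learning-rate schedule.

All models in this package are trained the same way: AdamW with decoupled
weight decay, and a learning rate that follows a half-cosine from its maximum
down to ``eta_min`` and jumps back to the maximum at the start of every
restart period (default 25 epochs).
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor


class AdamW:
    """Adam with decoupled weight decay (no decay applied through the gradient)."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-5,
    ):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * ((m / bc1) / (np.sqrt(v / bc2) + self.eps) + self.weight_decay * p.data)


def cosine_restart_lr(base_lr: float, epoch: int, period: int = 25, eta_min: float = 0.0) -> float:
    """Learning rate at `epoch` under cosine annealing with warm restarts.

    The rate equals ``base_lr`` at epochs 0, period, 2*period, ... and decays
    along a half-cosine to ``eta_min`` within each period.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    frac = (epoch % period) / period
    return eta_min + 0.5 * (base_lr - eta_min) * (1.0 + math.cos(math.pi * frac))
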