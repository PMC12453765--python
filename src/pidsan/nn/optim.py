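"""Stochastic gradient descent with momentum (SGDM) and L2 weight decay."""

from __future__ import annotations

import numpy as np


class SGDM:
    """v <- mu*v + g + l2*w ;  w <- w - lr*v.

    ``l2`` is the regularisation factor applied as decoupled-from-loss weight
    decay added to the gradient (the classical L2 formulation).
    """

    def __init__(self, params, lr: float = 0.001, momentum: float = 0.9, l2: float = 0.0,
                 clip_norm: float | None = None):
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params = list(params)
        self.lr, self.momentum, self.l2 = lr, momentum, l2
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad * scale if scale != 1.0 else p.grad
            if self.l2:
                g = g + self.l2 * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
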