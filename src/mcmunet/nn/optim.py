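"""Stochastic gradient descent with Nesterov momentum."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class SGD:
    """SGD with (Nesterov) momentum and optional weight decay.

    Update per parameter p with gradient g:
        buf <- mu * buf + g
        p   <- p - lr * (g + mu * buf)     (Nesterov)
        p   <- p - lr * buf                (plain momentum)
    """

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.99,
                 nesterov: bool = True, weight_decay: float = 0.0):
        if not 0.0 <= momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.nesterov = nesterov
        self.weight_decay = weight_decay
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, buf in zip(self.params, self._buf):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            if self.nesterov:
                p.data -= self.lr * (g + self.momentum * buf)
            else:
                p.data -= self.lr * buf

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
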