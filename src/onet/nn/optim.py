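"""First-order optimizers: SGD with momentum and AdamW."""

from __future__ import annotations

import numpy as np

from .modules import Parameter


class Optimizer:
    def __init__(self, params):
        self.params: list[Parameter] = list(params)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:  # pragma: no cover - interface
        raise NotImplementedError


class SGD(Optimizer):
    """Stochastic gradient descent with classical momentum and L2 weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        super().__init__(params)
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._buf = [None] * len(self.params)

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            if self.momentum:
                if self._buf[i] is None:
                    self._buf[i] = g.copy()
                else:
                    self._buf[i] = self.momentum * self._buf[i] + g
                g = self._buf[i]
            p.data = p.data - self.lr * g


class AdamW(Optimizer):
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        super().__init__(params)
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self._t
        bc2 = 1 - b2 ** self._t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            if self.weight_decay:
                p.data = p.data * (1 - self.lr * self.weight_decay)
            self._m[i] = b1 * self._m[i] + (1 - b1) * p.grad
            self._v[i] = b2 * self._v[i] + (1 - b2) * p.grad ** 2
            mhat = self._m[i] / bc1
            vhat = self._v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
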