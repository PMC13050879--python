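"""Adam optimizer and cosine-annealing learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params: list[Parameter] = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class CosineAnnealingLR:
    """Decay lr from ``base_lr`` to ``eta_min`` over ``t_max`` epochs."""

    def __init__(self, optimizer: Adam, t_max: int, eta_min: float = 0.0):
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.t_max = max(t_max, 1)
        self.eta_min = eta_min
        self.epoch = 0

    def step(self) -> None:
        self.epoch += 1
        frac = min(self.epoch, self.t_max) / self.t_max
        self.optimizer.lr = float(
            self.eta_min
            + 0.5 * (self.base_lr - self.eta_min) * (1 + np.cos(np.pi * frac))
        )
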