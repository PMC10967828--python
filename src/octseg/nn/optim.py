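"""AdaBound: Adam with per-parameter step sizes clipped inside bounds that
converge to a final learning rate, so the optimizer transitions smoothly from
adaptive (Adam-like) to SGD-like behaviour.

Implements the update rule of the defining publication with its published
defaults (final_lr 0.1, gamma 1e-3, betas 0.9/0.999).  When an external
scheduler changes ``lr``, the bound schedule rescales by lr/base_lr, matching
the reference implementation.
"""

from __future__ import annotations

import numpy as np

from .core import Tensor


class AdaBound:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 final_lr: float = 0.1, gamma: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.base_lr = lr
        self.final_lr = final_lr
        self.gamma = gamma
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        t = self.t
        bias1 = 1.0 - self.b1 ** t
        bias2 = 1.0 - self.b2 ** t
        step_size = self.lr * np.sqrt(bias2) / bias1
        # bounds tighten around final_lr (scaled along with any lr schedule)
        final_lr = self.final_lr * self.lr / self.base_lr
        lower = final_lr * (1.0 - 1.0 / (self.gamma * t + 1.0))
        upper = final_lr * (1.0 + 1.0 / (self.gamma * t))
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            eta = np.clip(step_size / (np.sqrt(v) + self.eps), lower, upper)
            p.data -= eta * m
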