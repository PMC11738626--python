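"""RMSprop optimizer (square-gradient moving average, no momentum)."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class RMSprop:
    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        alpha: float = 0.99,
        eps: float = 1e-8,
    ):
        self.params = dict(params)
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self._sq = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self):
        for k, p in self.params.items():
            if p.grad is None:
                continue
            v = self._sq[k]
            v *= self.alpha
            v += (1.0 - self.alpha) * p.grad**2
            p.data -= self.lr * p.grad / (np.sqrt(v) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()
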