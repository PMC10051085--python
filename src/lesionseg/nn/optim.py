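"""Adam optimizer (adaptive moment estimation)."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Adam"]


class Adam:
    """Adam with bias-corrected first/second moments.

    Defaults follow the training protocol used throughout this package:
    beta1 = 0.9 and beta2 = 0.99 (the second-moment decay deliberately set
    below the common 0.999; see the methods note).
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.99,
        eps: float = 1e-8,
    ):
        if not 0.0 < beta1 < 1.0 or not 0.0 < beta2 < 1.0:
            raise ValueError("betas must lie in (0, 1)")
        self.params = list(params)
        self.lr = float(lr)
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            mhat = m / b1t
            vhat = v / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
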