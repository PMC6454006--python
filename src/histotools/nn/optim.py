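"""Adam optimizer with optional L2 penalty."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter

__all__ = ["Adam"]


class Adam:
    """Adam (Kingma & Ba) over a list of parameters.

    ``l2`` adds a penalty ``l2 * sum(w^2)`` to the objective; its gradient
    ``2 * l2 * w`` is applied here so the data loss reported by training loops
    stays separable from the regularizer.  With ``l2 = 0`` the update is the
    plain Adam step on the unregularized loss.
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 l2: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.l2 = l2
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def penalty(self) -> float:
        if self.l2 == 0.0:
            return 0.0
        return self.l2 * float(sum((p.data.astype(np.float64) ** 2).sum()
                                   for p in self.params))

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.l2:
                g = g + 2.0 * self.l2 * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
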