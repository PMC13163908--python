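"""AdamW optimizer (decoupled weight decay)."""

from __future__ import annotations

import numpy as np

from .model import Model

__all__ = ["AdamW"]


class AdamW:
    """Adam with decoupled weight decay.

    Update per parameter p with gradient g:
        m <- b1*m + (1-b1)*g;  v <- b2*v + (1-b2)*g^2
        p <- p - lr * (m_hat / (sqrt(v_hat) + eps) + weight_decay * p)
    """

    def __init__(self, model: Model, lr: float = 5e-4, weight_decay: float = 1e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        for name, p, _ in model.named_parameters():
            self._m[name] = np.zeros_like(p)
            self._v[name] = np.zeros_like(p)

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for name, p, g in self.model.named_parameters():
            m = self._m[name]
            v = self._v[name]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p -= self.lr * (update + self.weight_decay * p)

    def zero_grad(self) -> None:
        self.model.zero_grad()
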