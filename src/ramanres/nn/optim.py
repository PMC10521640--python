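"""Adaptive moment estimation (Adam) on flat parameter/gradient dicts."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Standard Adam with bias correction.

    ``modules`` is any iterable of objects exposing ``params`` and ``grads``
    dicts; state is keyed by (module index, parameter name).
    """

    def __init__(self, modules, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.modules = list(modules)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, mod in enumerate(self.modules):
            for name, p in mod.params.items():
                g = mod.grads.get(name)
                if g is None:
                    continue
                g = g.astype(p.dtype, copy=False)
                key = (i, name)
                m = self._m.setdefault(key, np.zeros_like(p))
                v = self._v.setdefault(key, np.zeros_like(p))
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
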