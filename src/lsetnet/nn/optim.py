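"""Adam optimizer operating on a layer tree's named parameters."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with bias correction (Kingma & Ba); default betas (0.9, 0.999)."""

    def __init__(self, root, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.root = root
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for path, layer, key in self.root.named_params():
            g = layer.grads.get(key)
            if g is None:
                continue
            m = self._m.setdefault(path, np.zeros_like(layer.params[key]))
            v = self._v.setdefault(path, np.zeros_like(layer.params[key]))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            layer.params[key] -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(
                layer.params[key].dtype
            )
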