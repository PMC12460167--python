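"""Adaptive-moment (Adam) optimizer over layer parameter dicts."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, layers, lr=4e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = list(layers)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: dict = {}
        self._v: dict = {}
        self._t = 0

    def zero_grads(self):
        for layer in self.layers:
            layer.zero_grads()

    def step(self):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                g = layer.grads[name]
                key = (i, name)
                m = self._m.get(key)
                if m is None:
                    m = np.zeros_like(p)
                    self._v[key] = np.zeros_like(p)
                v = self._v[key]
                m = b1 * m + (1 - b1) * g
                v = b2 * v + (1 - b2) * g * g
                self._m[key], self._v[key] = m, v
                mhat = m / (1 - b1**self._t)
                vhat = v / (1 - b2**self._t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            layer.constrain()
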