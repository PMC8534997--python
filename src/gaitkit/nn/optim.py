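"""Nadam: the Adam optimizer with Nesterov momentum (Dozat, 2016)."""

from __future__ import annotations

import numpy as np


class Nadam:
    def __init__(self, learning_rate=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = {}
        self._v = {}

    def step(self, layers):
        """Apply one in-place update using each layer's current gradients."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(layers):
            params = layer.params()
            if not params:
                continue
            grads = layer.grads()
            for name, p in params.items():
                key = (li, name)
                g = grads[name].astype(np.float32)
                m = self._m.get(key)
                if m is None:
                    m = np.zeros_like(p)
                    self._m[key] = m
                    self._v[key] = np.zeros_like(p)
                v = self._v[key]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                # Nesterov look-ahead on the first moment
                m_hat = b1 * m / (1 - b1 ** (self.t + 1)) + (1 - b1) * g / (1 - b1 ** self.t)
                v_hat = v / (1 - b2 ** self.t)
                p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
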