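"""Adam optimizer updating trainable parameter arrays in place."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, model, beta1=0.9, beta2=0.999, eps=1e-7):
        self.model = model
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, lr: float) -> None:
        self.t += 1
        grads = self.model.grads()
        for name, param, trainable in self.model.param_arrays():
            if not trainable:
                continue
            g = grads.get(name)
            if g is None:
                continue
            g = np.asarray(g, dtype=np.float32)
            m = self._m.setdefault(name, np.zeros_like(param))
            v = self._v.setdefault(name, np.zeros_like(param))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            param -= lr * mhat / (np.sqrt(vhat) + self.eps)
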