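"""Stochastic gradient descent with momentum and per-group learning rates."""

from __future__ import annotations

import numpy as np


class SGD:
    """Momentum SGD over (module, key) parameter references.

    ``groups`` is a list of (param_refs, lr_scale) pairs; the effective step
    for a group is ``lr * lr_scale``. A single flat list of refs is also
    accepted. ``weight_decay`` is decoupled L2 on the raw parameters.
    """

    def __init__(self, groups, lr=0.01, momentum=0.9, weight_decay=0.0):
        groups = list(groups)
        if groups and not isinstance(groups[0][0], list):
            groups = [(groups, 1.0)]  # flat list of (module, key) refs
        self.groups = [(list(refs), float(scale)) for refs, scale in groups]
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = {}

    def zero_grad(self):
        for refs, _ in self.groups:
            for m, k in refs:
                m.grads[k] = np.zeros_like(m.params[k])

    def step(self):
        for refs, scale in self.groups:
            eff_lr = self.lr * scale
            for m, k in refs:
                g = m.grads[k]
                if self.weight_decay and k in ("weight", "w1", "w2"):
                    g = g + self.weight_decay * m.params[k]
                key = (id(m), k)
                v = self._velocity.get(key)
                if v is None:
                    v = np.zeros_like(m.params[k])
                v = self.momentum * v - eff_lr * g
                self._velocity[key] = v
                m.params[k] += v
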