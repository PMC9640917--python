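"""Residual block with optional per-block channel attention."""

from __future__ import annotations

import numpy as np

from .layers import DTYPE, BatchNorm2d, Conv2d, Module, ReLU, Sequential


class ResidualBlock(Module):
    """conv-bn-relu-conv-bn [-attention] + shortcut, then relu.

    ``attention`` is an already-constructed attention module over ``c_out``
    channels (SEBlock / ECABlock) or None for a plain residual block.
    """

    def __init__(self, c_in, c_out, stride=1, attention: Module | None = None, *, rng):
        super().__init__()
        self.conv1 = Conv2d(c_in, c_out, 3, stride=stride, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        self.attention = attention
        if stride != 1 or c_in != c_out:
            self.shortcut = Sequential(
                Conv2d(c_in, c_out, 1, stride=stride, pad=0, rng=rng),
                BatchNorm2d(c_out),
            )
        else:
            self.shortcut = None

    def children(self):
        out = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2]
        if self.attention is not None:
            out.append(self.attention)
        if self.shortcut is not None:
            out.append(self.shortcut)
        return out

    def forward(self, x):
        out = self.bn2.forward(
            self.conv2.forward(self.relu1.forward(self.bn1.forward(self.conv1.forward(x))))
        )
        if self.attention is not None:
            out = self.attention.forward(out)
        sc = x if self.shortcut is None else self.shortcut.forward(x)
        self._mask = (out + sc) > 0
        return np.where(self._mask, out + sc, 0).astype(DTYPE)

    def backward(self, dy):
        dy = np.where(self._mask, dy, 0).astype(DTYPE)
        d_main = dy
        if self.attention is not None:
            d_main = self.attention.backward(d_main)
        d_main = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(d_main))))
        )
        d_sc = dy if self.shortcut is None else self.shortcut.backward(dy)
        return (d_main + d_sc).astype(DTYPE)
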