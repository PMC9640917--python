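"""Channel-attention blocks: SE, ECA, and the prior-biased modality gate.

The modality gate (``ModalityChannelGate``) is a squeeze-and-excitation unit
applied to the raw modality channels of the input stack, with a fixed additive
bias ``log(p_c / mean(p))`` on the gate logits encoding a radiologist prior
``p`` over channels (e.g. upweighting the CT arterial phase). Only ratios of
``p`` matter. The excitation output layer is zero-initialised so training
starts from the prior alone (uniform prior => every gate is exactly 0.5).
"""

from __future__ import annotations

import numpy as np

from .layers import DTYPE, Module, he_init, sigmoid


class _SqueezeExcite(Module):
    """Shared machinery: gap -> fc -> relu -> fc (+bias term) -> sigmoid -> scale."""

    def __init__(self, c, reduction, *, rng, zero_out=False, competitive=False):
        super().__init__()
        self.c = c
        # competitive gating mean-centers the learned logits across channels:
        # channels compete for attention, a collective drift of all gates is
        # impossible and only relative contributions are expressible
        self.competitive = competitive
        hidden = max(1, c // reduction)
        self.params["w1"] = he_init(rng, (hidden, c), c)
        self.params["b1"] = np.zeros(hidden, dtype=DTYPE)
        if zero_out:
            self.params["w2"] = np.zeros((c, hidden), dtype=DTYPE)
        else:
            self.params["w2"] = he_init(rng, (c, hidden), hidden)
        self.params["b2"] = np.zeros(c, dtype=DTYPE)
        self.logit_bias = np.zeros(c, dtype=DTYPE)  # constant, not trained
        self.pinned_gates: np.ndarray | None = None
        self.last_gates: np.ndarray | None = None

    def _gates(self, x):
        s = x.mean(axis=(2, 3))
        h_pre = s @ self.params["w1"].T + self.params["b1"]
        h = np.maximum(h_pre, 0)
        z = h @ self.params["w2"].T + self.params["b2"]
        if self.competitive:
            z = z - z.mean(axis=1, keepdims=True)
        g = sigmoid(z + self.logit_bias).astype(DTYPE)
        return s, h_pre, h, g

    def forward(self, x):
        if self.pinned_gates is not None:
            g = np.broadcast_to(
                np.asarray(self.pinned_gates, dtype=DTYPE), (x.shape[0], self.c)
            )
            self._cache = (x, None, None, None, g)
            self.last_gates = g.mean(axis=0)
            return (x * g[:, :, None, None]).astype(DTYPE)
        s, h_pre, h, g = self._gates(x)
        self.last_gates = g.mean(axis=0)
        self._cache = (x, s, h_pre, h, g)
        return (x * g[:, :, None, None]).astype(DTYPE)

    def backward(self, dy):
        x, s, h_pre, h, g = self._cache
        dx = dy * g[:, :, None, None]
        if self.pinned_gates is not None:
            return dx.astype(DTYPE)
        dg = (dy * x).sum(axis=(2, 3))
        dz = dg * g * (1.0 - g)
        if self.competitive:
            dz = dz - dz.mean(axis=1, keepdims=True)
        self.add_grad("w2", dz.T @ h)
        self.add_grad("b2", dz.sum(axis=0))
        dh = dz @ self.params["w2"]
        dh = np.where(h_pre > 0, dh, 0)
        self.add_grad("w1", dh.T @ s)
        self.add_grad("b1", dh.sum(axis=0))
        ds = dh @ self.params["w1"]
        h_img, w_img = x.shape[2], x.shape[3]
        dx = dx + ds[:, :, None, None] / (h_img * w_img)
        return dx.astype(DTYPE)


class SEBlock(_SqueezeExcite):
    """Squeeze-and-excitation over feature channels (reduction r, default 4)."""

    def __init__(self, c, reduction=4, *, rng):
        super().__init__(c, reduction, rng=rng, zero_out=False)


class ModalityChannelGate(_SqueezeExcite):
    """SE gate over input modality channels with a log-ratio prior bias."""

    def __init__(self, n_channels, reduction=2, prior_weights=None, *, rng):
        super().__init__(n_channels, reduction, rng=rng, zero_out=True, competitive=True)
        if prior_weights is None:
            prior_weights = np.ones(n_channels)
        p = np.asarray(prior_weights, dtype=np.float64)
        if p.shape != (n_channels,):
            raise ValueError(f"prior_weights must have length {n_channels}")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValueError("prior_weights must be finite and nonnegative")
        if np.all(p == 0):
            raise ValueError("prior_weights must not be all zero")
        self.prior_weights = p
        self.logit_bias = np.log(p / p.mean()).astype(DTYPE)

    def forward(self, x):
        if x.shape[1] != self.c:
            raise ValueError(f"expected {self.c} channels, got {x.shape[1]}")
        return super().forward(x)


class ECABlock(Module):
    """Efficient channel attention: gap -> 1D conv across channels -> sigmoid."""

    def __init__(self, c, k_size=None, *, rng):
        super().__init__()
        if k_size is None:
            # adaptive odd kernel from channel count (ECA-Net heuristic)
            t = int(abs(np.log2(c) / 2.0 + 0.5))
            k_size = t if t % 2 else t + 1
            k_size = max(3, k_size)
        self.c, self.k = c, k_size
        self.params["weight"] = (rng.standard_normal(k_size) * 0.1).astype(DTYPE)

    def forward(self, x):
        s = x.mean(axis=(2, 3))  # (n, c)
        p = self.k // 2
        s_pad = np.pad(s, ((0, 0), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(s_pad, self.k, axis=1)
        z = win @ self.params["weight"]
        g = sigmoid(z).astype(DTYPE)
        self._cache = (x, win, g)
        return (x * g[:, :, None, None]).astype(DTYPE)

    def backward(self, dy):
        x, win, g = self._cache
        dx = dy * g[:, :, None, None]
        dg = (dy * x).sum(axis=(2, 3))
        dz = dg * g * (1.0 - g)
        self.add_grad("weight", np.einsum("nc,nck->k", dz, win).astype(DTYPE))
        # transpose of the sliding correlation: full correlation with flipped kernel
        p = self.k // 2
        dz_pad = np.pad(dz, ((0, 0), (p, p)))
        win_b = np.lib.stride_tricks.sliding_window_view(dz_pad, self.k, axis=1)
        ds = win_b @ self.params["weight"][::-1].copy()
        h_img, w_img = x.shape[2], x.shape[3]
        dx = dx + ds[:, :, None, None] / (h_img * w_img)
        return dx.astype(DTYPE)
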