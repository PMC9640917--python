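"""Minimal CPU neural-network layers with explicit forward/backward passes.

All arrays are float32, NCHW layout for images. Every layer caches what its
backward pass needs during forward; calling ``backward`` before ``forward``
is a usage error. Convolutions use im2col + BLAS matmul, which is the fastest
pure-numpy route on a single CPU core.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Module:
    """Base class: holds ``params``/``grads`` dicts and child modules."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    # -- composition ------------------------------------------------------
    def children(self):
        return []

    def modules(self):
        yield self
        for c in self.children():
            yield from c.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- parameters -------------------------------------------------------
    def named_parameters(self):
        """Yield (module, key) references in deterministic traversal order."""
        for m in self.modules():
            for k in sorted(m.params):
                yield m, k

    def zero_grad(self):
        for m, k in self.named_parameters():
            m.grads[k] = np.zeros_like(m.params[k])

    def add_grad(self, key, value):
        """Accumulate into ``grads[key]``, initialising it on first use."""
        if key in self.grads:
            self.grads[key] += value
        else:
            self.grads[key] = np.asarray(value, dtype=self.params[key].dtype).reshape(
                self.params[key].shape
            ).copy()

    def n_parameters(self) -> int:
        return int(sum(p.size for _, p in self.iter_arrays()))

    def iter_arrays(self):
        for m, k in self.named_parameters():
            yield f"{id(m)}.{k}", m.params[k]

    def state_arrays(self) -> list[np.ndarray]:
        """Parameters plus persistent buffers, in traversal order."""
        out = []
        for m in self.modules():
            for k in sorted(m.params):
                out.append(m.params[k])
            for k in sorted(getattr(m, "buffers", {})):
                out.append(m.buffers[k])
        return out

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        live = self.state_arrays()
        if len(live) != len(state):
            raise ValueError("state length mismatch")
        for dst, src in zip(live, state):
            if dst.shape != src.shape:
                raise ValueError("state shape mismatch")
        for dst, src in zip(live, state):
            dst[...] = src

    def save(self, path) -> None:
        np.savez(path, *self.state_arrays())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.set_state([data[k] for k in data.files])

    # -- computation ------------------------------------------------------
    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def children(self):
        return self.layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv2d(Module):
    """3x3 (or kxk) convolution, zero padding k//2 by default, optional bias."""

    def __init__(self, c_in, c_out, k=3, stride=1, pad=None, bias=False, *, rng):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = k // 2 if pad is None else pad
        self.params["weight"] = he_init(rng, (c_out, c_in, k, k), c_in * k * k)
        if bias:
            self.params["bias"] = np.zeros(c_out, dtype=DTYPE)

    def _im2col(self, x):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        hp, wp = x.shape[2], x.shape[3]
        ho = (hp - k) // s + 1
        wo = (wp - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (n, c, ho, wo, k, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
        return cols.reshape(n * ho * wo, c * k * k), (n, ho, wo, hp, wp)

    def forward(self, x):
        cols, (n, ho, wo, hp, wp) = self._im2col(x)
        w_mat = self.params["weight"].reshape(self.c_out, -1)
        out = cols @ w_mat.T
        if "bias" in self.params:
            out += self.params["bias"]
        self._cache = (cols, x.shape, (n, ho, wo, hp, wp))
        return np.ascontiguousarray(
            out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)
        )

    def backward(self, dy):
        cols, x_shape, (n, ho, wo, hp, wp) = self._cache
        k, s, p = self.k, self.stride, self.pad
        dy_mat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.add_grad("weight", (dy_mat.T @ cols).reshape(self.params["weight"].shape))
        if "bias" in self.params:
            self.add_grad("bias", dy_mat.sum(axis=0))
        dcols = dy_mat @ self.params["weight"].reshape(self.c_out, -1)
        dcols = dcols.reshape(n, ho, wo, self.c_in, k, k).transpose(0, 3, 4, 5, 1, 2)
        dx_pad = np.zeros((n, self.c_in, hp, wp), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dx_pad[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        if p:
            dx_pad = dx_pad[:, :, p:-p, p:-p]
        return np.ascontiguousarray(dx_pad)


class ChannelNormalizedConv2d(Conv2d):
    """Convolution whose weight energy per *input* channel is fixed to 1.

    The effective weight is ``w / ||w[:, c]||_F`` per input channel ``c``, so
    the network cannot re-encode an input-channel gain inside this layer:
    when it follows a channel gate, the gate is the sole carrier of channel
    importance (identifiability of the attention profile).
    """

    _EPS = 1e-8

    def _normalized(self):
        w = self.params["weight"]
        norms = np.sqrt((w * w).sum(axis=(0, 2, 3)) + self._EPS)
        return w / norms[None, :, None, None], norms

    def forward(self, x):
        w_raw = self.params["weight"]
        w_hat, norms = self._normalized()
        self.params["weight"] = w_hat
        try:
            out = super().forward(x)
        finally:
            self.params["weight"] = w_raw
        self._norm_cache = (w_hat.copy(), norms)
        return out

    def backward(self, dy):
        w_raw = self.params["weight"]
        w_hat, norms = self._norm_cache
        self.params["weight"] = w_hat
        saved = self.grads.pop("weight", None)
        try:
            dx = super().backward(dy)
            dw_hat = self.grads["weight"]
        finally:
            self.params["weight"] = w_raw
        # project out the per-channel radial component and rescale
        inner = (dw_hat * w_hat).sum(axis=(0, 2, 3))
        dw = (dw_hat - w_hat * inner[None, :, None, None]) / norms[None, :, None, None]
        self.grads["weight"] = dw.astype(DTYPE)
        if saved is not None:
            self.grads["weight"] += saved
        return dx


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(c, dtype=DTYPE)
        self.params["beta"] = np.zeros(c, dtype=DTYPE)
        self.buffers = {
            "running_mean": np.zeros(c, dtype=DTYPE),
            "running_var": np.ones(c, dtype=DTYPE),
        }

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            rm, rv = self.buffers["running_mean"], self.buffers["running_var"]
            rm += self.momentum * (mean.astype(DTYPE) - rm)
            rv += self.momentum * (var.astype(DTYPE) - rv)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        out = self.params["gamma"][:, None, None] * xhat + self.params["beta"][:, None, None]
        self._cache = (xhat.astype(DTYPE), inv_std.astype(DTYPE))
        return out.astype(DTYPE)

    def backward(self, dy):
        xhat, inv_std = self._cache
        self.add_grad("gamma", (dy * xhat).sum(axis=(0, 2, 3)))
        self.add_grad("beta", dy.sum(axis=(0, 2, 3)))
        g = self.params["gamma"][:, None, None]
        dxhat = dy * g
        if not self.training:
            return (dxhat * inv_std[:, None, None]).astype(DTYPE)
        mean_dxhat = dxhat.mean(axis=(0, 2, 3), keepdims=False)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3))
        dx = (
            dxhat
            - mean_dxhat[:, None, None]
            - xhat * mean_dxhat_xhat[:, None, None]
        ) * inv_std[:, None, None]
        return dx.astype(DTYPE)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE)

    def backward(self, dy):
        return np.where(self._mask, dy, 0).astype(DTYPE)


class AvgPool2d(Module):
    """Non-overlapping k x k mean pooling (anti-noise low-pass)."""

    def __init__(self, k=2):
        super().__init__()
        self.k = k

    def forward(self, x):
        n, c, h, w = x.shape
        k = self.k
        if h % k or w % k:
            raise ValueError(f"spatial size {h}x{w} not divisible by pool {k}")
        self._shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5)).astype(DTYPE)

    def backward(self, dy):
        n, c, h, w = self._shape
        k = self.k
        out = np.repeat(np.repeat(dy, k, axis=2), k, axis=3) / (k * k)
        return out.astype(DTYPE)


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(DTYPE)

    def backward(self, dy):
        n, c, h, w = self._shape
        return (np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)).astype(DTYPE)


class Flatten(Module):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Module):
    def __init__(self, d_in, d_out, *, rng, zero_init=False):
        super().__init__()
        if zero_init:
            self.params["weight"] = np.zeros((d_out, d_in), dtype=DTYPE)
        else:
            self.params["weight"] = he_init(rng, (d_out, d_in), d_in)
        self.params["bias"] = np.zeros(d_out, dtype=DTYPE)

    def forward(self, x):
        self._x = x
        return x @ self.params["weight"].T + self.params["bias"]

    def backward(self, dy):
        self.add_grad("weight", dy.T @ self._x)
        self.add_grad("bias", dy.sum(axis=0))
        return (dy @ self.params["weight"]).astype(DTYPE)


class L2Normalize(Module):
    """Row-wise projection onto the unit sphere (embedding convention)."""

    def __init__(self, eps=1e-12):
        super().__init__()
        self.eps = eps

    def forward(self, x):
        norm = np.sqrt((x * x).sum(axis=1, keepdims=True) + self.eps)
        y = x / norm
        self._cache = (y, norm)
        return y.astype(DTYPE)

    def backward(self, dy):
        y, norm = self._cache
        proj = (dy * y).sum(axis=1, keepdims=True)
        return ((dy - y * proj) / norm).astype(DTYPE)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))
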