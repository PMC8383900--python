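"""Minimal CPU convolutional-network engine (NumPy, manual backprop).

Implements exactly what the segmentation model needs: 2-D convolutions
via im2col/col2im, ReLU, nearest-neighbor 2x upsampling, residual blocks,
a sigmoid + binary-cross-entropy head, and Adam. Everything is float32
and driven by an explicit ``numpy.random.Generator``, so training is
bit-reproducible for a fixed seed on a given platform.

Tensors are laid out ``(N, C, H, W)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D", "ReLU", "Upsample2x", "Residual", "Sequential", "Adam",
    "sigmoid", "bce_with_logits",
]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]
    ho, wo = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), (ho, wo)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int,
            out_hw: tuple[int, int]) -> np.ndarray:
    n, c, h, w = x_shape
    ho, wo = out_hw
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, c, k, k, ho, wo)
    for di in range(k):
        for dj in range(k):
            dx[:, :, di:di + stride * ho:stride, dj:dj + stride * wo:stride] += \
                d[:, :, di, dj]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2D:
    """2-D convolution with He-initialized weights."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = (k // 2) if pad is None else pad
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((cout, cin * k * k)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self._cache: tuple | None = None

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def set_param(self, name, value):
        setattr(self, name, value)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        out = np.matmul(self.W, cols) + self.b[:, None]
        self._cache = (x.shape, cols, (ho, wo))
        return out.reshape(x.shape[0], -1, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, cols, out_hw = self._cache
        n = dout.shape[0]
        d2 = dout.reshape(n, dout.shape[1], -1)
        self.dW = np.einsum("ncl,ndl->cd", d2, cols, optimize=True)
        self.db = d2.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T, d2)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, out_hw)

    def grads(self):
        return [("W", self.dW), ("b", self.db)]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class Upsample2x:
    """Nearest-neighbor spatial doubling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def params(self):
        return []

    def grads(self):
        return []


class Residual:
    """y = relu(x + f(x)) for a channel-preserving inner stack ``f``."""

    def __init__(self, inner: list):
        self.inner = inner

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x
        for layer in self.inner:
            y = layer.forward(y)
        s = x + y
        self._mask = s > 0
        return s * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        ds = dout * self._mask
        dy = ds
        for layer in reversed(self.inner):
            dy = layer.backward(dy)
        return ds + dy

    def params(self):
        out = []
        for i, layer in enumerate(self.inner):
            out.extend(((f"{i}.{n}", v) for n, v in layer.params()))
        return out

    def grads(self):
        out = []
        for i, layer in enumerate(self.inner):
            out.extend(((f"{i}.{n}", v) for n, v in layer.grads()))
        return out


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def named_params(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for i, layer in enumerate(self.layers):
            out.extend(((f"{i}.{n}", v) for n, v in layer.params()))
        return out

    def named_grads(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for i, layer in enumerate(self.layers):
            out.extend(((f"{i}.{n}", v) for n, v in layer.grads()))
        return out

    def load_named_params(self, state: dict[str, np.ndarray]) -> None:
        for name, param in self.named_params():
            param[...] = state[name]


class Adam:
    """Adam optimizer over a Sequential's parameters (in-place updates)."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        params = dict(self.model.named_params())
        for name, g in self.model.named_grads():
            g = g.astype(np.float32)
            m = self.m.setdefault(name, np.zeros_like(g))
            v = self.v.setdefault(name, np.zeros_like(g))
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            params[name][...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray,
                    pos_weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. logits ``z``.

    ``pos_weight`` scales the positive-class term, the usual remedy for
    the foreground/background imbalance of segmentation masks.
    """
    p = sigmoid(z)
    eps = 1e-7
    w = np.where(y > 0.5, pos_weight, 1.0)
    loss = -(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))).mean()
    dz = (w * (p - y) / z.size).astype(np.float32)
    return float(loss), dz
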