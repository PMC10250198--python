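"""Minimal NumPy layer stack with manual backpropagation.

Implements exactly the pieces the embedding network needs — 3D convolution
(im2col + GEMM), group normalization, leaky rectifier, max / adaptive-max
pooling, dropout, fully connected layers, L2 normalization — plus an Adam
optimizer.  All tensors are float32 with layout ``(N, C, D, H, W)``.

Forward passes cache intermediates only when ``train=True``; inference is
cache-free and deterministic (dropout inactive).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Sequential",
    "Conv3d",
    "GroupNorm",
    "LeakyReLU",
    "MaxPool3d",
    "AdaptiveMaxPool3d",
    "Flatten",
    "Dropout",
    "Linear",
    "L2Normalize",
    "Adam",
]

_F32 = np.float32


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=_F32)
        self.grad = np.zeros_like(self.value)


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, train=False):
        return self.forward(x, train=train)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _he_std(fan_in: int, negative_slope: float) -> float:
    gain = np.sqrt(2.0 / (1.0 + negative_slope**2))
    return float(gain / np.sqrt(fan_in))


class Conv3d(Module):
    """3x3x3 convolution with unit zero-padding (spatial size preserved)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 negative_slope: float = 0.1):
        self.c_in, self.c_out = c_in, c_out
        std = _he_std(c_in * 27, negative_slope)
        self.w = Param(rng.normal(0.0, std, size=(c_out, c_in, 3, 3, 3)))
        self.b = Param(np.zeros(c_out))
        self._cols = None

    def params(self):
        return [self.w, self.b]

    @staticmethod
    def _im2col(xp: np.ndarray, d: int, h: int, w: int) -> np.ndarray:
        n, c = xp.shape[:2]
        views = []
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    views.append(xp[:, :, i:i + d, j:j + h, k:k + w])
        cols = np.stack(views, axis=2)            # (N, C, 27, D, H, W)
        return cols.reshape(n, c * 27, d * h * w)

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        cols = self._im2col(xp, d, h, w)
        w2 = self.w.value.reshape(self.c_out, -1)
        out = np.matmul(w2, cols)                 # (N, C_out, P)
        out += self.b.value[:, None]
        if train:
            self._cols = cols
            self._spatial = (d, h, w)
        return np.ascontiguousarray(out.reshape(n, self.c_out, d, h, w))

    def backward(self, grad):
        d, h, w = self._spatial
        n = grad.shape[0]
        g2 = grad.reshape(n, self.c_out, -1)
        self.b.grad += g2.sum(axis=(0, 2))
        dw = np.matmul(g2, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.w.grad += dw.reshape(self.w.value.shape)
        w2 = self.w.value.reshape(self.c_out, -1)
        dcols = np.matmul(w2.T, g2)               # (N, C_in*27, P)
        dcols = dcols.reshape(n, self.c_in, 27, d, h, w)
        dxp = np.zeros((n, self.c_in, d + 2, h + 2, w + 2), dtype=_F32)
        idx = 0
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    dxp[:, :, i:i + d, j:j + h, k:k + w] += dcols[:, :, idx]
                    idx += 1
        self._cols = None
        return dxp[:, :, 1:1 + d, 1:1 + h, 1:1 + w]


class GroupNorm(Module):
    """Group normalization over (channel-group, D, H, W) per sample."""

    def __init__(self, channels: int, groups: int = 64, eps: float = 1e-5):
        groups = min(groups, channels)
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.channels, self.groups, self.eps = channels, groups, eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).astype(_F32)
        if train:
            self._xhat, self._inv = xhat, inv.astype(_F32)
            self._shape = x.shape
        out = xhat.reshape(n, c, d, h, w)
        gam = self.gamma.value[None, :, None, None, None]
        bet = self.beta.value[None, :, None, None, None]
        return out * gam + bet

    def backward(self, grad):
        n, c, d, h, w = self._shape
        g = self.groups
        self.gamma.grad += (grad * self._xhat.reshape(n, c, d, h, w)).sum(axis=(0, 2, 3, 4))
        self.beta.grad += grad.sum(axis=(0, 2, 3, 4))
        gam = self.gamma.value[None, :, None, None, None]
        dxhat = (grad * gam).reshape(n, g, -1)
        m = dxhat.shape[2]
        xhat = self._xhat
        t1 = dxhat.sum(axis=2, keepdims=True)
        t2 = (dxhat * xhat).sum(axis=2, keepdims=True)
        dx = self._inv / m * (m * dxhat - t1 - xhat * t2)
        self._xhat = None
        return dx.reshape(n, c, d, h, w).astype(_F32)


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.1):
        self.slope = negative_slope

    def forward(self, x, train=False):
        out = np.where(x >= 0, x, self.slope * x).astype(_F32)
        if train:
            self._mask = x >= 0
        return out

    def backward(self, grad):
        out = np.where(self._mask, grad, self.slope * grad).astype(_F32)
        self._mask = None
        return out


class MaxPool3d(Module):
    """2x2x2 max pooling with stride 2; trailing odd voxels are dropped.

    Gradient at ties is split equally between the tied positions.
    """

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        xc = x[:, :, :2 * d2, :2 * h2, :2 * w2]
        win = xc.reshape(n, c, d2, 2, h2, 2, w2, 2)
        out = win.max(axis=(3, 5, 7))
        if train:
            mask = (win == out[:, :, :, None, :, None, :, None])
            counts = mask.sum(axis=(3, 5, 7), keepdims=True)
            self._mask = mask / counts
            self._inshape = x.shape
        return out

    def backward(self, grad):
        n, c, d, h, w = self._inshape
        d2, h2, w2 = d // 2, h // 2, w // 2
        gexp = grad[:, :, :, None, :, None, :, None] * self._mask
        dx = np.zeros(self._inshape, dtype=_F32)
        dx[:, :, :2 * d2, :2 * h2, :2 * w2] = gexp.reshape(n, c, 2 * d2, 2 * h2, 2 * w2)
        self._mask = None
        return dx


class AdaptiveMaxPool3d(Module):
    """Max pooling to a fixed 2x2x2 output, regions as in common DL practice:
    output cell i covers [floor(i*S/2), ceil((i+1)*S/2))."""

    @staticmethod
    def _bounds(size: int):
        return [(0, -(-size // 2)), (size // 2, size)]

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        out = np.empty((n, c, 2, 2, 2), dtype=_F32)
        if train:
            self._inshape = x.shape
            self._masks = {}
        bd, bh, bw = self._bounds(d), self._bounds(h), self._bounds(w)
        for i, (d0, d1) in enumerate(bd):
            for j, (h0, h1) in enumerate(bh):
                for k, (w0, w1) in enumerate(bw):
                    region = x[:, :, d0:d1, h0:h1, w0:w1]
                    mx = region.max(axis=(2, 3, 4))
                    out[:, :, i, j, k] = mx
                    if train:
                        mask = region == mx[:, :, None, None, None]
                        cnt = mask.sum(axis=(2, 3, 4), keepdims=True)
                        self._masks[(i, j, k)] = ((d0, h0, w0), mask / cnt)
        return out

    def backward(self, grad):
        dx = np.zeros(self._inshape, dtype=_F32)
        for (i, j, k), ((d0, h0, w0), mask) in self._masks.items():
            sd, sh, sw = mask.shape[2:]
            dx[:, :, d0:d0 + sd, h0:h0 + sh, w0:w0 + sw] += (
                grad[:, :, i, j, k][:, :, None, None, None] * mask)
        self._masks = None
        return dx


class Flatten(Module):
    def forward(self, x, train=False):
        if train:
            self._inshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._inshape)


class Dropout(Module):
    """Inverted dropout; identity when ``train`` is False or rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_F32) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        out = grad * self._mask
        self._mask = None
        return out


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 negative_slope: float = 0.1):
        std = _he_std(n_in, negative_slope)
        self.w = Param(rng.normal(0.0, std, size=(n_out, n_in)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad):
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        dx = grad @ self.w.value
        self._x = None
        return dx


class L2Normalize(Module):
    """Project row vectors onto the unit hypersphere."""

    def __init__(self, eps: float = 1e-8):
        self.eps = eps

    def forward(self, x, train=False):
        norm = np.linalg.norm(x, axis=1, keepdims=True)
        if np.any(norm < self.eps):
            raise FloatingPointError(
                "degenerate embedding: pre-normalization vector has ~zero norm")
        y = (x / norm).astype(_F32)
        if train:
            self._y, self._norm = y, norm
        return y

    def backward(self, grad):
        y, norm = self._y, self._norm
        dot = (grad * y).sum(axis=1, keepdims=True)
        dx = (grad - y * dot) / norm
        self._y = self._norm = None
        return dx.astype(_F32)


class Adam:
    """Adaptive moment estimation over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
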