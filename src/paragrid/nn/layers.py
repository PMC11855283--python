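"""Layer implementations.

Tensor layout is channels-first, ``(B, C, D, H, W)``, for volumetric
layers and ``(B, T, C)`` for token layers.  3D convolution is computed by
shift-and-matmul: one GEMM per kernel offset, which keeps memory flat
(no im2col buffer) and is the fastest pure-NumPy formulation at these
problem sizes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter", "Module", "Conv3d", "BatchNorm3d", "ReLU", "MaxPool3d",
    "Linear", "Dropout", "LayerNorm", "MultiHeadSelfAttention",
    "TransformerBlock", "Sequential", "GlobalAvgPool3d", "sigmoid",
    "bce_with_logits",
]


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Module:
    """Base class: subclasses implement forward/backward and list params."""

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x, training: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, training: bool = False):
        return self.forward(x, training)


def _out_dim(n: int, k: int, s: int, p: int, d: int) -> int:
    return (n + 2 * p - d * (k - 1) - 1) // s + 1


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: int | None = None, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        if padding is None:
            padding = dilation * (kernel - 1) // 2
        self.cin, self.cout, self.k = cin, cout, kernel
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = cin * kernel ** 3
        w = rng.standard_normal((cout, cin, kernel, kernel, kernel)) * np.sqrt(2.0 / fan_in)
        self.weight = Parameter(w.astype(dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype)) if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _slices(self, ki, kj, kk, Do, Ho, Wo):
        s, d = self.stride, self.dilation
        return (
            slice(ki * d, ki * d + (Do - 1) * s + 1, s),
            slice(kj * d, kj * d + (Ho - 1) * s + 1, s),
            slice(kk * d, kk * d + (Wo - 1) * s + 1, s),
        )

    def forward(self, x, training=False):
        B, C, D, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        Do = _out_dim(D, self.k, self.stride, p, self.dilation)
        Ho = _out_dim(H, self.k, self.stride, p, self.dilation)
        Wo = _out_dim(W, self.k, self.stride, p, self.dilation)
        out = np.zeros((B, self.cout, Do, Ho, Wo), dtype=x.dtype)
        out2 = out.reshape(B, self.cout, -1)
        for ki in range(self.k):
            for kj in range(self.k):
                for kk in range(self.k):
                    sl = self._slices(ki, kj, kk, Do, Ho, Wo)
                    xs = xp[:, :, sl[0], sl[1], sl[2]].reshape(B, C, -1)
                    Wk = self.weight.value[:, :, ki, kj, kk]
                    out2 += np.matmul(Wk, xs)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None, None]
        self._cache = (xp, x.shape, (Do, Ho, Wo)) if training else None
        return out

    def backward(self, dy):
        if self._cache is None:
            raise RuntimeError("backward called without a training-mode forward")
        xp, xshape, (Do, Ho, Wo) = self._cache
        B = xshape[0]
        p = self.padding
        dy2 = dy.reshape(B, self.cout, -1)
        dxp = np.zeros_like(xp)
        for ki in range(self.k):
            for kj in range(self.k):
                for kk in range(self.k):
                    sl = self._slices(ki, kj, kk, Do, Ho, Wo)
                    xs = xp[:, :, sl[0], sl[1], sl[2]].reshape(B, self.cin, -1)
                    # dW: sum over batch and positions
                    self.weight.grad[:, :, ki, kj, kk] += np.tensordot(
                        dy2, xs, axes=([0, 2], [0, 2]))
                    Wk = self.weight.value[:, :, ki, kj, kk]
                    dxs = np.matmul(Wk.T, dy2).reshape(B, self.cin, Do, Ho, Wo)
                    dxp[:, :, sl[0], sl[1], sl[2]] += dxs
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3, 4))
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class BatchNorm3d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Parameter(np.ones(c, dtype=dtype))
        self.beta = Parameter(np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        axes = (0, 2, 3, 4)
        shape = (1, self.c, 1, 1, 1)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        if training:
            self._cache = (xhat, invstd, x.shape)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dy):
        xhat, invstd, xshape = self._cache
        shape = (1, self.c, 1, 1, 1)
        axes = (0, 2, 3, 4)
        N = dy.size // self.c
        dgamma = (dy * xhat).sum(axis=axes)
        dbeta = dy.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value.reshape(shape) * invstd.reshape(shape)
        dx = g / N * (N * dy - dbeta.reshape(shape) - xhat * dgamma.reshape(shape))
        return dx.astype(dy.dtype)


class ReLU(Module):
    def forward(self, x, training=False):
        mask = x > 0
        if training:
            self._mask = mask
        return x * mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool3d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        self.k, self.stride, self.padding = kernel, stride, padding
        self._cache = None

    def forward(self, x, training=False):
        B, C, D, H, W = x.shape
        p = self.padding
        neg = np.finfo(x.dtype).min
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)), constant_values=neg)
        Do = _out_dim(D, self.k, self.stride, p, 1)
        Ho = _out_dim(H, self.k, self.stride, p, 1)
        Wo = _out_dim(W, self.k, self.stride, p, 1)
        s = self.stride
        best = np.full((B, C, Do, Ho, Wo), neg, dtype=x.dtype)
        arg = np.zeros((B, C, Do, Ho, Wo), dtype=np.int8)
        off = 0
        for ki in range(self.k):
            for kj in range(self.k):
                for kk in range(self.k):
                    xs = xp[:, :, ki:ki + (Do - 1) * s + 1:s,
                            kj:kj + (Ho - 1) * s + 1:s,
                            kk:kk + (Wo - 1) * s + 1:s]
                    better = xs > best
                    best = np.where(better, xs, best)
                    arg = np.where(better, np.int8(off), arg)
                    off += 1
        if training:
            self._cache = (arg, xp.shape, x.shape, (Do, Ho, Wo))
        return best

    def backward(self, dy):
        arg, xpshape, xshape, (Do, Ho, Wo) = self._cache
        p, s = self.padding, self.stride
        dxp = np.zeros(xpshape, dtype=dy.dtype)
        off = 0
        for ki in range(self.k):
            for kj in range(self.k):
                for kk in range(self.k):
                    mask = arg == off
                    dxp[:, :, ki:ki + (Do - 1) * s + 1:s,
                        kj:kj + (Ho - 1) * s + 1:s,
                        kk:kk + (Wo - 1) * s + 1:s] += dy * mask
                    off += 1
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        w = rng.standard_normal((cin, cout)) * np.sqrt(2.0 / cin)
        self.weight = Parameter(w.astype(dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype))
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.weight.grad += x2.T @ dy2
        self.bias.grad += dy2.sum(axis=0)
        return dy @ self.weight.value.T


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class LayerNorm(Module):
    def __init__(self, c: int, eps: float = 1e-5, dtype=np.float32):
        self.c, self.eps = c, eps
        self.gamma = Parameter(np.ones(c, dtype=dtype))
        self.beta = Parameter(np.zeros(c, dtype=dtype))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        if training:
            self._cache = (xhat, invstd)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, invstd = self._cache
        axes = tuple(range(dy.ndim - 1))
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = dy * self.gamma.value
        n = self.c
        dx = invstd / n * (
            n * g - g.sum(axis=-1, keepdims=True)
            - xhat * (g * xhat).sum(axis=-1, keepdims=True)
        )
        return dx.astype(dy.dtype)


class MultiHeadSelfAttention(Module):
    def __init__(self, c: int, heads: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        if c % heads != 0:
            raise ValueError("channel width must be divisible by the head count")
        rng = rng or np.random.default_rng(0)
        self.c, self.h = c, heads
        self.dh = c // heads
        self.qkv = Linear(c, 3 * c, rng=rng, dtype=dtype)
        self.proj = Linear(c, c, rng=rng, dtype=dtype)

    def params(self):
        return self.qkv.params() + self.proj.params()

    def forward(self, x, training=False):
        B, T, C = x.shape
        qkv = self.qkv.forward(x, training)
        q, k, v = np.split(qkv, 3, axis=-1)
        # (B, h, T, dh)
        def heads(a):
            return a.reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)
        q, k, v = heads(q), heads(k), heads(v)
        scale = 1.0 / np.sqrt(self.dh)
        att = np.matmul(q, k.transpose(0, 1, 3, 2)) * scale
        att -= att.max(axis=-1, keepdims=True)
        p = np.exp(att)
        p /= p.sum(axis=-1, keepdims=True)
        y = np.matmul(p, v)  # (B, h, T, dh)
        out = y.transpose(0, 2, 1, 3).reshape(B, T, C)
        if training:
            self._cache = (q, k, v, p)
        return self.proj.forward(out, training)

    def backward(self, dy):
        q, k, v, p = self._cache
        B, h, T, dh = q.shape
        dout = self.proj.backward(dy)
        dyh = dout.reshape(B, T, h, dh).transpose(0, 2, 1, 3)
        dp = np.matmul(dyh, v.transpose(0, 1, 3, 2))
        dv = np.matmul(p.transpose(0, 1, 3, 2), dyh)
        datt = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
        scale = 1.0 / np.sqrt(dh)
        datt *= scale
        dq = np.matmul(datt, k)
        dk = np.matmul(datt.transpose(0, 1, 3, 2), q)
        def merge(a):
            return a.transpose(0, 2, 1, 3).reshape(B, T, h * dh)
        dqkv = np.concatenate([merge(dq), merge(dk), merge(dv)], axis=-1)
        return self.qkv.backward(dqkv)


class TransformerBlock(Module):
    """Pre-norm transformer block: self-attention + 2-layer MLP, residual."""

    def __init__(self, c: int, heads: int, mlp_ratio: int = 2,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.ln1 = LayerNorm(c, dtype=dtype)
        self.attn = MultiHeadSelfAttention(c, heads, rng=rng, dtype=dtype)
        self.ln2 = LayerNorm(c, dtype=dtype)
        self.fc1 = Linear(c, c * mlp_ratio, rng=rng, dtype=dtype)
        self.act = ReLU()
        self.fc2 = Linear(c * mlp_ratio, c, rng=rng, dtype=dtype)

    def params(self):
        return (self.ln1.params() + self.attn.params() + self.ln2.params()
                + self.fc1.params() + self.fc2.params())

    def forward(self, x, training=False):
        x = x + self.attn.forward(self.ln1.forward(x, training), training)
        x = x + self.fc2.forward(
            self.act.forward(self.fc1.forward(self.ln2.forward(x, training), training),
                             training), training)
        return x

    def backward(self, dy):
        d_mlp = self.ln2.backward(
            self.fc1.backward(self.act.backward(self.fc2.backward(dy))))
        dy = dy + d_mlp
        d_att = self.ln1.backward(self.attn.backward(dy))
        return dy + d_att


class GlobalAvgPool3d(Module):
    """(B, C, D, H, W) -> (B, C) mean over the spatial axes."""

    def forward(self, x, training=False):
        if training:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy):
        B, C, D, H, W = self._shape
        return np.broadcast_to(
            dy[:, :, None, None, None], self._shape
        ).astype(dy.dtype) / (D * H * W)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def params(self):
        out = []
        for m in self.modules:
            out.extend(m.params())
        return out

    def forward(self, x, training=False):
        for m in self.modules:
            x = m.forward(x, training)
        return x

    def backward(self, dy):
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = z.astype(np.float64)
    y = y.astype(np.float64)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = (sigmoid(z) - y) / len(z)
    return float(loss), dz
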