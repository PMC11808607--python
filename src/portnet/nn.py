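"""Minimal numpy neural-network engine used by the PortNet model.

Layers implement explicit ``forward``/``backward`` passes in float32 and hold
their trainable arrays as :class:`Param` objects, so the model can be both
trained (via :class:`Adam`) and introspected (exact trainable-parameter
enumeration, gradient capture at intermediate activations for class-activation
maps) without a deep-learning framework.

Conventions: activations are ``(N, C, H, W)`` float32; convolutions carry no
bias (they are always followed by batch normalization); 3x3 convolutions use
zero padding 1, so spatial size maps H -> ceil(H / stride) for even H.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "ReLU",
    "Linear",
    "SEGate",
    "GlobalAvgPool",
    "Adam",
    "softmax",
    "cross_entropy",
    "uniform_fan_in",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


def uniform_fan_in(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


class Conv2d(Layer):
    """Standard cross-channel convolution, bias-free.

    Weight shape ``(C_out, C_in, k, k)``; fan-in ``C_in * k * k``. k>1 runs
    as im2col + one BLAS matmul; 1x1 as a batched matmul over flattened
    spatial positions.
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride, self.padding = stride, padding
        self.weight = Param(uniform_fan_in(rng, (c_out, c_in, k, k), c_in * k * k), "conv.weight")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[1]}")
        s, k, p = self.stride, self.k, self.padding
        xp = _pad_hw(x, p)
        if k == 1:
            xs = np.ascontiguousarray(xp[:, :, ::s, ::s])
            n, c, ho, wo = xs.shape
            w2d = self.weight.value[:, :, 0, 0]
            out = np.matmul(w2d, xs.reshape(n, c, ho * wo)).reshape(n, self.c_out, ho, wo)
            self._cache = (xp.shape, xs, None)
        else:
            patches = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
            n, c, ho, wo = patches.shape[:4]
            cols = np.ascontiguousarray(patches.transpose(0, 2, 3, 1, 4, 5)
                                        ).reshape(n * ho * wo, c * k * k)
            wmat = self.weight.value.reshape(self.c_out, -1)
            out = (cols @ wmat.T).reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)
            self._cache = (xp.shape, cols, (n, ho, wo))
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s, k, p = self.stride, self.k, self.padding
        xp_shape, cached, dims = self._cache
        n, o, ho, wo = dout.shape
        if k == 1:
            xs = cached
            doutl = dout.reshape(n, o, ho * wo)
            xsl = xs.reshape(n, self.c_in, ho * wo)
            dw = np.matmul(doutl, xsl.transpose(0, 2, 1)).sum(axis=0)
            self.weight.grad += dw[:, :, None, None]
            dxp = np.zeros(xp_shape, dtype=np.float32)
            w2d = self.weight.value[:, :, 0, 0]
            dxp[:, :, ::s, ::s] = np.matmul(w2d.T, doutl).reshape(n, self.c_in, ho, wo)
        else:
            cols = cached
            dout_mat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, o)
            self.weight.grad += (dout_mat.T @ cols).reshape(self.weight.value.shape)
            dxp = np.zeros(xp_shape, dtype=np.float32)
            doutl = dout.reshape(n, o, ho * wo)
            for i in range(k):
                for j in range(k):
                    contrib = np.matmul(self.weight.value[:, :, i, j].T, doutl)
                    dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += contrib.reshape(
                        n, self.c_in, ho, wo)
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return np.ascontiguousarray(dxp)


class DepthwiseConv2d(Layer):
    """Per-channel k x k spatial convolution, bias-free; weight ``(C, k, k)``.

    Runs as k*k shifted multiply-accumulate taps, which vectorizes well for
    the small kernels used here.
    """

    def __init__(self, channels: int, k: int = 3, stride: int = 1,
                 padding: int = 1, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.channels, self.k = channels, k
        self.stride, self.padding = stride, padding
        self.weight = Param(uniform_fan_in(rng, (channels, k, k), k * k), "dwconv.weight")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight]

    def _out_hw(self, xp_shape) -> tuple[int, int]:
        s, k = self.stride, self.k
        return ((xp_shape[2] - k) // s + 1, (xp_shape[3] - k) // s + 1)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        s, k, p = self.stride, self.k, self.padding
        xp = _pad_hw(x, p)
        ho, wo = self._out_hw(xp.shape)
        out = np.zeros((x.shape[0], self.channels, ho, wo), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                out += (xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
                        * self.weight.value[:, i, j][None, :, None, None])
        self._cache = (xp, ho, wo)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s, k, p = self.stride, self.k, self.padding
        xp, ho, wo = self._cache
        dxp = np.zeros(xp.shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                xslice = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
                self.weight.grad[:, i, j] += (dout * xslice).sum(axis=(0, 2, 3))
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += (
                    dout * self.weight.value[:, i, j][None, :, None, None])
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return np.ascontiguousarray(dxp)


class BatchNorm2d(Layer):
    """Per-channel batch normalization; 2 trainable values per channel.

    Running statistics (used in eval mode) are buffers, not parameters. With
    ``momentum=None`` (default) they are cumulative averages over all
    training batches, which stays calibrated even for the short training
    schedules used here; a float momentum gives the usual exponential
    average.
    """

    def __init__(self, channels: int, eps: float = 1e-5,
                 momentum: float | None = None) -> None:
        self.channels = channels
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(channels, dtype=np.float32), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.num_batches = 0
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.num_batches += 1
            m = (1.0 / self.num_batches) if self.momentum is None else self.momentum
            n = x.shape[0] * x.shape[2] * x.shape[3]
            var_unbiased = var * (n / max(n - 1, 1))
            self.running_mean += m * (mean - self.running_mean)
            self.running_var += m * (var_unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None]).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return (dout * g * inv[None, :, None, None]).astype(np.float32)
        n = shape[0] * shape[2] * shape[3]
        dxhat = dout * g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return (dx * inv[None, :, None, None]).astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class Linear(Layer):
    """Affine map with bias; weight ``(out, in)``."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.n_in, self.n_out = n_in, n_out
        self.weight = Param(uniform_fan_in(rng, (n_out, n_in), n_in), "linear.weight")
        self.bias = Param(uniform_fan_in(rng, (n_out,), n_in), "linear.bias")
        self._x = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return (x @ self.weight.value.T + self.bias.value).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return (dout @ self.weight.value).astype(np.float32)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class SEGate(Layer):
    """Squeeze-and-excitation channel gate.

    Global average pool over space -> affine C->h (bias) -> ReLU -> affine
    h->C (bias) -> sigmoid -> per-channel rescaling of the input. Gate values
    lie strictly in (0, 1), so gated activations never exceed the input in
    magnitude.
    """

    def __init__(self, channels: int, hidden: int, rng: np.random.Generator | None = None) -> None:
        if hidden < 1:
            raise ValueError("SE hidden width must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.channels, self.hidden = channels, hidden
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self._cache = None

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.channels:
            raise ValueError(
                f"SE gate expects (n, {self.channels}, h, w), got {x.shape}")
        z = x.mean(axis=(2, 3))
        a = self.fc1.forward(z, train)
        a_relu = np.maximum(a, 0.0)
        self._relu_mask = a > 0
        g = _sigmoid(self.fc2.forward(a_relu, train))
        self._cache = (x, g)
        return (x * g[:, :, None, None]).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, g = self._cache
        h, w = x.shape[2], x.shape[3]
        dg = (dout * x).sum(axis=(2, 3))
        dpre2 = dg * g * (1.0 - g)
        da = self.fc2.backward(dpre2)
        da = np.where(self._relu_mask, da, 0.0)
        dz = self.fc1.backward(da)
        dx = dout * g[:, :, None, None] + dz[:, :, None, None] / (h * w)
        return dx.astype(np.float32)

    def gate_values(self, x: np.ndarray) -> np.ndarray:
        """Gate vector (n, C) for an input batch, without caching."""
        z = x.mean(axis=(2, 3))
        a = np.maximum(z @ self.fc1.weight.value.T + self.fc1.bias.value, 0.0)
        return _sigmoid(a @ self.fc2.weight.value.T + self.fc2.bias.value)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = p.astype(np.float32)
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - b1) * (p.grad - m)
            v += (1.0 - b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
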