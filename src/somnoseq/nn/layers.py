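"""Layers with explicit forward/backward passes.

Sequence-domain convention: convolutional layers operate on arrays of
shape ``(N, L, C)`` (batch, samples, channels); the recurrent layer on
``(B, T, F)`` (batch, time steps, features).  Every layer caches what
its backward pass needs during forward; ``backward`` must be called at
most once per forward.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    params: list[Param]

    def __init__(self) -> None:
        self.params = []

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution with 'same' padding (Keras convention) and stride."""

    def __init__(self, in_channels: int, filters: int, kernel: int, stride: int,
                 rng: np.random.Generator, dtype=np.float32, name: str = "conv"):
        super().__init__()
        self.cin, self.cout, self.k, self.s = in_channels, filters, kernel, stride
        w = glorot_uniform(rng, (kernel * in_channels, filters),
                           kernel * in_channels, filters, dtype)
        self.W = Param(f"{name}.W", w)
        self.b = Param(f"{name}.b", np.zeros(filters, dtype=dtype))
        self.params = [self.W, self.b]

    def out_length(self, L: int) -> int:
        return -(-L // self.s)  # ceil

    def _pad(self, L: int) -> tuple[int, int]:
        Lout = self.out_length(L)
        total = max((Lout - 1) * self.s + self.k - L, 0)
        return total // 2, total - total // 2

    def forward(self, x, training=False, rng=None):
        N, L, _ = x.shape
        pl, pr = self._pad(L)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        Lout = self.out_length(L)
        s0, s1, s2 = xp.strides
        win = as_strided(xp, shape=(N, Lout, self.k, self.cin),
                         strides=(s0, s1 * self.s, s1, s2))
        cols = win.reshape(N * Lout, self.k * self.cin)
        y = cols @ self.W.value + self.b.value
        self._cache = (cols, N, L, Lout, pl, pr, xp.shape[1])
        return y.reshape(N, Lout, self.cout)

    def backward(self, dy):
        cols, N, L, Lout, pl, pr, Lp = self._cache
        dyf = dy.reshape(N * Lout, self.cout)
        self.W.grad += cols.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.W.value.T).reshape(N, Lout, self.k, self.cin)
        dxp = np.zeros((N, Lp, self.cin), dtype=dy.dtype)
        for k in range(self.k):
            dxp[:, k:k + self.s * Lout:self.s, :] += dcols[:, :, k, :]
        return dxp[:, pl:Lp - pr, :] if (pl or pr) else dxp


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (N, L) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32, name: str = "bn"):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Param(f"{name}.gamma", np.ones(channels, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(channels, dtype=dtype))
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x, training=False, rng=None):
        if training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.astype(np.float64)
            self.running_var = m * self.running_var + (1 - m) * var.astype(np.float64)
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * invstd
        if training:
            self._cache = (xhat, invstd.astype(x.dtype), x.shape[0] * x.shape[1])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, invstd, M = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma.value
        # batch-statistics backward (mean and variance both depend on x)
        return (invstd / M) * (
            M * dxhat
            - dxhat.sum(axis=(0, 1))
            - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1d(Layer):
    """Valid max pooling; the usual case here is non-overlapping (p == s)."""

    def __init__(self, pool: int, stride: int):
        super().__init__()
        self.p, self.s = pool, stride

    def out_length(self, L: int) -> int:
        return (L - self.p) // self.s + 1

    def forward(self, x, training=False, rng=None):
        N, L, C = x.shape
        Lout = self.out_length(L)
        if Lout < 1:
            raise ValueError(f"pooling window {self.p} longer than input {L}")
        s0, s1, s2 = x.strides
        win = as_strided(x, shape=(N, Lout, self.p, C),
                         strides=(s0, s1 * self.s, s1, s2))
        idx = win.argmax(axis=2)
        y = np.take_along_axis(win, idx[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, (N, L, C) = self._cache
        Lout = dy.shape[1]
        dx = np.zeros((N, L, C), dtype=dy.dtype)
        if self.p <= self.s:  # no window overlap -> scatter without collisions
            dxw = np.zeros((N, Lout, self.p, C), dtype=dy.dtype)
            np.put_along_axis(dxw, idx[:, :, None, :], dy[:, :, None, :], axis=2)
            for k in range(self.p):
                dx[:, k:k + self.s * Lout:self.s, :] += dxw[:, :, k, :]
        else:
            pos = idx + (np.arange(Lout) * self.s)[None, :, None]
            np.add.at(dx, (np.arange(N)[:, None, None], pos,
                           np.arange(C)[None, None, :]), dy)
        return dx


class GlobalAvgPool1d(Layer):
    def forward(self, x, training=False, rng=None):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._L, axis=1) / self._L


class GaussianDropout(Layer):
    """Multiplicative N(1, rate/(1-rate)) noise; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._noise = None
            return x
        if rng is None:
            raise ValueError("GaussianDropout needs an rng during training")
        sd = np.sqrt(self.rate / (1.0 - self.rate))
        self._noise = rng.normal(1.0, sd, size=x.shape).astype(x.dtype)
        return x * self._noise

    def backward(self, dy):
        return dy if self._noise is None else dy * self._noise


def _hard_sigmoid(z):
    return np.clip(0.2 * z + 0.5, 0.0, 1.0)


def _hard_sigmoid_grad(z):
    return np.where((z > -2.5) & (z < 2.5), 0.2, 0.0)


class _LSTMDirection:
    """One direction of the LSTM; gate order (i, f, g, o).

    Cell activation is tanh; the recurrent (gate) activation is the
    hard sigmoid.  The forget-gate bias starts at 1.
    """

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator,
                 dtype, name: str):
        self.F, self.H = input_size, hidden
        self.Wx = Param(f"{name}.Wx", glorot_uniform(
            rng, (input_size, 4 * hidden), input_size, 4 * hidden, dtype))
        self.Wh = Param(f"{name}.Wh", glorot_uniform(
            rng, (hidden, 4 * hidden), hidden, 4 * hidden, dtype))
        b = np.zeros(4 * hidden, dtype=dtype)
        b[hidden:2 * hidden] = 1.0
        self.b = Param(f"{name}.b", b)
        self.params = [self.Wx, self.Wh, self.b]

    def forward(self, x):  # x: (B, T, F)
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        hs = np.empty((B, T, H), dtype=x.dtype)
        self._steps = []
        for t in range(T):
            z = x[:, t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            zi, zf, zg, zo = np.split(z, 4, axis=1)
            i, f, o = _hard_sigmoid(zi), _hard_sigmoid(zf), _hard_sigmoid(zo)
            g = np.tanh(zg)
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, t] = h
            self._steps.append((zi, zf, zg, zo, i, f, g, o, c_prev, tc, h_prev))
        self._x = x
        return hs

    def backward(self, dhs):  # dhs: (B, T, H)
        x = self._x
        B, T, _ = x.shape
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, self.H), dtype=x.dtype)
        dc_next = np.zeros((B, self.H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            zi, zf, zg, zo, i, f, g, o, c_prev, tc, h_prev = self._steps[t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di, dg, df = dc * g, dc * i, dc * c_prev
            dz = np.concatenate([
                di * _hard_sigmoid_grad(zi),
                df * _hard_sigmoid_grad(zf),
                dg * (1.0 - g**2),
                do * _hard_sigmoid_grad(zo),
            ], axis=1)
            self.Wx.grad += x[:, t].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
            dc_next = dc * f
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM returning one output per time step, concat of
    the two directions: (B, T, F) -> (B, T, 2H)."""

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "bilstm"):
        super().__init__()
        self.fwd = _LSTMDirection(input_size, hidden, rng, dtype, f"{name}.fwd")
        self.bwd = _LSTMDirection(input_size, hidden, rng, dtype, f"{name}.bwd")
        self.params = self.fwd.params + self.bwd.params

    def forward(self, x, training=False, rng=None):
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dy):
        H = self.fwd.H
        dxf = self.fwd.backward(dy[:, :, :H])
        dxb = self.bwd.backward(dy[:, ::-1, H:])[:, ::-1]
        return dxf + dxb


class Dense(Layer):
    """Affine map applied to the last axis (time-distributed when 3-D)."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32, name: str = "dense"):
        super().__init__()
        self.W = Param(f"{name}.W", glorot_uniform(
            rng, (in_features, out_features), in_features, out_features, dtype))
        self.b = Param(f"{name}.b", np.zeros(out_features, dtype=dtype))
        self.params = [self.W, self.b]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam with an externally supplied learning rate per step (the
    warm-restart schedule drives it)."""

    def __init__(self, params: list[Param], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
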