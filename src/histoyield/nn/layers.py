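"""Neural-network layers with hand-derived backward passes.

Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``Param.g`` during ``backward``.
Shapes follow the channels-last convention; convolution and pooling act
along the *last spatial axis only* (kernel 1x2), which is how the yield
models treat histogram bins: bands are independent rows that are never
mixed by the convolution.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Layer", "Dense", "ReLU", "Conv1x2", "MaxPool1x2",
           "BatchNorm", "Dropout", "Flatten", "AsImage", "FlattenTime",
           "LSTM", "TimeDistributed", "Sequential"]


class Param:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray, dtype=np.float32):
        self.v = np.asarray(value, dtype=dtype)
        self.g = np.zeros_like(self.v)


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []

    def state(self) -> list[np.ndarray]:
        """Non-trainable arrays that define the layer's behaviour at
        inference (e.g. batch-norm running statistics)."""
        return []

    def set_state(self, arrays: list[np.ndarray]) -> None:
        assert not arrays

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map on the last axis (shared across all leading axes)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = Param(glorot(rng, (n_in, n_out), n_in, n_out), dtype)
        self.b = Param(np.zeros(n_out), dtype)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W.v + self.b.v

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.g += x2.T @ dy2
        self.b.g += dy2.sum(axis=0)
        return dy @ self.W.v.T


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._m = x > 0
        return np.where(self._m, x, 0.0)

    def backward(self, dy):
        return np.where(self._m, dy, 0.0)


class Conv1x2(Layer):
    """2-D convolution with a 1x2 kernel and 'same' padding.

    Input (..., rows, cols, c_in); the kernel spans two adjacent columns
    (histogram bins) of one row, padded with one zero column on the right
    so the column count is preserved.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        fan_in, fan_out = 2 * c_in, 2 * c_out
        self.W0 = Param(glorot(rng, (c_in, c_out), fan_in, fan_out), dtype)
        self.W1 = Param(glorot(rng, (c_in, c_out), fan_in, fan_out), dtype)
        self.b = Param(np.zeros(c_out), dtype)

    def params(self):
        return [self.W0, self.W1, self.b]

    def forward(self, x, train, rng):
        self._x = x
        y = x @ self.W0.v
        y[..., :-1, :] += x[..., 1:, :] @ self.W1.v
        y += self.b.v
        return y

    def backward(self, dy):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        xs = np.ascontiguousarray(self._x[..., 1:, :]).reshape(-1, self._x.shape[-1])
        dys = np.ascontiguousarray(dy[..., :-1, :]).reshape(-1, dy.shape[-1])
        self.W0.g += x2.T @ dy2
        self.W1.g += xs.T @ dys
        self.b.g += dy2.sum(axis=0)
        dx = dy @ self.W0.v.T
        dx[..., 1:, :] += dy[..., :-1, :] @ self.W1.v.T
        return dx


class MaxPool1x2(Layer):
    """Max-pool of stride 2 along the column (bin) axis; needs even length."""

    def forward(self, x, train, rng):
        cols = x.shape[-2]
        if cols % 2:
            raise ValueError(f"MaxPool1x2 needs an even column count, got {cols}")
        a = x[..., ::2, :]
        b = x[..., 1::2, :]
        self._left = a >= b  # ties route the gradient to the left cell
        self._in_shape = x.shape
        return np.where(self._left, a, b)

    def backward(self, dy):
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[..., ::2, :] = np.where(self._left, dy, 0.0)
        dx[..., 1::2, :] = np.where(self._left, 0.0, dy)
        return dx


class BatchNorm(Layer):
    """Per-channel (last axis) batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3, dtype=np.float32):
        self.gamma = Param(np.ones(channels), dtype)
        self.beta = Param(np.zeros(channels), dtype)
        self.momentum = momentum
        self.eps = eps
        self.run_mean = np.zeros(channels, dtype=dtype)
        self.run_var = np.ones(channels, dtype=dtype)

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return [self.run_mean, self.run_var]

    def set_state(self, arrays):
        self.run_mean, self.run_var = arrays

    def forward(self, x, train, rng):
        C = x.shape[-1]
        if train:
            x2 = np.ascontiguousarray(x).reshape(-1, C)
            n = x2.shape[0]
            mu = x2.mean(axis=0)
            xhat = x - mu.astype(x.dtype)
            xm2 = xhat.reshape(-1, C)
            var = np.einsum("ij,ij->j", xm2, xm2) / n  # centred: no cancellation
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            self._n = n
            self._invstd = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
            xhat *= self._invstd
            self._xhat = xhat
            return xhat * self.gamma.v + self.beta.v
        xhat = (x - self.run_mean) / np.sqrt(self.run_var + self.eps)
        return self.gamma.v * xhat + self.beta.v

    def backward(self, dy):
        C = dy.shape[-1]
        xhat, invstd, n = self._xhat, self._invstd, self._n
        dy2 = np.ascontiguousarray(dy).reshape(-1, C)
        xhat2 = xhat.reshape(-1, C)
        dg = np.einsum("ij,ij->j", dy2, xhat2)
        db = dy2.sum(axis=0)
        self.gamma.g += dg
        self.beta.g += db
        dx = dy * (self.gamma.v * invstd)
        dx -= xhat * ((dg * self.gamma.v * invstd / n).astype(dy.dtype))
        dx -= (db * self.gamma.v * invstd / n).astype(dy.dtype)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    """Collapse all axes after the first into one."""

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class AsImage(Layer):
    """(N, n_bins, n_bands) -> (N, n_bands, n_bins, 1): bands become rows,
    bins become the convolved column axis, one input channel."""

    def forward(self, x, train, rng):
        return np.ascontiguousarray(np.swapaxes(x, 1, 2))[..., None]

    def backward(self, dy):
        return np.ascontiguousarray(np.swapaxes(dy[..., 0], 1, 2))


class FlattenTime(Layer):
    """(B, T, F) -> (B, T*F): concatenate all per-step feature vectors."""

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class LSTM(Layer):
    """Single-layer LSTM returning the full output sequence.

    Input (B, T, n_in) -> output (B, T, units).  Standard gate equations
    (sigmoid input/forget/output gates, tanh candidate and cell output)
    with forget-gate bias initialised to 1; gradients flow by full
    backpropagation through time.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator, dtype=np.float32):
        self.units = units
        self.dtype = dtype
        self.Wx = Param(glorot(rng, (n_in, 4 * units), n_in + units, 4 * units), dtype)
        self.Wh = Param(glorot(rng, (units, 4 * units), n_in + units, 4 * units), dtype)
        b = np.zeros(4 * units)
        b[units:2 * units] = 1.0  # forget gate bias
        self.b = Param(b, dtype)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def forward(self, x, train, rng):
        B, T, _ = x.shape
        U = self.units
        h = np.zeros((B, U), dtype=x.dtype)
        c = np.zeros((B, U), dtype=x.dtype)
        self._x = x
        self._cache = []
        xz = x.reshape(B * T, -1) @ self.Wx.v + self.b.v
        xz = xz.reshape(B, T, 4 * U)
        out = np.empty((B, T, U), dtype=x.dtype)
        for t in range(T):
            z = xz[:, t] + h @ self.Wh.v
            i = self._sigmoid(z[:, :U])
            f = self._sigmoid(z[:, U:2 * U])
            g = np.tanh(z[:, 2 * U:3 * U])
            o = self._sigmoid(z[:, 3 * U:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            out[:, t] = h
        return out

    def backward(self, dy):
        x = self._x
        B, T, _ = x.shape
        U = self.units
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, U))
        dc_next = np.zeros((B, U))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            dh = dy[:, t] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            self.Wx.g += x[:, t].T @ dz
            self.Wh.g += h_prev.T @ dz
            self.b.g += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.v.T
            dh_next = dz @ self.Wh.v.T
            dc_next = dc * f
        return dx


class TimeDistributed(Layer):
    """Apply a layer stack independently to every time step by folding the
    time axis into the batch axis."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def state(self):
        return [a for l in self.layers for a in l.state()]

    def set_state(self, arrays):
        for l in self.layers:
            n = len(l.state())
            l.set_state(arrays[:n])
            arrays = arrays[n:]

    def forward(self, x, train, rng):
        B, T = x.shape[:2]
        self._bt = (B, T)
        y = x.reshape((B * T,) + x.shape[2:])
        for l in self.layers:
            y = l.forward(y, train, rng)
        return y.reshape((B, T) + y.shape[1:])

    def backward(self, dy):
        B, T = self._bt
        d = dy.reshape((B * T,) + dy.shape[2:])
        for l in reversed(self.layers):
            d = l.backward(d)
        return d.reshape((B, T) + d.shape[1:])


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def state(self):
        return [a for l in self.layers for a in l.state()]

    def set_state(self, arrays):
        for l in self.layers:
            n = len(l.state())
            l.set_state(arrays[:n])
            arrays = arrays[n:]

    def forward(self, x, train, rng):
        for l in self.layers:
            x = l.forward(x, train, rng)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy
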