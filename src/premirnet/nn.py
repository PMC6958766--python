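"""Minimal NumPy neural-network core: layers, backprop, Adam.

Implements exactly what the two classifier architectures need — 1-D
convolution over a channels-last sequence, max pooling, dense layers,
inverted dropout, stacked LSTM with input dropout, and a softmax output
— with analytic gradients (verified against numerical differentiation in
the test suite).  Parameters live in a single configurable dtype
(float64 by default, float32 during training for speed); everything is
single-threaded NumPy, so runs are bit-reproducible given a seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ValidationError


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: holds ``params`` and matching ``grads`` lists."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def initialize(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def forward(self, x, training: bool = False, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.params = [np.zeros((n_in, n_out)), np.zeros(n_out)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def initialize(self, rng):
        self.params[0][:] = _glorot(rng, (self.n_in, self.n_out), self.n_in, self.n_out)
        self.params[1][:] = 0.0

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dy):
        self.grads[0][:] = self._x.T @ dy
        self.grads[1][:] = dy.sum(axis=0)
        return dy @ self.params[0].T


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Conv1D(Layer):
    """Valid 1-D convolution over (batch, length, channels) input."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int):
        super().__init__()
        self.in_channels, self.filters, self.kernel_size = in_channels, filters, kernel_size
        self.params = [np.zeros((kernel_size * in_channels, filters)), np.zeros(filters)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def initialize(self, rng):
        fan_in = self.kernel_size * self.in_channels
        self.params[0][:] = _glorot(rng, self.params[0].shape, fan_in, self.filters)
        self.params[1][:] = 0.0

    def out_length(self, length: int) -> int:
        return length - self.kernel_size + 1

    def forward(self, x, training=False, rng=None):
        B, L, C = x.shape
        if self.out_length(L) < 1:
            raise ValidationError(
                f"input length {L} too short for kernel size {self.kernel_size}"
            )
        # (B, Lout, C, k) -> (B, Lout, k, C) -> (B, Lout, k*C)
        win = sliding_window_view(x, self.kernel_size, axis=1)
        cols = win.transpose(0, 1, 3, 2).reshape(B, self.out_length(L), -1)
        self._cols, self._in_shape = cols, x.shape
        return cols @ self.params[0] + self.params[1]

    def backward(self, dy):
        B, Lout, F = dy.shape
        kC = self.params[0].shape[0]
        self.grads[0][:] = self._cols.reshape(-1, kC).T @ dy.reshape(-1, F)
        self.grads[1][:] = dy.sum(axis=(0, 1))
        dcols = (dy @ self.params[0].T).reshape(B, Lout, self.kernel_size, self.in_channels)
        dx = np.zeros(self._in_shape, dy.dtype)
        for t in range(self.kernel_size):
            dx[:, t : t + Lout, :] += dcols[:, :, t, :]
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the sequence axis (floor remainder)."""

    def __init__(self, pool_size: int = 2):
        super().__init__()
        self.pool_size = pool_size

    def out_length(self, length: int) -> int:
        return length // self.pool_size

    def forward(self, x, training=False, rng=None):
        B, L, C = x.shape
        Lp = self.out_length(L)
        if Lp < 1:
            raise ValidationError(f"input length {L} too short for pool size {self.pool_size}")
        trimmed = x[:, : Lp * self.pool_size, :].reshape(B, Lp, self.pool_size, C)
        self._argmax = trimmed.argmax(axis=2)
        self._in_shape = x.shape
        return trimmed.max(axis=2)

    def backward(self, dy):
        B, Lp, C = dy.shape
        dx = np.zeros(self._in_shape, dy.dtype)
        b_ix, l_ix, c_ix = np.meshgrid(
            np.arange(B), np.arange(Lp), np.arange(C), indexing="ij"
        )
        dx[b_ix, l_ix * self.pool_size + self._argmax, c_ix] = dy
        return dx


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValidationError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValidationError("training-mode dropout requires an rng")
        self._mask = ((rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Standard (no-peephole) LSTM over (batch, time, features) input.

    Gate order in the fused weight matrices is input, forget, candidate,
    output.  The forget-gate bias initializes to 1.  ``input_dropout``
    applies inverted dropout to this layer's inputs during training,
    with an independent mask per element.
    """

    def __init__(self, n_in: int, units: int, return_sequences: bool = False,
                 input_dropout: float = 0.0):
        super().__init__()
        if not (0.0 <= input_dropout < 1.0):
            raise ValidationError(f"input_dropout {input_dropout} outside [0, 1)")
        self.n_in, self.units = n_in, units
        self.return_sequences = return_sequences
        self.input_dropout = input_dropout
        H = units
        self.params = [np.zeros((n_in, 4 * H)), np.zeros((H, 4 * H)), np.zeros(4 * H)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def initialize(self, rng):
        H = self.units
        self.params[0][:] = _glorot(rng, (self.n_in, 4 * H), self.n_in, H)
        self.params[1][:] = _glorot(rng, (H, 4 * H), H, H)
        self.params[2][:] = 0.0
        self.params[2][H : 2 * H] = 1.0  # forget-gate bias

    def forward(self, x, training=False, rng=None):
        Wx, Uh, b = self.params
        B, T, D = x.shape
        H = self.units
        if training and self.input_dropout > 0.0:
            if rng is None:
                raise ValidationError("training-mode dropout requires an rng")
            self._mask = ((rng.random(x.shape) >= self.input_dropout)
                          / (1.0 - self.input_dropout)).astype(x.dtype)
            xd = x * self._mask
        else:
            self._mask = None
            xd = x
        self._xd = xd
        zx = xd @ Wx + b  # (B, T, 4H)
        dt = zx.dtype
        i_s = np.empty((T, B, H), dt); f_s = np.empty((T, B, H), dt)
        g_s = np.empty((T, B, H), dt); o_s = np.empty((T, B, H), dt)
        c_s = np.empty((T, B, H), dt); hc_s = np.empty((T, B, H), dt)
        hprev_s = np.empty((T, B, H), dt); cprev_s = np.empty((T, B, H), dt)
        h = np.zeros((B, H), dt); c = np.zeros((B, H), dt)
        hs = np.empty((T, B, H), dt)
        for t in range(T):
            hprev_s[t] = h; cprev_s[t] = c
            z = zx[:, t, :] + h @ Uh
            i = _sigmoid(z[:, :H]); f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H]); o = _sigmoid(z[:, 3 * H :])
            c = i * g + f * c
            hc = np.tanh(c)
            h = o * hc
            i_s[t], f_s[t], g_s[t], o_s[t] = i, f, g, o
            c_s[t], hc_s[t], hs[t] = c, hc, h
        self._cache = (i_s, f_s, g_s, o_s, c_s, hc_s, hprev_s, cprev_s)
        if self.return_sequences:
            return hs.transpose(1, 0, 2)
        return hs[-1]

    def backward(self, dy):
        Wx, Uh, b = self.params
        i_s, f_s, g_s, o_s, c_s, hc_s, hprev_s, cprev_s = self._cache
        T, B, H = i_s.shape
        dt = i_s.dtype
        dZ = np.empty((T, B, 4 * H), dt)
        dh_next = np.zeros((B, H), dt); dc_next = np.zeros((B, H), dt)
        for t in range(T - 1, -1, -1):
            if self.return_sequences:
                dh = dy[:, t, :] + dh_next
            else:
                dh = (dy if t == T - 1 else 0.0) + dh_next
            i, f, g, o = i_s[t], f_s[t], g_s[t], o_s[t]
            hc = hc_s[t]
            do = dh * hc
            dc = dh * o * (1.0 - hc * hc) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * cprev_s[t]
            dc_next = dc * f
            dZ[t, :, :H] = di * i * (1.0 - i)
            dZ[t, :, H : 2 * H] = df * f * (1.0 - f)
            dZ[t, :, 2 * H : 3 * H] = dg * (1.0 - g * g)
            dZ[t, :, 3 * H :] = do * o * (1.0 - o)
            dh_next = dZ[t] @ Uh.T
        dZ_bt = dZ.transpose(1, 0, 2)  # (B, T, 4H)
        xd = self._xd
        self.grads[0][:] = xd.reshape(B * T, -1).T @ dZ_bt.reshape(B * T, -1)
        self.grads[1][:] = np.einsum("tbh,tbk->hk", hprev_s, dZ)
        self.grads[2][:] = dZ.sum(axis=(0, 1))
        dxd = dZ_bt @ Wx.T
        return dxd if self._mask is None else dxd * self._mask


class Softmax(Layer):
    def forward(self, x, training=False, rng=None):
        shifted = x - x.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        self._y = e / e.sum(axis=-1, keepdims=True)
        return self._y

    def backward(self, dy):
        y = self._y
        return y * (dy - (dy * y).sum(axis=-1, keepdims=True))


class Sequential:
    """A plain layer stack with shared forward/backward plumbing.

    All parameters share one dtype (default float64; training casts to
    float32 for speed).  Inputs are cast to that dtype on entry, so
    inference stays bit-reproducible for a given weight dtype.
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.dtype = np.dtype(np.float64)

    def initialize(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.initialize(rng)
        self.cast(self.dtype)

    def cast(self, dtype) -> None:
        self.dtype = np.dtype(dtype)
        for layer in self.layers:
            layer.params[:] = [p.astype(self.dtype) for p in layer.params]
            layer.grads[:] = [g.astype(self.dtype) for g in layer.grads]

    def forward(self, x, training: bool = False, rng: np.random.Generator | None = None):
        x = np.asarray(x, dtype=self.dtype)
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights) -> None:
        weights = list(weights)
        params = self.parameters()
        if len(weights) != len(params):
            raise ValidationError(
                f"expected {len(params)} weight arrays, got {len(weights)}"
            )
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValidationError(f"weight shape {w.shape} != parameter shape {p.shape}")
        # adopt the incoming dtype so saved weights reload bit-identically
        if weights and weights[0].dtype != self.dtype:
            self.cast(weights[0].dtype)
        for p, w in zip(self.parameters(), weights):
            p[:] = w


class CrossEntropyLoss:
    """Mean cross-entropy -sum(y log s) over a batch of probability rows.

    Predicted probabilities are clipped below at ``floor`` before the
    log, so a confidently wrong prediction costs -log(floor) rather than
    infinity.
    """

    def __init__(self, floor: float = 1e-7):
        self.floor = floor

    def forward(self, probs: np.ndarray, y_onehot: np.ndarray) -> float:
        if probs.shape != y_onehot.shape:
            raise ValidationError(f"shape mismatch {probs.shape} vs {y_onehot.shape}")
        self._probs, self._y = probs, y_onehot
        clipped = np.clip(probs, self.floor, 1.0)
        return float(-(y_onehot * np.log(clipped)).sum() / probs.shape[0])

    def backward(self) -> np.ndarray:
        clipped = np.clip(self._probs, self.floor, 1.0)
        inside = (self._probs >= self.floor) & (self._probs <= 1.0)
        return -(self._y / clipped) * inside / self._probs.shape[0]


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params: list[np.ndarray], learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
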