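"""Minimal NumPy neural-network engine for 1-D RF-segment models.

Implements exactly the pieces the segment classifiers need — 1-D "same"
convolution, ReLU, max pooling, nearest-neighbour upsampling with
deterministic pad-to-length, dropout, dense layers, an Elman recurrent
layer, softmax cross-entropy, and Adam — with hand-written backward passes.
Arrays are float32 throughout; activations are laid out (batch, time,
channels).

The engine is deliberately small: layers cache what their backward pass
needs, models wire layers explicitly (the U-net's skip connections do not
fit a Sequential abstraction), and gradients are verified against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(F32)


class Conv1D:
    """Kernel-3, stride-1, zero-padded ("same") 1-D convolution."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int = 3, name: str = "conv"):
        self.k = kernel
        self.c_in = c_in
        self.c_out = c_out
        self.W = Param(he_init(rng, (kernel * c_in, c_out), kernel * c_in), f"{name}.W")
        self.b = Param(np.zeros(c_out), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        n, t, _ = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # cols: (n, t, c_in, k) -> (n, t, k, c_in)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(n, t, self.k * self.c_in)
        self._cols = cols
        return cols @ self.W.value + self.b.value

    def backward(self, dy):
        n, t, _ = dy.shape
        cols = self._cols
        self.W.grad += cols.reshape(-1, self.k * self.c_in).T @ dy.reshape(-1, self.c_out)
        self.b.grad += dy.sum(axis=(0, 1))
        g = (dy @ self.W.value.T).reshape(n, t, self.k, self.c_in)
        p = self.k // 2
        dxp = np.zeros((n, t + 2 * p, self.c_in), dtype=F32)
        for j in range(self.k):
            dxp[:, j : j + t, :] += g[:, :, j, :]
        return dxp[:, p : p + t, :]


class ReLU:
    def params(self):
        return []

    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D:
    """Size-2 max pooling; an odd trailing sample is dropped."""

    def params(self):
        return []

    def forward(self, x, training=False):
        n, t, c = x.shape
        t2 = t // 2
        self._in_len = t
        pairs = x[:, : 2 * t2, :].reshape(n, t2, 2, c)
        self._argmax = pairs.argmax(axis=2)
        return pairs.max(axis=2)

    def backward(self, dy):
        n, t2, c = dy.shape
        dpairs = np.zeros((n, t2, 2, c), dtype=F32)
        np.put_along_axis(dpairs, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((n, self._in_len, c), dtype=F32)
        dx[:, : 2 * t2, :] = dpairs.reshape(n, 2 * t2, c)
        return dx


class Upsample1D:
    """Nearest-neighbour x2 upsampling, then zero-pad (or crop) to target_len.

    The pad/crop rule makes odd encoder lengths (15 -> 7 -> 14 -> pad 15)
    deterministic so skip concatenations always align.
    """

    def __init__(self, target_len: int):
        self.target_len = target_len

    def params(self):
        return []

    def forward(self, x, training=False):
        n, t, c = x.shape
        self._in_len = t
        y = np.repeat(x, 2, axis=1)
        if y.shape[1] < self.target_len:
            y = np.pad(y, ((0, 0), (0, self.target_len - y.shape[1]), (0, 0)))
        elif y.shape[1] > self.target_len:
            y = y[:, : self.target_len, :]
        return np.ascontiguousarray(y)

    def backward(self, dy):
        n, _, c = dy.shape
        full = np.zeros((n, 2 * self._in_len, c), dtype=F32)
        m = min(2 * self._in_len, self.target_len)
        full[:, :m, :] = dy[:, :m, :]
        return full.reshape(n, self._in_len, 2, c).sum(axis=2)


class Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def params(self):
        return []

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten:
    def params(self):
        return []

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense:
    def __init__(self, rng, n_in: int, n_out: int, name: str = "dense"):
        self.W = Param(he_init(rng, (n_in, n_out), n_in), f"{name}.W")
        self.b = Param(np.zeros(n_out), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ElmanRNN:
    """tanh recurrence h_t = tanh(x_t Wx + h_{t-1} Wh + b), returns sequence."""

    def __init__(self, rng, n_in: int, n_hidden: int, name: str = "rnn"):
        self.n_hidden = n_hidden
        scale = 1.0 / np.sqrt(n_hidden)
        self.Wx = Param(he_init(rng, (n_in, n_hidden), n_in), f"{name}.Wx")
        self.Wh = Param(rng.uniform(-scale, scale, (n_hidden, n_hidden)).astype(F32), f"{name}.Wh")
        self.b = Param(np.zeros(n_hidden), f"{name}.b")

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, training=False):
        n, t, _ = x.shape
        self._x = x
        h = np.zeros((n, t + 1, self.n_hidden), dtype=F32)
        for i in range(t):
            h[:, i + 1] = np.tanh(x[:, i] @ self.Wx.value + h[:, i] @ self.Wh.value + self.b.value)
        self._h = h
        return h[:, 1:]

    def backward(self, dy):
        x, h = self._x, self._h
        n, t, _ = dy.shape
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, self.n_hidden), dtype=F32)
        for i in range(t - 1, -1, -1):
            dh = dy[:, i] + dh_next
            dz = dh * (1.0 - h[:, i + 1] ** 2)
            self.Wx.grad += x[:, i].T @ dz
            self.Wh.grad += h[:, i].T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, i] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(labels)
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), labels] + eps))
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(F32)


class Adam:
    """Adam optimiser with bias-corrected first/second moments."""

    def __init__(self, params, lr=1e-5, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
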