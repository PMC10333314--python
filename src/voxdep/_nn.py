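"""Minimal feed-forward/recurrent network core on numpy.

Implements exactly the layers the depression-assessment networks need —
dense, ReLU, inverted dropout, full-width temporal convolution (im2col),
a standard LSTM with backpropagation through time — plus the Adam
optimizer.  Forward passes cache what backward needs; weights are float32.

Initialisation is uniform fan-in scaling U(-1/sqrt(fan_in), 1/sqrt(fan_in))
under a caller-supplied Generator, so a fixed seed reproduces training runs
bit-identically.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


def _init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(_init(rng, (n_in, n_out), n_in))
        self.b = Param(_init(rng, (n_out,), n_in))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = float(p)
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, T, F) -> (B, T-k+1, k*F) sliding patches along the time axis."""
    B, T, F = x.shape
    T_out = T - k + 1
    out = np.empty((B, T_out, k * F), dtype=x.dtype)
    for j in range(k):
        out[:, :, j * F:(j + 1) * F] = x[:, j:j + T_out, :]
    return out


class TemporalConv(Layer):
    """Valid 1-D convolution along time, stride 1, full feature width.

    Input (B, T, F) -> output (B, T-k+1, channels).  With F = L and a single
    input "channel" this is the (k, L) kernel of the first convolutional
    layer; with F = 50 it is the kernel-4 second layer over branch channels.
    """

    def __init__(self, kernel: int, n_features: int, channels: int,
                 rng: np.random.Generator):
        self.kernel = kernel
        self.n_features = n_features
        fan_in = kernel * n_features
        self.W = Param(_init(rng, (fan_in, channels), fan_in))
        self.b = Param(_init(rng, (channels,), fan_in))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        if x.shape[1] < self.kernel:
            raise ValueError(
                f"temporal length {x.shape[1]} shorter than kernel {self.kernel}"
            )
        self._cols = _im2col(x, self.kernel)          # (B, T_out, kF)
        self._in_shape = x.shape
        return self._cols @ self.W.value + self.b.value

    def backward(self, grad):
        B, T_out, _ = grad.shape
        cols2d = self._cols.reshape(B * T_out, -1)
        grad2d = grad.reshape(B * T_out, -1)
        self.W.grad += cols2d.T @ grad2d
        self.b.grad += grad2d.sum(axis=0)
        dcols = grad @ self.W.value.T                 # (B, T_out, kF)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        F = self.n_features
        for j in range(self.kernel):
            dx[:, j:j + T_out, :] += dcols[:, :, j * F:(j + 1) * F]
        return dx


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTMLayer(Layer):
    """Single LSTM layer returning the full hidden sequence (B, T, H)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.H = n_hidden
        fan_in = n_in + n_hidden
        self.W = Param(_init(rng, (fan_in, 4 * n_hidden), fan_in))
        self.b = Param(_init(rng, (4 * n_hidden,), fan_in))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        B, T, F = x.shape
        H = self.H
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        self._x = x
        self._cache = []
        out = np.empty((B, T, H), dtype=DTYPE)
        for t in range(T):
            xh = np.concatenate([x[:, t, :], h], axis=1)
            z = xh @ self.W.value + self.b.value
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            out[:, t, :] = h
            self._cache.append((xh, i, f, g, o, c_prev, tc))
        return out

    def backward(self, grad):
        B, T, H = grad.shape
        F = self._x.shape[2]
        dx = np.zeros_like(self._x)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        dc_next = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            xh, i, f, g, o, c_prev, tc = self._cache[t]
            dh = grad[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            self.W.grad += xh.T @ dz
            self.b.grad += dz.sum(axis=0)
            dxh = dz @ self.W.value.T
            dx[:, t, :] = dxh[:, :F]
            dh_next = dxh[:, F:]
            dc_next = dc * f
        return dx


class Adam:
    """Adam optimizer (default betas match the training recipe: 0.9, 0.99)."""

    def __init__(self, params: list[Param], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad * p.grad
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def nll_loss_grad(logits: np.ndarray, y: np.ndarray,
                  sample_weight: np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted negative log-likelihood over softmax logits.

    Returns (mean weighted loss, gradient wrt logits).
    """
    B = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    logp = np.log(np.clip(p[np.arange(B), y], 1e-12, None))
    loss = float(-(sample_weight * logp).mean())
    grad = p
    grad[np.arange(B), y] -= 1.0
    grad *= (sample_weight / B)[:, None]
    return loss, grad.astype(DTYPE)


def mse_loss_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over a single-output head."""
    diff = pred.astype(np.float64) - target
    loss = float((diff * diff).mean())
    grad = (2.0 / pred.shape[0]) * diff
    return loss, grad.astype(DTYPE)
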