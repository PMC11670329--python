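"""Minimal neural-network layers with explicit forward/backward passes.

Everything is plain numpy, float64, single device.  Each layer caches
what its backward pass needs during ``forward`` and consumes that cache
in ``backward`` (call order: forward, then backward, per step).  The
gradient of every layer is verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: trainable arrays live in ``params``/``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, *, train=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover
        raise NotImplementedError

    def zero_grads(self):
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Dense(Layer):
    """Affine map (N, D) -> (N, U), He-initialized for rectifier units."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / in_dim), (in_dim, units))
        self.params["b"] = np.zeros(units)
        self._x = None

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Conv1D(Layer):
    """1-D valid-padding convolution over (N, C_in, L) -> (N, C_out, L_out)."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 stride: int, rng: np.random.Generator):
        super().__init__()
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        fan_in = in_channels * kernel
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      (filters, in_channels, kernel))
        self.params["b"] = np.zeros(filters)
        self.kernel, self.stride = kernel, stride
        self._win = None
        self._in_shape = None

    def out_length(self, length: int) -> int:
        if length < self.kernel:
            raise ValueError(f"input length {length} shorter than kernel "
                             f"{self.kernel} (valid padding)")
        return (length - self.kernel) // self.stride + 1

    def forward(self, x, *, train=False, rng=None):
        n, c, length = x.shape
        t = self.out_length(length)
        k, s = self.kernel, self.stride
        sn, sc, sl = x.strides
        win = np.lib.stride_tricks.as_strided(
            x, shape=(n, c, t, k), strides=(sn, sc, sl * s, sl), writeable=False)
        self._win, self._in_shape = win, x.shape
        out = np.einsum("nctk,ock->not", win, self.params["W"], optimize=True)
        return out + self.params["b"][None, :, None]

    def backward(self, dout):
        k, s = self.kernel, self.stride
        t = dout.shape[2]
        self.grads["W"] = np.einsum("not,nctk->ock", dout, self._win,
                                    optimize=True)
        self.grads["b"] = dout.sum(axis=(0, 2))
        dx = np.zeros(self._in_shape)
        W = self.params["W"]
        for kk in range(k):
            contrib = np.einsum("not,oc->nct", dout, W[:, :, kk], optimize=True)
            dx[:, :, kk:kk + s * t:s] += contrib
        return dx


class LSTM(Layer):
    """Single LSTM layer over (N, T, D); returns the last hidden state."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(1.0 / (in_dim + units))
        self.params["Wx"] = rng.normal(0.0, scale, (in_dim, 4 * units))
        self.params["Wh"] = rng.normal(0.0, scale, (units, 4 * units))
        b = np.zeros(4 * units)
        b[units:2 * units] = 1.0  # forget-gate bias
        self.params["b"] = b
        self.units = units
        self._cache = None

    def forward(self, x, *, train=False, rng=None):
        n, T, d = x.shape
        H = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        steps = []
        for t in range(T):
            a = x[:, t, :] @ Wx + h @ Wh + b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            steps.append((i, f, g, o, c_prev, h_prev, c))
        self._cache = (x, steps)
        return h

    def backward(self, dh_last):
        x, steps = self._cache
        n, T, d = x.shape
        H = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh_next = dh_last
        dc_next = np.zeros((n, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, c = steps[t]
            tanh_c = np.tanh(c)
            dh = dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c ** 2) + dc_next
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            da = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dWx += x[:, t, :].T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, t, :] = da @ Wx.T
            dh_next = da @ Wh.T
            dc_next = dc * f
        self.grads["Wx"], self.grads["Wh"], self.grads["b"] = dWx, dWh, db
        return dx


class ReLU(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.3):
        super().__init__()
        self.slope = slope

    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam optimizer over a list of layers, with a shared lr schedule."""

    def __init__(self, layers: list[Layer], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.slots = [(layer, name) for layer in layers
                      for name in layer.params]
        self.m = [np.zeros_like(layer.params[name])
                  for layer, name in self.slots]
        self.v = [np.zeros_like(layer.params[name])
                  for layer, name in self.slots]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for idx, (layer, name) in enumerate(self.slots):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[idx] = b1 * self.m[idx] + (1 - b1) * g
            self.v[idx] = b2 * self.v[idx] + (1 - b2) * g * g
            mhat = self.m[idx] / (1 - b1 ** self.t)
            vhat = self.v[idx] / (1 - b2 ** self.t)
            layer.params[name] -= lr * mhat / (np.sqrt(vhat) + self.eps)
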