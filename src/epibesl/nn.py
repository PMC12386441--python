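"""Minimal neural-network building blocks in numpy.

Each layer exposes ``forward(x, training)`` and ``backward(dy)`` with
gradients accumulated in ``grads``; an :class:`Adam` optimizer updates the
collected parameters.  Inference-mode forward passes are deterministic
(dropout off, batch norm on running statistics).  The scope is deliberately
small: exactly the operations the EPI network needs, on (batch, length,
channels) sequence maps and (batch, features) vectors.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


class Layer:
    """Base layer: parameter/gradient dicts plus forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def glorot(rng: np.random.Generator, shape: tuple[int, ...],
           fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.params["W"] = glorot(rng, (n_in, n_out), n_in, n_out)
        if bias:
            self.params["b"] = np.zeros(n_out)
        self.bias = bias

    def forward(self, x, training=False):
        self._x = x
        y = x @ self.params["W"]
        if self.bias:
            y = y + self.params["b"]
        return y

    def backward(self, dy):
        x = self._x
        self.grads["W"] = x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
        if self.bias:
            self.grads["b"] = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.params["W"].T


class Conv1D(Layer):
    """1-D convolution over (batch, length, channels), valid padding, stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.c_in = c_in
        self.params["W"] = glorot(rng, (kernel * c_in, c_out),
                                  kernel * c_in, c_out)
        self.params["b"] = np.zeros(c_out)

    def _cols(self, x):
        b, length, c = x.shape
        n_out = length - self.kernel + 1
        if n_out <= 0:
            raise ValidationError(
                f"input length {length} below the kernel width {self.kernel}"
            )
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        # win: (b, n_out, c, kernel) -> (b, n_out, kernel*c)
        return win.transpose(0, 1, 3, 2).reshape(b, n_out, self.kernel * c)

    def forward(self, x, training=False):
        self._shape = x.shape
        self._cols_cache = self._cols(x)
        return self._cols_cache @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        b, n_out, c_out = dy.shape
        cols = self._cols_cache.reshape(-1, self.kernel * self.c_in)
        self.grads["W"] = cols.T @ dy.reshape(-1, c_out)
        self.grads["b"] = dy.reshape(-1, c_out).sum(axis=0)
        dcols = (dy @ self.params["W"].T).reshape(b, n_out, self.kernel, self.c_in)
        dx = np.zeros(self._shape)
        for j in range(self.kernel):
            dx[:, j:j + n_out, :] += dcols[:, :, j, :]
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValidationError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.zeros(channels)
        self.n_updates = 0
        self.momentum = momentum
        self.eps = eps

    def _running_stats(self) -> tuple[np.ndarray, np.ndarray]:
        if self.n_updates == 0:
            return np.zeros_like(self.running_mean), np.ones_like(self.running_var)
        # zero-debiased EMA: unbiased even after very few updates
        corr = 1.0 - self.momentum ** self.n_updates
        return self.running_mean / corr, self.running_var / corr

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
            self.n_updates += 1
        else:
            mean, var = self._running_stats()
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        axes = self._axes
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        if not self._training:
            return dy * self.params["gamma"] / self._std
        m = dy.size // dy.shape[-1]
        dxhat = dy * self.params["gamma"]
        return (dxhat - dxhat.mean(axis=axes)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std


class AvgPool1D(Layer):
    """Non-overlapping average pooling along axis 1; trailing remainder dropped."""

    def __init__(self, width: int):
        super().__init__()
        if width <= 0:
            raise ValidationError("pool width must be positive")
        self.width = width

    def forward(self, x, training=False):
        b, length, c = x.shape
        n_out = length // self.width
        if n_out == 0:
            raise ValidationError(
                f"input length {length} below the pool width {self.width}"
            )
        self._shape = x.shape
        return x[:, :n_out * self.width, :].reshape(
            b, n_out, self.width, c).mean(axis=2)

    def backward(self, dy):
        b, n_out, c = dy.shape
        dx = np.zeros(self._shape)
        dx[:, :n_out * self.width, :] = np.repeat(
            dy / self.width, self.width, axis=1)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, training=False):
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._length, axis=1) / self._length


class Tanh(Layer):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1 - self._y ** 2)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray,
                  floor: float = 1e-7) -> float:
    """Mean categorical cross-entropy; probabilities clipped at ``floor``."""
    p = np.clip(probs[np.arange(labels.size), labels], floor, 1.0)
    return float(-np.log(p).mean())


class Adam:
    """Adam over an ordered list of (layer, name) parameter handles."""

    def __init__(self, handles: list[tuple[Layer, str]], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.handles = handles
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[name]) for layer, name in handles]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in handles]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (layer, name) in enumerate(self.handles):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g ** 2
            mhat = self.m[i] / (1 - self.beta1 ** self.t)
            vhat = self.v[i] / (1 - self.beta2 ** self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
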