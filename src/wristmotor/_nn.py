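"""Minimal feed-forward network primitives on numpy.

Implements exactly what the motor-state classifier needs: valid-padding
strided 1-D convolution, batch normalization, ReLU, dense layers, softmax
cross-entropy against soft (probability-vector) targets, and Adam.  Forward
and backward passes are vectorized via im2col + matmul.  All randomness is
injected through a numpy Generator, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1d", "BatchNorm1d", "ReLU", "Flatten", "Dense",
           "Network", "Adam", "softmax", "soft_cross_entropy"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def soft_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy of softmax(logits) against probability targets.

    Returns (loss, dloss/dlogits); the gradient is (p - t) / N.
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-(targets * np.log(np.clip(p, 1e-12, None))).sum() / n)
    return loss, (p - targets) / n


class Conv1d:
    """Valid-padding strided 1-D convolution, (N, C_in, L) -> (N, C_out, L_out).

    No bias: every use here is followed by batch normalization, whose shift
    parameter absorbs it.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.c_in, self.c_out, self.k, self.s = c_in, c_out, kernel, stride
        fan_in = c_in * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in * kernel)).astype(np.float32)
        self.dW = np.zeros_like(self.W)
        self._cache = None

    @staticmethod
    def out_len(l_in: int, kernel: int, stride: int) -> int:
        return (l_in - kernel) // stride + 1

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, l = x.shape
        lo = self.out_len(l, self.k, self.s)
        win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=2)  # (N,C,L-k+1,k)
        patches = win[:, :, :: self.s][:, :, :lo]               # (N,C,Lo,k)
        patches = np.ascontiguousarray(patches.transpose(0, 2, 1, 3)).reshape(n * lo, c * self.k)
        y = (patches @ self.W.T).reshape(n, lo, self.c_out).transpose(0, 2, 1)
        if training:
            self._cache = (patches, x.shape)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        patches, x_shape = self._cache
        n, c, l = x_shape
        lo = dy.shape[2]
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(n * lo, self.c_out)
        self.dW[...] = dyf.T @ patches
        dpatch = (dyf @ self.W).reshape(n, lo, c, self.k).transpose(0, 2, 1, 3)
        dx = np.zeros(x_shape, dtype=dy.dtype)
        for j in range(self.k):
            dx[:, :, j: j + self.s * lo: self.s] += dpatch[:, :, :, j]
        return dx

    def parameters(self):
        return [(self.W, self.dW)]


class BatchNorm1d:
    """Per-channel batch normalization over the batch and temporal axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv[None, :, None]
        if training:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[2]
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2))
        self.dbeta[...] = dy.sum(axis=(0, 2))
        g = self.gamma[None, :, None] * inv[None, :, None]
        return g * (dy - self.dbeta[None, :, None] / m
                    - xhat * self.dgamma[None, :, None] / m)

    def parameters(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU:
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def parameters(self):
        return []


class Flatten:
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def parameters(self):
        return []


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x if training else None
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Network:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        return [pg for layer in self.layers for pg in layer.parameters()]

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p, _ in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for (p, _), s in zip(params, state[: len(params)]):
            p[...] = s
        rest = iter(state[len(params):])
        for layer in self.layers:
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[...] = next(rest)
                layer.running_var[...] = next(rest)


def refresh_batchnorm(net: "Network", x: np.ndarray, batch: int = 256) -> None:
    """Set every BatchNorm's running statistics to exact dataset statistics.

    Short trainings take too few optimizer steps for the exponential running
    average to converge, which skews inference-mode normalization; one exact
    pass over the training inputs removes that bias.  Layer by layer: compute
    the per-channel mean/variance of the current activations, write them into
    the layer, then push the activations through it in eval mode.
    """
    h = x
    for layer in net.layers:
        if isinstance(layer, BatchNorm1d):
            layer.running_mean[...] = h.mean(axis=(0, 2))
            layer.running_var[...] = h.var(axis=(0, 2))
        h = np.concatenate([layer.forward(h[i: i + batch], training=False)
                            for i in range(0, h.shape[0], batch)])


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
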