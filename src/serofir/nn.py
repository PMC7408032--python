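"""Minimal 1-D convolutional neural network in NumPy.

Implements exactly the ingredients the spectral classifier needs — 'same'
padded 1-D convolutions (im2col + matmul), ReLU, width-2 max pooling,
dense layers, inverted dropout, a fused softmax/cross-entropy head and
stochastic gradient descent with momentum and L2 weight decay.  Tensors are
``(batch, length, channels)``.  All randomness (init, dropout, batching)
flows through explicit ``numpy.random.Generator`` instances, so training is
reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: single precision keeps the matmul-bound training loop fast on one CPU
DTYPE = np.float32

__all__ = [
    "Conv1D", "ReLU", "MaxPool1D", "Flatten", "Dense", "Dropout",
    "Network", "softmax", "cross_entropy_grad", "SGDMomentum",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Layer:
    """Base layer: stateless unless it declares params/grads."""

    params: list
    grads: list

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """'Same'-padded 1-D convolution (cross-correlation), stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 == 0 or kernel_size < 1:
            raise ValueError("kernel_size must be odd and >= 1")
        self.k = kernel_size
        fan_in = kernel_size * in_channels
        self.W = (rng.standard_normal((kernel_size * in_channels, out_channels))
                  * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]
        self.in_channels = in_channels
        self.out_channels = out_channels
        #: weights participate in L2 decay, biases do not
        self.decay_mask = [True, False]

    def forward(self, x, train=False):
        h = (self.k - 1) // 2
        x = np.asarray(x, dtype=DTYPE)
        xp = np.pad(x, ((0, 0), (h, h), (0, 0)))
        cols = sliding_window_view(xp, self.k, axis=1)  # (B, L, C, k)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2))  # (B, L, k, C)
        B, L = cols.shape[:2]
        self._cols = cols.reshape(B, L, self.k * self.in_channels)
        self._in_len = x.shape[1]
        return self._cols @ self.W + self.b

    def backward(self, grad):
        B, L, _ = grad.shape
        flat_cols = self._cols.reshape(B * L, -1)
        flat_grad = grad.reshape(B * L, -1)
        self.dW[...] = flat_cols.T @ flat_grad
        self.db[...] = flat_grad.sum(axis=0)
        gcols = (grad @ self.W.T).reshape(B, L, self.k, self.in_channels)
        h = (self.k - 1) // 2
        gx = np.zeros((B, self._in_len + 2 * h, self.in_channels), dtype=DTYPE)
        for i in range(self.k):
            gx[:, i : i + L, :] += gcols[:, :, i, :]
        return gx[:, h : h + self._in_len, :]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, pool_size: int = 2):
        super().__init__()
        self.pool = pool_size

    def forward(self, x, train=False):
        B, L, C = x.shape
        L2 = L // self.pool
        if L2 == 0:
            raise ValueError("pooled length reached 0")
        xv = x[:, : L2 * self.pool, :].reshape(B, L2, self.pool, C)
        self._argmax = xv.argmax(axis=2)
        self._shape = x.shape
        return np.take_along_axis(xv, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad):
        B, L2, C = grad.shape
        gx = np.zeros(self._shape, dtype=grad.dtype)
        gv = gx[:, : L2 * self.pool, :].reshape(B, L2, self.pool, C)
        np.put_along_axis(gv, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        return gx


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)



class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.W = (rng.standard_normal((in_features, out_features))
                  * np.sqrt(2.0 / in_features)).astype(DTYPE)
        self.b = np.zeros(out_features, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]
        self.decay_mask = [True, False]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(DTYPE)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Network:
    """A plain sequential stack with parameter bookkeeping."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        """Yields (param, grad, decays) triples over all layers."""
        for layer in self.layers:
            masks = getattr(layer, "decay_mask", [False] * len(layer.params))
            yield from zip(layer.params, layer.grads, masks)

    def n_parameters(self) -> int:
        return sum(p.size for p, _, _ in self.parameters())

    def get_weights(self) -> list:
        return [p.copy() for p, _, _ in self.parameters()]

    def set_weights(self, weights: list) -> None:
        for (p, _, _), w in zip(self.parameters(), weights):
            p[...] = w


class SGDMomentum:
    """SGD with classical momentum and L2 weight decay on weight tensors."""

    def __init__(self, network: Network, learning_rate: float,
                 momentum: float = 0.9, l2: float = 0.0):
        if learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if not 0.0 <= momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if l2 < 0:
            raise ValueError("l2 must be >= 0")
        self.network = network
        self.lr = learning_rate
        self.momentum = momentum
        self.l2 = l2
        self.velocity = [np.zeros_like(p) for p, _, _ in network.parameters()]

    def step(self) -> None:
        for v, (p, g, decays) in zip(self.velocity, self.network.parameters()):
            grad = g + self.l2 * p if decays else g
            v *= self.momentum
            v -= self.lr * grad
            p += v
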