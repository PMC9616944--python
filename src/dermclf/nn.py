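"""Minimal NumPy neural-network layers, loss and optimizer.

A small, fully deterministic building-block set sufficient for the compact
lesion CNN: 3x3 same-padding convolution (im2col + BLAS matmul), spatial
and per-feature batch normalisation, ReLU, non-overlapping max pooling,
inverted dropout, flatten, dense, and a fused softmax / categorical
cross-entropy head trained with Adam.

Data layout is NCHW float32 throughout.  Each layer exposes
``forward(x, training)`` and ``backward(grad)`` plus ``params`` / ``grads``
dictionaries for the optimizer.  All randomness (weight init, dropout)
flows through generators derived from a single seed, so two runs with the
same seed produce identical weights.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: stateless by default."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_shape(self, in_shape: tuple) -> tuple:
        return in_shape


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, H*W) patch matrix for stride-1 same conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    d6 = dcols.reshape(n, c, k, k, h, w)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d6[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2D(Layer):
    """3x3 (or kxk) stride-1 convolution with same padding, He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.pad = k // 2
        fan_in = in_ch * k * k
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, fan_in)).astype(np.float32),
            "b": np.zeros(out_ch, dtype=np.float32),
        }

    def forward(self, x, training):
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k, self.pad)
        n, _, hw = self._cols.shape
        out = self.params["W"] @ self._cols + self.params["b"][:, None]
        h = w = int(np.sqrt(hw)) if x.shape[2] == x.shape[3] else 0
        return out.reshape(n, self.out_ch, x.shape[2], x.shape[3])

    def backward(self, grad):
        n, f, h, w = grad.shape
        g = grad.reshape(n, f, h * w)
        self.grads["W"] = np.einsum("nfp,ncp->fc", g, self._cols, optimize=True)
        self.grads["b"] = g.sum(axis=(0, 2))
        dcols = np.einsum("fc,nfp->ncp", self.params["W"], g, optimize=True)
        return _col2im(dcols, self._x_shape, self.k, self.pad)

    def output_shape(self, in_shape):
        _, h, w = in_shape
        return (self.out_ch, h, w)


class BatchNorm(Layer):
    """Batch normalisation over (N, H, W) per channel, or per feature for 2-D input."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(n_features, dtype=np.float32),
            "beta": np.zeros(n_features, dtype=np.float32),
        }
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)

    def _moments_axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _expand(self, v, ndim):
        return v if ndim == 2 else v[:, None, None]

    def forward(self, x, training):
        axes = self._moments_axes(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        e = lambda v: self._expand(v, x.ndim)
        self._std_inv = 1.0 / np.sqrt(var + self.eps)
        self._x_hat = (x - e(mean)) * e(self._std_inv)
        self._training_batch = x.shape[0] * (1 if x.ndim == 2 else x.shape[2] * x.shape[3])
        return e(self.params["gamma"]) * self._x_hat + e(self.params["beta"])

    def backward(self, grad):
        axes = self._moments_axes(grad)
        e = lambda v: self._expand(v, grad.ndim)
        m = self._training_batch
        self.grads["gamma"] = (grad * self._x_hat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        dxhat = grad * e(self.params["gamma"])
        return (
            e(self._std_inv)
            / m
            * (
                m * dxhat
                - e(dxhat.sum(axis=axes))
                - self._x_hat * e((dxhat * self._x_hat).sum(axis=axes))
            )
        )


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool(Layer):
    """Non-overlapping max pooling: pool size = stride."""

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x, training):
        p = self.pool
        n, c, h, w = x.shape
        if h % p or w % p:
            raise ValueError(f"spatial size {h}x{w} not divisible by pool {p}")
        ho, wo = h // p, w // p
        xr = x.reshape(n, c, ho, p, wo, p).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, p * p)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        p = self.pool
        n, c, h, w = self._in_shape
        ho, wo = h // p, w // p
        dxr = np.zeros((n, c, ho, wo, p * p), dtype=grad.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], grad[..., None], axis=-1)
        return dxr.reshape(n, c, ho, wo, p, p).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)

    def output_shape(self, in_shape):
        c, h, w = in_shape
        return (c, h // self.pool, w // self.pool)


class Dropout(Layer):
    """Inverted dropout: inference is the identity."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, grad):
        if not hasattr(self, "_mask"):
            return grad
        return grad * self._mask.astype(grad.dtype)


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)

    def output_shape(self, in_shape):
        return (int(np.prod(in_shape)),)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(np.float32),
            "b": np.zeros(n_out, dtype=np.float32),
        }
        self.n_out = n_out

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T

    def output_shape(self, in_shape):
        return (self.n_out,)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SoftmaxCrossEntropy:
    """Fused softmax + categorical cross-entropy −Σ y·log(p)."""

    def forward(self, logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
        probs = softmax(logits)
        loss = float(-np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1)))
        self._probs, self._onehot = probs, onehot
        return loss, probs

    def backward(self) -> np.ndarray:
        n = self._probs.shape[0]
        return ((self._probs - self._onehot) / n).astype(np.float32)


class Sequential:
    """Ordered layer stack with a softmax cross-entropy head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.loss_fn = SoftmaxCrossEntropy()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self):
        """Yield (layer, name) pairs for every trainable array."""
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def get_weights(self) -> list[np.ndarray]:
        return [layer.params[name].copy() for layer, name in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (layer, name), w in zip(self.parameters(), weights):
            layer.params[name] = w.astype(layer.params[name].dtype).copy()


class Adam:
    """Adam with externally scheduled learning rate (set ``lr`` per epoch)."""

    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, (layer, name) in enumerate(self.model.parameters()):
            g = layer.grads[name].astype(np.float32)
            key = (li, name)
            m = self._m.setdefault(key, np.zeros_like(g))
            v = self._v.setdefault(key, np.zeros_like(g))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            layer.params[name] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
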