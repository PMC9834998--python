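"""A compact, seeded neural-network engine for 1-D spectral models.

Implements exactly the pieces the CNN architectures need — 1-D convolution
(same padding, computed as shifted GEMMs), ReLU, max pooling, batch
normalisation, dense layers, inverted dropout, softmax cross-entropy and L1
losses, and SGD/Adam optimisers — with explicit forward/backward passes in
float32. Convolutional activations use a channel-last ``(batch, length,
channels)`` layout so every contraction maps onto a contiguous GEMM. All
randomness (initialisation, shuffling, dropout) flows from numpy
Generators, so a fixed seed gives a bit-identical training trajectory on a
single thread. Gradients with respect to the *input* are available for
saliency maps.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-5


class Layer:
    """Base layer: parameter-free unless it fills ``params``/``grads``."""

    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def init(self, rng: np.random.Generator) -> None:  # noqa: D401
        pass

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _uniform(rng, shape, fan_in):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv1d(Layer):
    """Same-padded 1-D convolution, stride 1, odd kernel; x is (B, L, C)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size

    def init(self, rng):
        fan_in = self.cin * self.k
        self.params = {
            "W": _uniform(rng, (self.cout, self.cin, self.k), fan_in),
            "b": _uniform(rng, (self.cout,), fan_in),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training):
        B, L, C = x.shape
        pad = self.k // 2
        xp = np.zeros((B, L + 2 * pad, C), dtype=x.dtype)
        xp[:, pad : pad + L, :] = x
        W = self.params["W"]
        y = np.tensordot(xp[:, 0:L, :], W[:, :, 0], axes=([2], [1]))
        for d in range(1, self.k):
            y += np.tensordot(xp[:, d : d + L, :], W[:, :, d], axes=([2], [1]))
        y += self.params["b"]
        self._cache = (xp, L)
        return y

    def backward(self, dy):
        xp, L = self._cache
        pad = self.k // 2
        W = self.params["W"]
        for d in range(self.k):
            self.grads["W"][:, :, d] = np.tensordot(
                dy, xp[:, d : d + L, :], axes=([0, 1], [0, 1])
            )
        self.grads["b"][...] = dy.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for d in range(self.k):
            dxp[:, d : d + L, :] += np.tensordot(dy, W[:, :, d], axes=([2], [0]))
        return dxp[:, pad : pad + L, :]


class ReLU(Layer):
    def __init__(self):
        super().__init__()

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class MaxPool1d(Layer):
    """Non-overlapping max pooling along length; odd tail dropped."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, training):
        B, L, C = x.shape
        L2 = L // self.size
        xr = x[:, : L2 * self.size, :].reshape(B, L2, self.size, C)
        self._idx = np.argmax(xr, axis=2)
        self._shape = (B, L, C)
        return np.take_along_axis(xr, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        B, L, C = self._shape
        L2 = dy.shape[1]
        dxr = np.zeros((B, L2, self.size, C), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C), dtype=dy.dtype)
        dx[:, : L2 * self.size, :] = dxr.reshape(B, L2 * self.size, C)
        return dx


class BatchNorm(Layer):
    """Batch normalisation with running statistics (momentum 0.1).

    Works on ``(B, L, C)`` conv activations (per-channel stats over batch
    and length) and ``(B, F)`` dense activations (per-feature stats).
    """

    def __init__(self, n_features: int, momentum: float = 0.1):
        super().__init__()
        self.nf = n_features
        self.momentum = momentum

    def init(self, rng):
        self.params = {
            "gamma": np.ones(self.nf, dtype=np.float32),
            "beta": np.zeros(self.nf, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(self.nf, dtype=np.float32)
        self.running_var = np.ones(self.nf, dtype=np.float32)

    def forward(self, x, training):
        axes = (0, 1) if x.ndim == 3 else (0,)
        self._training = training
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + EPS)).astype(np.float32)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, axes)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, inv, axes = self._cache
        g = self.params["gamma"]
        self.grads["gamma"][...] = (dy * xhat).sum(axis=axes)
        self.grads["beta"][...] = dy.sum(axis=axes)
        if not self._training:
            return dy * (g * inv)
        dxhat = dy * g
        term = (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).mean(axis=axes)
        )
        return term * inv


class Flatten(Layer):
    def __init__(self):
        super().__init__()

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int):
        super().__init__()
        self.fi, self.fo = in_features, out_features

    def init(self, rng):
        self.params = {
            "W": _uniform(rng, (self.fi, self.fo), self.fi),
            "b": _uniform(rng, (self.fo,), self.fi),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"][...] = self._x.T @ dy
        self.grads["b"][...] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float = 0.5):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Network:
    """A sequential stack with explicit forward/backward and input gradients.

    Spectral inputs enter as ``(batch, length)`` and are fed through the
    stack as ``(batch, length, 1)``.
    """

    def __init__(self, layers, input_length: int, n_outputs: int):
        self.layers = list(layers)
        self.input_length = input_length
        self.n_outputs = n_outputs
        self.initialized = False

    def init_params(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.init(rng)
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        self.initialized = True

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not self.initialized:
            raise RuntimeError("network parameters are not initialized")
        out = np.asarray(x, dtype=np.float32)
        if out.ndim == 2:
            out = out[:, :, None]
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        grad = dy.astype(np.float32, copy=False)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        out = []
        for layer in self.layers:
            for name in layer.params:
                out.append((layer.params[name], layer.grads[name]))
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))

    def input_gradient(self, X: np.ndarray, units=None, batch_size: int = 256) -> np.ndarray:
        """d(output unit)/d(input) per sample, in inference mode.

        ``units`` selects an output unit per sample (e.g. the true-class
        logit); ``None`` uses the single scalar output.
        """
        X = np.asarray(X, dtype=np.float32)
        n = X.shape[0]
        grads = np.empty((n, self.input_length), dtype=np.float32)
        for start in range(0, n, batch_size):
            xb = X[start : start + batch_size]
            out = self.forward(xb, training=False)
            dy = np.zeros_like(out)
            if units is None:
                if out.shape[1] != 1:
                    raise ValueError("units required for multi-output models")
                dy[:, 0] = 1.0
            else:
                ub = np.asarray(units[start : start + batch_size], dtype=int)
                dy[np.arange(len(ub)), ub] = 1.0
            grads[start : start + batch_size] = self.backward(dy)[:, :, 0]
        return grads


class SoftmaxCrossEntropy:
    """Mean softmax cross-entropy over integer class targets."""

    def forward(self, logits: np.ndarray, y_idx: np.ndarray):
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        p = ez / ez.sum(axis=1, keepdims=True)
        n = logits.shape[0]
        loss = float(-np.mean(np.log(p[np.arange(n), y_idx] + 1e-12)))
        self._p, self._y = p, y_idx
        return loss

    def backward(self) -> np.ndarray:
        n = self._p.shape[0]
        d = self._p.copy()
        d[np.arange(n), self._y] -= 1.0
        return d / n


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


class L1Loss:
    """Mean absolute error for a scalar-output regression network."""

    def forward(self, pred: np.ndarray, y: np.ndarray):
        r = pred.ravel() - y
        self._sign = np.sign(r).astype(np.float32)
        self._shape = pred.shape
        return float(np.mean(np.abs(r)))

    def backward(self) -> np.ndarray:
        return (self._sign / self._sign.size).reshape(self._shape)


class SGD:
    def __init__(self, params):
        self.params = params

    def step(self, lr: float):
        for p, g in self.params:
            p -= (lr * g).astype(p.dtype)


class Adam:
    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
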