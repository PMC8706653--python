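"""Minimal numpy neural-network engine.

No deep-learning framework ships with the target environment, so the
layers the fusion classifier needs — 1-D convolution, batch normalization,
ReLU, dropout, dense — are implemented here directly, together with the
Adam optimizer.  Everything is float32 and single-threaded-deterministic:
given the same seed the same parameters, batches and updates result.

Conventions: convolutional activations are ``[B, L, C]`` (batch, length,
channels); dense activations ``[B, F]``.  Each layer exposes
``forward(x, train)``, ``backward(grad)`` and ``params``/``grads`` lists
that the optimizer walks in order.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: stateless pass-through."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


def _uniform_fan_in(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    """Uniform fan-in initialization: U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    limit = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv1D(Layer):
    """Stride-1 1-D convolution with 'same' or 'valid' padding.

    Weight shape ``[k * C_in, C_out]``.  The forward pass is computed as k
    shifted GEMMs accumulated in place (cheaper than materializing an
    im2col matrix for the small kernels used here).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        padding: str = "same",
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError("kernel size must be a positive odd integer")
        if padding not in {"same", "valid"}:
            raise ValueError("padding must be 'same' or 'valid'")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        rng = rng or np.random.default_rng()
        fan_in = kernel_size * in_channels
        self.W = _uniform_fan_in(rng, fan_in, (fan_in, out_channels))
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._xpad: np.ndarray | None = None
        self._in_len: int = 0

    def out_len(self, in_len: int) -> int:
        return in_len if self.padding == "same" else in_len - self.kernel_size + 1

    def _taps(self) -> np.ndarray:
        # per-offset weight slabs: [k, C_in, C_out]
        k, C = self.kernel_size, self.in_channels
        return self.W.reshape(k, C, self.out_channels)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[2] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[2]}"
            )
        if self.padding == "valid" and x.shape[1] < self.kernel_size:
            raise ValueError("input shorter than kernel under valid padding")
        x = x.astype(DTYPE, copy=False)
        self._in_len = x.shape[1]
        k = self.kernel_size
        pad = k // 2 if self.padding == "same" else 0
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0))) if pad else x
        L_out = self.out_len(self._in_len)
        taps = self._taps()
        out = xp[:, 0:L_out, :] @ taps[0]
        for i in range(1, k):
            out += xp[:, i : i + L_out, :] @ taps[i]
        out += self.b
        self._xpad = xp if train else None
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._xpad is not None, "backward before forward(train=True)"
        B, L_out, _ = grad.shape
        k, C = self.kernel_size, self.in_channels
        grad = grad.astype(DTYPE, copy=False)
        g2d = grad.reshape(-1, self.out_channels)
        taps = self._taps()
        dW = self.grads[0].reshape(k, C, self.out_channels)
        dxp = np.zeros_like(self._xpad)
        for i in range(k):
            x_slab = self._xpad[:, i : i + L_out, :].reshape(-1, C)
            dW[i] = x_slab.T @ g2d
            dxp[:, i : i + L_out, :] += grad @ taps[i].T
        self.grads[1][...] = g2d.sum(axis=0)
        pad = k // 2 if self.padding == "same" else 0
        self._xpad = None
        return dxp[:, pad : pad + self._in_len, :] if pad else dxp


class BatchNorm(Layer):
    """Batch normalization over all non-channel axes.

    Works for both ``[B, L, C]`` conv activations (statistics over batch
    and length) and ``[B, F]`` dense activations.  Running statistics with
    momentum 0.1 are used in inference mode; eps guards zero variance.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(n_features, dtype=DTYPE)
        self.beta = np.zeros(n_features, dtype=DTYPE)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = x.astype(DTYPE, copy=False)
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std, axes)
        return self.gamma * xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv_std, axes = self._cache
        grad = grad.astype(DTYPE, copy=False)
        m = np.prod([grad.shape[a] for a in axes])
        self.grads[0][...] = (grad * xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        dxhat = grad * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).sum(axis=axes) / m
        ) * inv_std
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = x > 0
        self._mask = mask if train else None
        return np.where(mask, x, 0).astype(DTYPE, copy=False)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
        self._mask = mask
        return x * mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        out = grad * self._mask
        self._mask = None
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.W = _uniform_fan_in(rng, in_features, (in_features, out_features))
        self.b = np.zeros(out_features, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = x.astype(DTYPE, copy=False)
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad.astype(DTYPE, copy=False)
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        dx = grad @ self.W.T
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:  # type: ignore[override]
        return [p for l in self.layers for p in l.params]

    @params.setter
    def params(self, value) -> None:  # Layer.__init__ assigns []
        pass

    @property
    def grads(self) -> list[np.ndarray]:  # type: ignore[override]
        return [g for l in self.layers for g in l.grads]

    @grads.setter
    def grads(self, value) -> None:
        pass

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shift-stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, eps: float = 1e-12
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy against integer labels + logit gradient."""
    probs = softmax(logits.astype(np.float64))
    B = len(labels)
    loss = float(-np.log(np.maximum(probs[np.arange(B), labels], eps)).mean())
    grad = probs
    grad[np.arange(B), labels] -= 1.0
    return loss, (grad / B).astype(DTYPE)


try:  # fused elementwise update: one memory pass instead of ~8
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _adam_update(p, g, m, v, lr_t, b1, b2, eps):  # pragma: no cover
        for i in range(p.size):
            m[i] += (1.0 - b1) * (g[i] - m[i])
            v[i] += (1.0 - b2) * (g[i] * g[i] - v[i])
            p[i] -= lr_t * m[i] / (np.sqrt(v[i]) + eps)

except ImportError:  # pragma: no cover

    def _adam_update(p, g, m, v, lr_t, b1, b2, eps):
        m += (1.0 - b1) * (g - m)
        v += (1.0 - b2) * (g * g - v)
        p -= lr_t * m / (np.sqrt(v) + eps)


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.grads = grads
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            _adam_update(
                p.reshape(-1), g.reshape(-1), m.reshape(-1), v.reshape(-1),
                DTYPE(lr_t), DTYPE(b1), DTYPE(b2), DTYPE(self.eps),
            )
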