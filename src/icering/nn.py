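"""A small, self-contained convolutional-network engine on numpy.

Implements exactly the pieces the ice-ring classifier needs — 'same'-padded
3x3 convolutions, batch normalization, 2x2 max pooling, dense layers,
inverted dropout, a sigmoid/binary-cross-entropy head and the Adam
optimizer — with analytic backward passes throughout, so the classifier is
trainable and differentiable (for sensitivity maps) with no framework
dependency.  All randomness flows through explicit numpy Generators, and
every operation is deterministic for a fixed seed.

Layout convention: activations are NHWC, i.e. (batch, rows, cols, channels).
Convolutions use stride 1; spatial reduction happens only in pooling.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Dropout",
    "Network",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z)
    if not np.issubdtype(z.dtype, np.floating):
        z = z.astype(float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(
    z: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean weighted binary cross-entropy and its gradient w.r.t. logits.

    Stable form: BCE(z, y) = softplus(-z) + (1 - y) * z.
    """
    z = z.ravel()
    y = np.asarray(y, dtype=float).ravel()
    w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float).ravel()
    softplus = np.logaddexp(0.0, -z)
    loss = float(np.mean(w * (softplus + (1.0 - y) * z)))
    grad = (w * (sigmoid(z) - y) / z.size).astype(z.dtype, copy=False)
    return loss, grad


class Layer:
    """Base layer: trainable params/grads plus cached forward state."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> list[np.ndarray]:
        """Arrays beyond params needed to reproduce inference (e.g. BN stats)."""
        return []


class Conv2D(Layer):
    """3x3 (or kxk) stride-1 'same' convolution, He-initialized.

    The k*k spatial taps are applied as k^2 shifted GEMMs on contiguous
    patch copies, which profiles faster than one big im2col gather at these
    channel counts; the patches are cached for the weight gradient.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.k = k
        self.c_in = c_in
        scale = np.sqrt(2.0 / (k * k * c_in))
        w = rng.standard_normal((k, k, c_in, c_out)) * scale
        self.params = [w.astype(dtype), np.zeros(c_out, dtype=dtype)]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        w, b = self.params
        k, c_in = self.k, self.c_in
        p = k // 2
        n, h, wd, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp_shape = xp.shape
        self._patches = []
        y = np.empty((n * h * wd, w.shape[3]), dtype=x.dtype)
        y[...] = b
        for i in range(k):
            for j in range(k):
                patch = np.ascontiguousarray(xp[:, i : i + h, j : j + wd, :]).reshape(-1, c_in)
                self._patches.append(patch)
                y += patch @ w[i, j]
        return y.reshape(n, h, wd, w.shape[3])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        k = self.k
        n, h, wd, c_out = dy.shape
        p = k // 2
        dy_flat = dy.reshape(-1, c_out)
        dxp = np.zeros(self._xp_shape, dtype=dy.dtype)
        dw = self.grads[0]
        for idx in range(k * k):
            i, j = divmod(idx, k)
            patch = self._patches[idx]
            dw[i, j] = patch.T @ dy_flat
            dxp[:, i : i + h, j : j + wd, :] += (dy_flat @ w[i, j].T).reshape(n, h, wd, -1)
        self.grads[1][...] = dy_flat.sum(axis=0)
        self._patches = []
        return dxp[:, p : p + h, p : p + wd, :]


class BatchNorm(Layer):
    """Per-channel batch normalization with running inference statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.params = [np.ones(channels, dtype=dtype), np.zeros(channels, dtype=dtype)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        gamma, beta = self.params
        self._shape = x.shape
        flat = x.reshape(-1, x.shape[-1])
        if training:
            mu = flat.mean(axis=0)
            diff = flat - mu
            var = np.einsum("nc,nc->c", diff, diff) / flat.shape[0]
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(self.running_mean.dtype)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(self.running_var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
            diff = flat - mu
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        self._xhat = diff
        self._xhat *= self._inv_std
        self._training = training
        return (gamma * self._xhat + beta).reshape(x.shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        gamma, _ = self.params
        flat = dy.reshape(-1, dy.shape[-1])
        self.grads[0][...] = (flat * self._xhat).sum(axis=0)
        self.grads[1][...] = flat.sum(axis=0)
        if self._training:
            m = flat.shape[0]
            dx = (gamma * self._inv_std / m) * (
                m * flat
                - flat.sum(axis=0)
                - self._xhat * (flat * self._xhat).sum(axis=0)
            )
        else:
            dx = gamma * self._inv_std * flat
        return dx.reshape(self._shape).astype(dy.dtype)

    def state(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (input spatial dims must be even)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(n, h // 2, w // 2, c, 4)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dxr.reshape(n, h, w, c)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = [
            (rng.standard_normal((n_in, n_out)) * scale).astype(dtype),
            np.zeros(n_out, dtype=dtype),
        ]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        self.grads[0][...] = (self._x.T @ dy).astype(w.dtype)
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ w.T


class Dropout(Layer):
    """Inverted dropout; identity at inference.  Draws from the shared rng."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(x.dtype)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Network:
    """A plain layer stack ending in a single logit."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x.ravel()

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        dy = dlogit.reshape(-1, 1)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Sigmoid scores for a (N, H, W, C) batch, inference mode."""
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(sigmoid(self.forward(x[i : i + batch_size], training=False)))
        return np.concatenate(out) if out else np.empty(0)

    # -- weight snapshots (params + batch-norm running stats) ----------------
    def all_params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def all_grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        arrays = []
        for layer in self.layers:
            arrays.extend(p.copy() for p in layer.params)
            arrays.extend(s.copy() for s in layer.state())
        return arrays

    def set_weights(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for layer in self.layers:
            for p in layer.params:
                p[...] = next(it)
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()

    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params)


class Adam:
    """Adaptive-moment gradient descent with bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
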