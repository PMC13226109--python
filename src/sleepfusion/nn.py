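"""Minimal CPU neural-network core used by the fusion stager.

A small, explicit layer library (valid convolutions, batch norm, max
pooling, dense, dropout) with hand-written backward passes and an Adam
optimizer.  Everything is float64 numpy; gradients are verified against
central finite differences in the test suite.

Conventions: 1D activations are (N, C, L); 2D activations are (N, C, H, W);
dense activations are (N, D).  All modules expose ``forward(x, train)``,
``backward(dy)`` (which also accumulates parameter gradients) and
``params()``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Module", "Conv1d", "Conv2d", "BatchNorm", "ReLU", "Sigmoid",
    "MaxPool1d", "MaxPool2d", "GlobalAvgPool", "Dense", "Dropout",
    "Sequential", "Adam", "softmax", "weighted_cross_entropy",
    "default_dtype", "set_default_dtype",
]

#: Compute dtype for parameters and activations.  float32 is the training
#: default (memory-bandwidth bound workload); gradient-verification tests
#: switch to float64.
_DEFAULT_DTYPE = np.float32


def default_dtype() -> np.dtype:
    return _DEFAULT_DTYPE


def set_default_dtype(dtype) -> None:
    global _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype)


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=_DEFAULT_DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def params(self) -> list[Param]:
        return []

    def _cast(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=_DEFAULT_DTYPE)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # checkpoint support: arrays beyond params (e.g. batch-norm running stats)
    def state_extra(self) -> dict:
        return {}

    def load_extra(self, state: dict) -> None:
        pass


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Module):
    """Valid (unpadded) 1-D convolution with stride."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.stride = stride
        self.W = Param(_he_init(rng, (cout, cin, kernel), cin * kernel), "conv1d.W")
        self.b = Param(np.zeros(cout), "conv1d.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        # im2col: contiguous (N*Lout, C*k) patch matrix, then one BLAS matmul
        x = self._cast(x)
        xw = sliding_window_view(x, self.kernel, axis=2)[:, :, :: self.stride]
        N, C, Lout, k = xw.shape
        cols = np.ascontiguousarray(xw.transpose(0, 2, 1, 3)).reshape(N * Lout, C * k)
        self._cols = cols
        self._xshape = x.shape
        self._lout = Lout
        Wmat = self.W.value.reshape(self.W.value.shape[0], C * k)
        y = cols @ Wmat.T + self.b.value
        return y.reshape(N, Lout, -1).transpose(0, 2, 1)

    def backward(self, dy):
        N, C, L = self._xshape
        cout = dy.shape[1]
        Lout = self._lout
        dyr = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(N * Lout, cout)
        self.W.grad += (dyr.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += dyr.sum(axis=0)
        dcols = (dyr @ self.W.value.reshape(cout, -1)).reshape(N, Lout, C, self.kernel)
        dx = np.zeros((N, C, L), dtype=dy.dtype)
        for kk in range(self.kernel):
            stop = kk + self.stride * Lout
            dx[:, :, kk:stop: self.stride] += dcols[:, :, :, kk].transpose(0, 2, 1)
        return dx


class Conv2d(Module):
    """Valid (unpadded) square 2-D convolution, stride 1."""

    def __init__(self, cin: int, cout: int, kernel: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.W = Param(
            _he_init(rng, (cout, cin, kernel, kernel), cin * kernel * kernel),
            "conv2d.W",
        )
        self.b = Param(np.zeros(cout), "conv2d.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        x = self._cast(x)
        xw = sliding_window_view(x, (self.kernel, self.kernel), axis=(2, 3))
        N, C, Ho, Wo, _, _ = xw.shape
        ck = C * self.kernel * self.kernel
        cols = np.ascontiguousarray(xw.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, ck
        )
        self._cols = cols
        self._xshape = x.shape
        self._out_hw = (Ho, Wo)
        Wmat = self.W.value.reshape(self.W.value.shape[0], ck)
        y = cols @ Wmat.T + self.b.value
        return y.reshape(N, Ho, Wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dy):
        N, C, H, W = self._xshape
        Ho, Wo = self._out_hw
        cout = dy.shape[1]
        dyr = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, cout)
        self.W.grad += (dyr.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += dyr.sum(axis=0)
        dcols = (dyr @ self.W.value.reshape(cout, -1)).reshape(
            N, Ho, Wo, C, self.kernel, self.kernel
        )
        dx = np.zeros((N, C, H, W), dtype=dy.dtype)
        for i in range(self.kernel):
            for j in range(self.kernel):
                dx[:, :, i : i + Ho, j : j + Wo] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dx


class BatchNorm(Module):
    """Batch normalisation over all axes except channel axis 1.

    Works for (N, C), (N, C, L) and (N, C, H, W) activations.  Training
    uses batch statistics and updates exponential running estimates;
    evaluation uses the running estimates.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=_DEFAULT_DTYPE)
        self.running_var = np.ones(channels, dtype=_DEFAULT_DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return tuple(i for i in range(x.ndim) if i != 1)

    def _shape(self, x):
        return tuple(-1 if i == 1 else 1 for i in range(x.ndim))

    def forward(self, x, train=False):
        x = self._cast(x)
        axes = self._axes(x)
        shp = self._shape(x)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(shp)) * inv.reshape(shp)
        self._cache = (xhat, inv, axes, shp, train, x.size // x.shape[1])
        return self.gamma.value.reshape(shp) * xhat + self.beta.value.reshape(shp)

    def backward(self, dy):
        xhat, inv, axes, shp, train, m = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value.reshape(shp)
        if not train:
            return dy * g * inv.reshape(shp)
        dxhat = dy * g
        term1 = m * dxhat
        term2 = dxhat.sum(axis=axes).reshape(shp)
        term3 = xhat * (dxhat * xhat).sum(axis=axes).reshape(shp)
        return (inv.reshape(shp) / m) * (term1 - term2 - term3)

    def state_extra(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def load_extra(self, state):
        self.running_mean = np.asarray(state["running_mean"], dtype=_DEFAULT_DTYPE)
        self.running_var = np.asarray(state["running_var"], dtype=_DEFAULT_DTYPE)


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Module):
    def forward(self, x, train=False):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dy):
        return dy * self._out * (1.0 - self._out)


class MaxPool1d(Module):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, pool: int) -> None:
        self.pool = pool

    def forward(self, x, train=False):
        N, C, L = x.shape
        Lout = L // self.pool
        xr = x[:, :, : Lout * self.pool].reshape(N, C, Lout, self.pool)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy):
        N, C, L = self._shape
        Lout = dy.shape[2]
        dxr = np.zeros((N, C, Lout, self.pool), dtype=dy.dtype)
        n, c, l = np.ix_(np.arange(N), np.arange(C), np.arange(Lout))
        dxr[n, c, l, self._arg] = dy
        dx = np.zeros((N, C, L), dtype=dy.dtype)
        dx[:, :, : Lout * self.pool] = dxr.reshape(N, C, Lout * self.pool)
        return dx


class MaxPool2d(Module):
    """Non-overlapping 2x2-style max pooling on (N, C, H, W)."""

    def __init__(self, pool: int = 2) -> None:
        self.pool = pool

    def forward(self, x, train=False):
        p = self.pool
        N, C, H, W = x.shape
        Ho, Wo = H // p, W // p
        xr = x[:, :, : Ho * p, : Wo * p].reshape(N, C, Ho, p, Wo, p)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Ho, Wo, p * p)
        self._arg = xr.argmax(axis=4)
        self._shape = x.shape
        return xr.max(axis=4)

    def backward(self, dy):
        p = self.pool
        N, C, H, W = self._shape
        Ho, Wo = dy.shape[2], dy.shape[3]
        dxr = np.zeros((N, C, Ho, Wo, p * p), dtype=dy.dtype)
        n, c, h, w = np.ix_(np.arange(N), np.arange(C), np.arange(Ho), np.arange(Wo))
        dxr[n, c, h, w, self._arg] = dy
        dxr = dxr.reshape(N, C, Ho, Wo, p, p).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((N, C, H, W), dtype=dy.dtype)
        dx[:, :, : Ho * p, : Wo * p] = dxr.reshape(N, C, Ho * p, Wo * p)
        return dx


class GlobalAvgPool(Module):
    """Mean over all trailing spatial axes: (N, C, ...) -> (N, C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], x.shape[1], -1).mean(axis=2)

    def backward(self, dy):
        shape = self._shape
        m = int(np.prod(shape[2:]))
        dx = np.repeat(dy[:, :, None] / m, m, axis=2)
        return dx.reshape(shape)


class Dense(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.W = Param(_he_init(rng, (din, dout), din), "dense.W")
        self.b = Param(np.zeros(dout), "dense.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = self._cast(x)
        return self._x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None) -> None:
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        self.modules = list(modules)

    def params(self):
        return [p for m in self.modules for p in m.params()]

    def forward(self, x, train=False):
        for m in self.modules:
            x = m.forward(x, train=train)
        return x

    def backward(self, dy):
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy

    def state_extra(self):
        return {str(i): m.state_extra() for i, m in enumerate(self.modules)
                if m.state_extra()}

    def load_extra(self, state):
        for i, m in enumerate(self.modules):
            if str(i) in state:
                m.load_extra(state[str(i)])


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy, mean over the batch.

    loss = (1/N) sum_i w[y_i] * (-log p_i[y_i]); with unit weights this is
    exactly the plain mean cross-entropy.  Returns (loss, dloss/dlogits).
    """
    labels = np.asarray(labels, dtype=int)
    weights = np.asarray(weights, dtype=float)
    n = logits.shape[0]
    p = softmax(logits)
    w = weights[labels]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None))
    loss = float(np.mean(w * nll))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / n)[:, None]
    return loss, grad
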