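"""Minimal NumPy neural-network core: layers with explicit backward passes.

Everything operates on batched time series of shape ``(batch, time,
channels)``.  Layers are *functional*: ``forward`` returns ``(output,
cache)`` and ``backward(d_output, cache)`` returns ``d_input`` while
accumulating parameter gradients in place.  Because caches travel with the
call rather than living on the layer, the same layer object can be applied
several times in one forward pass — which is exactly what weight sharing
across decoder blocks needs.

Only the pieces required by the envelope decoders are implemented: 1-D
convolution (valid, with optional front/end input padding), a per-time-step
dense layer, layer normalization over the channel axis, LeakyReLU, explicit
zero padding, and the Adam optimizer.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv1d",
    "Dense",
    "LayerNorm",
    "LeakyReLU",
    "ZeroPadEnd",
    "Sequential",
    "Adam",
    "pearson_batch",
    "neg_pearson_loss",
    "glorot_uniform",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray):
        raise NotImplementedError

    def backward(self, dy: np.ndarray, cache):
        raise NotImplementedError


class Conv1d(Layer):
    """Valid 1-D convolution along time, with optional input zero-padding.

    ``pad_front``/``pad_end`` zeros are prepended/appended to the *input*
    before the valid convolution.  A strictly causal layer uses
    ``pad_front=kernel-1``; an anti-causal (forward-looking) layer uses
    ``pad_end=kernel-1``.  Weight shape is ``(kernel, c_in, c_out)``.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        pad_front: int = 0,
        pad_end: int = 0,
        bias: bool = True,
        dtype=np.float32,
        name: str = "conv",
    ):
        if kernel < 1:
            raise ValueError("kernel size must be >= 1")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.pad_front, self.pad_end = pad_front, pad_end
        self.w = Parameter(
            glorot_uniform(rng, (kernel, c_in, c_out), kernel * c_in, c_out, dtype),
            name=f"{name}.w",
        )
        self.b = Parameter(np.zeros(c_out, dtype=dtype), name=f"{name}.b") if bias else None

    def params(self) -> list[Parameter]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray):
        # im2col in a time-major layout: unfold the (zero-padded) input into
        # an (out_time * batch, kernel * channels) matrix once, then the
        # whole convolution is a single GEMM
        B, T_in, _ = x.shape
        K = self.kernel
        C = self.c_in
        T = T_in + self.pad_front + self.pad_end
        To = T - K + 1
        if To < 1:
            raise ValueError(f"input of {T} samples shorter than kernel {K}")
        xt = np.zeros((T, B, C), dtype=x.dtype)
        xt[self.pad_front : self.pad_front + T_in] = np.swapaxes(x, 0, 1)
        if To * B * K * C * xt.itemsize <= self._COLS_BYTES_LIMIT:
            win = np.lib.stride_tricks.sliding_window_view(xt, K, axis=0)  # (To, B, C, K)
            cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(To * B, K * C)
            yt = cols @ self.w.value.reshape(K * C, self.c_out)
            cache = (cols, None, (T, B))
        else:
            # large unfolds would dominate memory; fall back to one GEMM
            # per lag over contiguous time-major slices
            w = self.w.value
            yt = np.zeros((To * B, self.c_out), dtype=x.dtype)
            for j in range(K):
                yt += xt[j : j + To].reshape(To * B, C) @ w[j]
            cache = (None, xt, (T, B))
        if self.b is not None:
            yt += self.b.value
        y = np.ascontiguousarray(np.swapaxes(yt.reshape(To, B, self.c_out), 0, 1))
        return y, cache

    #: unfolded-input caches above this size use the per-lag path instead
    _COLS_BYTES_LIMIT = 96 * 1024 * 1024

    def backward(self, dy: np.ndarray, cache):
        cols, xt, (T, B) = cache
        K = self.kernel
        C = self.c_in
        To = T - K + 1
        dyt = np.ascontiguousarray(np.swapaxes(dy, 0, 1)).reshape(To * B, self.c_out)
        dxt = np.zeros((T, B, C), dtype=dy.dtype)
        if cols is not None:
            self.w.grad += (cols.T @ dyt).reshape(K, C, self.c_out)
            dcols = (dyt @ self.w.value.reshape(K * C, self.c_out).T).reshape(To, B, K, C)
            # lag-major and contiguous so each fold step is a fast block add
            dcols = np.ascontiguousarray(dcols.transpose(2, 0, 1, 3))
            for j in range(K):  # fold overlapping windows back
                dxt[j : j + To] += dcols[j]
        else:
            w = self.w.value
            dw = self.w.grad
            for j in range(K):
                xs = xt[j : j + To].reshape(To * B, C)
                dw[j] += xs.T @ dyt
                dxt[j : j + To] += (dyt @ w[j].T).reshape(To, B, C)
        if self.b is not None:
            self.b.grad += dyt.sum(axis=0)
        dxt = dxt[self.pad_front : T - self.pad_end or None]
        return np.ascontiguousarray(np.swapaxes(dxt, 0, 1))


class Dense(Layer):
    """Per-time-step linear map ``(B, T, c_in) -> (B, T, c_out)``."""

    def __init__(self, c_in, c_out, rng, bias=True, dtype=np.float32, name="dense"):
        self.c_in, self.c_out = c_in, c_out
        self.w = Parameter(glorot_uniform(rng, (c_in, c_out), c_in, c_out, dtype), name=f"{name}.w")
        self.b = Parameter(np.zeros(c_out, dtype=dtype), name=f"{name}.b") if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x):
        y = x @ self.w.value
        if self.b is not None:
            y += self.b.value
        return y, x

    def backward(self, dy, cache):
        x = cache
        self.w.grad += np.tensordot(x, dy, axes=([0, 1], [0, 1]))
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 1))
        return dy @ self.w.value.T


class LayerNorm(Layer):
    """Normalization over the channel axis, independently at each time step.

    This keeps the layer agnostic to sequence length.  ``eps`` follows the
    convention of the Keras family (1e-3).
    """

    def __init__(self, c, eps=1e-3, dtype=np.float32, name="ln"):
        self.c = c
        self.eps = eps
        self.gamma = Parameter(np.ones(c, dtype=dtype), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(c, dtype=dtype), name=f"{name}.beta")

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        y = xhat * self.gamma.value + self.beta.value
        return y, (xhat, inv)

    def backward(self, dy, cache):
        xhat, inv = cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma.value
        c = xhat.shape[-1]
        # standard layer-norm backward over the last axis
        dx = (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        ) * inv
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope=0.3):
        self.slope = slope

    def forward(self, x):
        mask = x >= 0
        y = np.where(mask, x, self.slope * x)
        return y, mask

    def backward(self, dy, cache):
        mask = cache
        return np.where(mask, dy, self.slope * dy)


class ZeroPadEnd(Layer):
    """Append ``n`` zero samples at the end of the time axis."""

    def __init__(self, n: int):
        self.n = n

    def forward(self, x):
        if self.n == 0:
            return x, None
        return np.pad(x, ((0, 0), (0, self.n), (0, 0))), None

    def backward(self, dy, cache):
        if self.n == 0:
            return dy
        return dy[:, : dy.shape[1] - self.n, :]


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x):
        caches = []
        for l in self.layers:
            x, c = l.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, dy, caches):
        for l, c in zip(reversed(self.layers), reversed(caches)):
            dy = l.backward(dy, c)
        return dy


class Adam:
    """Adam optimizer over a list of (possibly shared) parameters."""

    def __init__(self, params: Sequence[Parameter], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        # deduplicate shared parameters so each is updated exactly once
        seen: dict[int, Parameter] = {}
        for p in params:
            seen.setdefault(id(p), p)
        self.params = list(seen.values())
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.value -= (self.lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)


def pearson_batch(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Pearson correlation per row of two ``(B, T)`` arrays.

    Rows where either input has zero variance yield NaN.
    """
    p = pred - pred.mean(axis=-1, keepdims=True)
    t = target - target.mean(axis=-1, keepdims=True)
    np_ = np.sqrt((p * p).sum(axis=-1))
    nt = np.sqrt((t * t).sum(axis=-1))
    denom = np_ * nt
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (p * t).sum(axis=-1) / denom, np.nan)
    return r


def neg_pearson_loss(pred: np.ndarray, target: np.ndarray, grad: bool = True):
    """Mean negative Pearson correlation over a batch of windows.

    Returns ``(loss, d_loss/d_pred)``; the gradient is ``None`` when
    ``grad=False``.  Raises on zero-variance windows (the correlation is
    undefined there).
    """
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape or pred.ndim != 2 or pred.shape[1] < 2:
        raise ValueError(f"need matching (B, T>=2) arrays, got {pred.shape} vs {target.shape}")
    B = pred.shape[0]
    p = pred - pred.mean(axis=-1, keepdims=True)
    t = target - target.mean(axis=-1, keepdims=True)
    npn = np.sqrt((p * p).sum(axis=-1, keepdims=True))
    ntn = np.sqrt((t * t).sum(axis=-1, keepdims=True))
    if np.any(npn == 0) or np.any(ntn == 0):
        raise ValueError("zero-variance window: Pearson correlation undefined")
    r = (p * t).sum(axis=-1, keepdims=True) / (npn * ntn)
    loss = float(-r.mean())
    if not grad:
        return loss, None
    # d(-r_b)/d pred = -(t/(|p||t|) - r * p/|p|^2); mean over batch
    dp = -(t / (npn * ntn) - r * p / (npn * npn)) / B
    return loss, dp.astype(pred.dtype)
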