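"""Minimal NumPy neural-network layers for span-aware 1-D convolution.

The layers operate on batches of feature maps, shape (B, C, L), together with
per-sample spans (start, n) marking the occupied region.  Two convolution
flavours are provided:

* ordinary "same" convolution with zero padding over the full length L;
* circular convolution whose receptive field wraps around *within the
  occupied span only* — position j inside the span reads input positions
  start + ((j - start + d) mod n); positions outside the span stay zero.

Every layer implements ``forward`` and ``backward``; ``backward`` both
accumulates parameter gradients and returns the gradient with respect to the
layer input, so input saliency falls out of the same machinery as training.
All randomness is injected through a ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1dSame",
    "BatchNorm",
    "ReLU",
    "SpanMaxPool",
    "SpanAvgPool",
    "Dense",
    "Network",
    "Adam",
]


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, spans: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _span_gather_plan(start: int, n: int, L: int, k: int, cyclic: bool):
    """Index/mask tables for one (start, n) span.

    Returns (idx, tap_mask, out_mask): idx is (L, k) input positions, tap_mask
    (L, k) marks valid taps, out_mask (L,) marks valid output positions.
    """
    half = k // 2
    idx = np.zeros((L, k), dtype=np.intp)
    tap = np.zeros((L, k))
    out = np.zeros(L)
    if cyclic:
        for j in range(start, start + n):
            out[j] = 1.0
            for d in range(k):
                idx[j, d] = start + ((j - start + d - half) % n)
                tap[j, d] = 1.0
    else:
        for j in range(L):
            out[j] = 1.0
            for d in range(k):
                p = j + d - half
                if 0 <= p < L:
                    idx[j, d] = p
                    tap[j, d] = 1.0
    return idx, tap, out


class Conv1dSame(Layer):
    """1-D convolution preserving length, ordinary (zero-padded) or cyclic."""

    def __init__(self, c_in: int, c_out: int, k: int, cyclic: bool, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k, self.cyclic = c_in, c_out, k, cyclic
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, k))
        self.b = np.zeros(c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._plan_cache: dict[tuple[int, int], tuple] = {}

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def _plans(self, spans: np.ndarray, L: int):
        idx = np.empty((len(spans), L, self.k), dtype=np.intp)
        tap = np.empty((len(spans), L, self.k))
        out = np.empty((len(spans), L))
        for i, (s, n) in enumerate(spans):
            key = (int(s), int(n))
            if self.cyclic and self.k > n:
                raise ValueError(f"kernel larger than ring: k={self.k} > n={n}")
            if key not in self._plan_cache:
                self._plan_cache[key] = _span_gather_plan(
                    int(s), int(n), L, self.k, self.cyclic
                )
            idx[i], tap[i], out[i] = self._plan_cache[key]
        return idx, tap, out

    def forward(self, x, spans, train):
        B, C, L = x.shape
        idx, tap, out = self._plans(spans, L)
        flat = idx.reshape(B, -1)  # (B, L*k)
        xg = np.take_along_axis(x, flat[:, None, :], axis=2).reshape(B, C, L, self.k)
        xg = xg * tap[:, None, :, :]
        y = np.einsum("bclk,ock->bol", xg, self.W, optimize=True)
        y += self.b[None, :, None]
        y *= out[:, None, :]
        self._cache = (x.shape, xg, flat, tap, out)
        return y

    def backward(self, gout):
        (B, C, L), xg, flat, tap, out = self._cache
        g = gout * out[:, None, :]
        self.gW += np.einsum("bclk,bol->ock", xg, g, optimize=True)
        self.gb += g.sum(axis=(0, 2))
        gxg = np.einsum("ock,bol->bclk", self.W, g, optimize=True)
        gxg *= tap[:, None, :, :]
        gx = np.zeros((B, C, L))
        bi = np.arange(B)[:, None, None]
        ci = np.arange(C)[None, :, None]
        np.add.at(gx, (bi, ci, flat[:, None, :]), gxg.reshape(B, C, -1))
        return gx


class BatchNorm(Layer):
    """Batch normalization over (B, C, L) per channel or (B, F) per feature."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(num_features)
        self.beta = np.zeros(num_features)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2)

    def _shape(self, x):
        return (1, -1) if x.ndim == 2 else (1, -1, 1)

    def forward(self, x, spans, train):
        axes, shp = self._axes(x), self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv.reshape(shp)
        self._cache = (xhat, inv, axes, shp, train, x.shape)
        return self.gamma.reshape(shp) * xhat + self.beta.reshape(shp)

    def backward(self, gout):
        xhat, inv, axes, shp, train, shape = self._cache
        self.ggamma += (gout * xhat).sum(axis=axes)
        self.gbeta += gout.sum(axis=axes)
        gxhat = gout * self.gamma.reshape(shp)
        if not train:
            return gxhat * inv.reshape(shp)
        m = np.prod([shape[a] for a in axes])
        term = (
            gxhat
            - gxhat.mean(axis=axes).reshape(shp)
            - xhat * (gxhat * xhat).mean(axis=axes).reshape(shp)
        )
        return term * inv.reshape(shp)


class ReLU(Layer):
    def forward(self, x, spans, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class SpanMaxPool(Layer):
    """Global max pooling over the occupied span: (B, C, L) -> (B, C)."""

    def forward(self, x, spans, train):
        B, C, L = x.shape
        cols = np.arange(L)[None, None, :]
        valid = (cols >= spans[:, 0, None, None]) & (
            cols < (spans[:, 0] + spans[:, 1])[:, None, None]
        )
        masked = np.where(valid, x, -np.inf)
        self._argmax = masked.argmax(axis=2)
        self._shape = x.shape
        return np.take_along_axis(masked, self._argmax[:, :, None], axis=2)[:, :, 0]

    def backward(self, gout):
        B, C, L = self._shape
        gx = np.zeros((B, C, L))
        bi = np.arange(B)[:, None]
        ci = np.arange(C)[None, :]
        np.add.at(gx, (bi, ci, self._argmax), gout)
        return gx


class SpanAvgPool(Layer):
    """Global average pooling over the occupied span: (B, C, L) -> (B, C)."""

    def forward(self, x, spans, train):
        B, C, L = x.shape
        cols = np.arange(L)[None, None, :]
        valid = (cols >= spans[:, 0, None, None]) & (
            cols < (spans[:, 0] + spans[:, 1])[:, None, None]
        )
        self._valid = valid
        self._counts = spans[:, 1].astype(float)
        return (x * valid).sum(axis=2) / self._counts[:, None]

    def backward(self, gout):
        return self._valid * (gout / self._counts[:, None])[:, :, None]


class Dense(Layer):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / f_in)
        self.W = rng.normal(0.0, scale, size=(f_in, f_out))
        self.b = np.zeros(f_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, spans, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, gout):
        self.gW += self._x.T @ gout
        self.gb += gout.sum(axis=0)
        return gout @ self.W.T


class Network:
    """A sequential stack with explicit forward/backward passes."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads()]

    def zero_grad(self) -> None:
        for g in self.gradients():
            g[...] = 0.0

    def forward(self, x: np.ndarray, spans: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, spans, train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.parameters()]
        for l in self.layers:
            if isinstance(l, BatchNorm):
                state.append(l.running_mean.copy())
                state.append(l.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state[: len(params)]):
            p[...] = s
        rest = state[len(params) :]
        i = 0
        for l in self.layers:
            if isinstance(l, BatchNorm):
                l.running_mean[...] = rest[i]
                l.running_var[...] = rest[i + 1]
                i += 2


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def cyclic_conv1d(values: np.ndarray, span: tuple[int, int], kernel: np.ndarray,
                  bias: np.ndarray | None = None) -> np.ndarray:
    """Single-map circular convolution: (C_in, L) values with span (start, n)
    under a (C_out, C_in, k) kernel -> (C_out, L), zeros outside the span."""
    start, n = span
    c_out, c_in, k = kernel.shape
    if k > n:
        raise ValueError(f"kernel larger than ring: k={k} > n={n}")
    rng = np.random.default_rng(0)  # unused; Conv1dSame requires a generator
    conv = Conv1dSame(c_in, c_out, k, cyclic=True, rng=rng)
    conv.W[...] = kernel
    conv.b[...] = 0.0 if bias is None else bias
    spans = np.array([[start, n]], dtype=np.intp)
    return conv.forward(values[None], spans, train=False)[0]
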