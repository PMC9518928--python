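"""Minimal seeded feed-forward networks with manual backpropagation.

All model components of the pipeline — the shape VAE, the local-to-global map
Phi, the patch regressors, and the reference-landmark detector — are small
fully-connected or convolutional stacks.  This module implements them
directly on numpy with hand-derived gradients and an Adam optimizer, which
keeps training single-threaded, dependency-free, and bit-reproducible for a
fixed seed (the reproducibility contract the rest of the package relies on).

Layers operate on float64 batches shaped (N, features) for dense layers and
(N, C, *spatial) for convolutions.  Convolutions are stride-1 with "same"
zero padding; spatial downsampling is by 2x average pooling, so input edges
must be divisible by 2**n_blocks.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization, appropriate for the ReLU stacks used throughout
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gy):
        self.W.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value.T


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Conv(Layer):
    """Stride-1 "same" convolution for 2D or 3D inputs (N, C, *spatial)."""

    def __init__(self, n_dim: int, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.n_dim = n_dim
        self.k = k
        #: set on the first layer of a stack: no layer below consumes the
        #: input gradient, and for convolutions it is the costliest part
        self.skip_input_grad = False
        fan_in = c_in * k ** n_dim
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(c_out, c_in) + (k,) * n_dim))
        self.b = Param(np.zeros(c_out))
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def _pad(self, x, p):
        pad = [(0, 0), (0, 0)] + [(p, p)] * self.n_dim
        return np.pad(x, pad)

    def _im2col(self, x):
        """(N, C, *sp_pad) -> column matrix (N * prod(sp_out), C * k^nd).

        Rows follow (sample, spatial) order, columns (channel, kernel) order,
        so the convolution becomes one GEMM against the flattened kernel.
        """
        win = np.lib.stride_tricks.sliding_window_view(
            x, (self.k,) * self.n_dim, axis=tuple(range(2, 2 + self.n_dim)))
        order = (0,) + tuple(range(2, 2 + self.n_dim)) + (1,) \
            + tuple(range(2 + self.n_dim, 2 + 2 * self.n_dim))
        win = win.transpose(order)
        sp_out = win.shape[1:1 + self.n_dim]
        return win.reshape(x.shape[0] * int(np.prod(sp_out)), -1), sp_out

    def forward(self, x):
        p = self.k // 2
        xp = self._pad(x, p)
        c_out = self.W.value.shape[0]
        col, sp_out = self._im2col(xp)
        self._col, self._sp_out, self._n = col, sp_out, x.shape[0]
        y = col @ self.W.value.reshape(c_out, -1).T + self.b.value
        y = y.reshape((x.shape[0],) + sp_out + (c_out,))
        return np.moveaxis(y, -1, 1)

    def backward(self, gy):
        c_out = self.W.value.shape[0]
        gy_flat = np.moveaxis(gy, 1, -1).reshape(-1, c_out)
        self.W.grad += (gy_flat.T @ self._col).reshape(self.W.value.shape)
        self.b.grad += gy_flat.sum(axis=0)
        if self.skip_input_grad:
            return None
        # input gradient = "full" convolution of gy with the flipped kernel,
        # also expressed as an im2col GEMM
        k, p = self.k, self.k // 2
        gyp = self._pad(gy, k - 1)
        gcol, sp = self._im2col(gyp)
        flip = self.W.value[(slice(None), slice(None))
                            + (slice(None, None, -1),) * self.n_dim]
        c_in = flip.shape[1]
        # (c_out, c_in, *k) -> (c_in, c_out * k^nd) matching gcol's layout
        fmat = np.moveaxis(flip, 1, 0).reshape(c_in, -1)
        gxp = gcol @ fmat.T
        gxp = np.moveaxis(gxp.reshape((gy.shape[0],) + sp + (c_in,)), -1, 1)
        sl = (slice(None), slice(None)) + tuple(
            slice(p, gxp.shape[2 + d] - p) for d in range(self.n_dim))
        return np.ascontiguousarray(gxp[sl])


class AvgPool(Layer):
    """2x average pooling over every spatial axis."""

    def __init__(self, n_dim: int):
        self.n_dim = n_dim
        self._in_shape = None

    def forward(self, x):
        self._in_shape = x.shape
        n, c = x.shape[:2]
        sp = x.shape[2:]
        if any(s % 2 for s in sp):
            raise ValueError(f"spatial dims {sp} not divisible by 2")
        shape = (n, c) + sum(((s // 2, 2) for s in sp), ())
        axes = tuple(3 + 2 * i for i in range(self.n_dim))
        return x.reshape(shape).mean(axis=axes)

    def backward(self, gy):
        g = gy / (2 ** self.n_dim)
        for ax in range(2, 2 + self.n_dim):
            g = np.repeat(g, 2, axis=ax)
        return g


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out: list[Param] = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy


def mlp(widths: list[int], rng: np.random.Generator,
        final_activation: bool = False) -> Sequential:
    """Fully-connected ReLU stack; the last Dense is linear unless requested."""
    layers: list[Layer] = []
    for i in range(len(widths) - 1):
        layers.append(Dense(widths[i], widths[i + 1], rng))
        if i < len(widths) - 2 or final_activation:
            layers.append(ReLU())
    return Sequential(layers)


def conv_regressor(n_dim: int, in_edge: int, in_channels: int, out_dim: int,
                   channels: list[int], fc_width: int,
                   rng: np.random.Generator, k: int = 3,
                   dtype=np.float32) -> Sequential:
    """Small VGG-flavored conv stack: [Conv-ReLU-Pool2]*B -> Dense -> Dense.

    ``in_edge`` must be divisible by 2**len(channels).  Convolutional stacks
    default to float32: single precision is ample for patch regression and
    roughly halves the memory traffic that dominates their runtime.
    """
    n_blocks = len(channels)
    if in_edge % (2 ** n_blocks):
        raise ValueError(f"edge {in_edge} not divisible by 2^{n_blocks}")
    layers: list[Layer] = []
    c_prev = in_channels
    for c in channels:
        layers += [Conv(n_dim, c_prev, c, k, rng), ReLU(), AvgPool(n_dim)]
        c_prev = c
    layers[0].skip_input_grad = True
    final_edge = in_edge // 2 ** n_blocks
    flat = c_prev * final_edge ** n_dim
    layers += [Flatten(), Dense(flat, fc_width, rng), ReLU(),
               Dense(fc_width, out_dim, rng)]
    net = Sequential(layers)
    if dtype is not None:
        for p in net.params():
            p.value = p.value.astype(dtype)
            p.grad = p.grad.astype(dtype)
    return net


def net_dtype(net: Sequential):
    return net.params()[0].value.dtype


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999), full-batch by convention."""

    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_regressor(net: Sequential, x: np.ndarray, y: np.ndarray,
                    epochs: int, lr: float) -> list[float]:
    """Full-batch squared-error training; returns the per-epoch loss curve."""
    dt = net_dtype(net)
    x = np.asarray(x, dtype=dt)
    y = np.asarray(y, dtype=dt)
    opt = Adam(net.params(), lr=lr)
    losses = []
    n = x.shape[0]
    for _ in range(epochs):
        opt.zero_grad()
        pred = net.forward(x)
        resid = pred - y
        loss = float(np.sum(resid ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at epoch {len(losses)}")
        net.backward(2.0 * resid)
        opt.step()
        losses.append(loss / n)
    return losses


def get_weights(net: Sequential) -> list[np.ndarray]:
    return [p.value.copy() for p in net.params()]


def set_weights(net: Sequential, weights: list[np.ndarray]) -> None:
    ps = net.params()
    if len(ps) != len(weights):
        raise ValueError("weight list does not match network parameters")
    for p, w in zip(ps, weights):
        if p.value.shape != w.shape:
            raise ValueError(f"weight shape {w.shape} != {p.value.shape}")
        p.value = np.asarray(w, dtype=p.value.dtype).copy()
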