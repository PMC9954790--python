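"""Minimal channels-last neural-network layers on numpy.

All layers operate on float32 batches shaped ``(n, *spatial, features)``
with one or two spatial axes.  Convolutions are evaluated as im2col +
BLAS matmul; every layer implements an exact analytic backward pass
(verified against central finite differences in the test suite).

Conventions
-----------
* "same" zero padding: for kernel extent ``k`` the leading pad is
  ``(k - 1) // 2`` and the trailing pad ``k // 2``, so output extent equals
  input extent at stride 1.
* Batch normalisation acts per feature (last axis), reducing over batch
  and spatial axes, with running-statistics update
  ``running <- (1 - momentum) * running + momentum * batch`` and biased
  variance throughout.
* Average pooling halves the *leading* spatial axis (floor, trailing odd
  element dropped) and is skipped when that axis has extent 1.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv",
    "SeparableConv",
    "BatchNorm",
    "Elu",
    "AvgPoolHalf",
    "Dropout",
    "Flatten",
    "Dense",
    "Softmax",
    "elu",
    "glorot_uniform",
]


def elu(z, alpha: float = 1.0):
    """Exponential linear unit: ``z`` for ``z > 0``, ``alpha*(e^z - 1)`` else.

    Continuous at 0 and bounded below by ``-alpha``.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0; got {alpha}")
    z = np.asarray(z)
    return np.where(z > 0, z, alpha * np.expm1(np.minimum(z, 0.0))).astype(
        z.dtype if np.issubdtype(z.dtype, np.floating) else np.float64
    )


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _same_pads(kernel: tuple[int, ...]) -> list[tuple[int, int]]:
    return [((k - 1) // 2, k // 2) for k in kernel]


class Layer:
    """Base class: trainable ``params`` with matching ``grads``."""

    name: str = "layer"

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def describe(self) -> dict:
        return {"kind": self.name, "params": self.n_params}


class Conv(Layer):
    """Plain convolution over 1 or 2 spatial axes, stride 1, "same" padding.

    Weights are stored as ``(prod(kernel) * in_channels, filters)`` with
    kernel-offset-major rows.  Kernels with a singleton extent — the only
    kind the default architecture uses — are evaluated as a shift-and-sum
    of batched matmuls along the non-trivial axis, which avoids
    materialising the im2col matrix entirely; genuinely two-dimensional
    kernels fall back to an explicit im2col + GEMM.
    """

    name = "conv"

    def __init__(
        self,
        kernel: tuple[int, ...],
        in_channels: int,
        filters: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.kernel = tuple(int(k) for k in kernel)
        if len(self.kernel) not in (1, 2):
            raise ValueError("kernel must have 1 or 2 extents")
        self.in_channels = int(in_channels)
        self.filters = int(filters)
        ksize = int(np.prod(self.kernel))
        fan_in = ksize * in_channels
        self.W = glorot_uniform(rng, fan_in, filters, (ksize * in_channels, filters), dtype)
        self.b = np.zeros(filters, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._xp: np.ndarray | None = None

    def describe(self) -> dict:
        return {
            "kind": self.name,
            "kernel": self.kernel,
            "in_channels": self.in_channels,
            "filters": self.filters,
            "params": self.n_params,
        }

    # -- folded 1-D path ----------------------------------------------------

    def _fold(self, x: np.ndarray) -> tuple[np.ndarray, int, tuple[int, ...]]:
        """Collapse a [k x 1]-style input to (batch', length, features).

        Returns the folded array, the effective kernel extent, and the
        original shape.  ``_unfold`` inverts the arrangement.
        """
        nd = len(self.kernel)
        if nd == 1:
            return x, self.kernel[0], x.shape
        n, h, w, c = x.shape
        if self.kernel[1] == 1:
            xf = np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(n * w, h, c)
            return xf, self.kernel[0], x.shape
        # kernel[0] == 1: slide along the second spatial axis
        return x.reshape(n * h, w, c), self.kernel[1], x.shape

    def _unfold(self, yf: np.ndarray, orig_shape: tuple[int, ...], features: int) -> np.ndarray:
        nd = len(self.kernel)
        if nd == 1:
            return yf
        n, h, w, _ = orig_shape
        if self.kernel[1] == 1:
            return np.ascontiguousarray(
                yf.reshape(n, w, h, features).transpose(0, 2, 1, 3)
            )
        return yf.reshape(n, h, w, features)

    @property
    def _folded(self) -> bool:
        return len(self.kernel) == 1 or 1 in self.kernel

    def _w3(self) -> np.ndarray:
        return self.W.reshape(-1, self.in_channels, self.filters)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        nd = len(self.kernel)
        if x.ndim != nd + 2:
            raise ValueError(f"expected {nd + 2}-axis input; got {x.ndim}")
        self._in_shape = x.shape
        if self._folded:
            xf, k, _ = self._fold(x)
            B, L, _ = xf.shape
            pl, pr = (k - 1) // 2, k // 2
            xp = np.pad(xf, [(0, 0), (pl, pr), (0, 0)])
            self._xp = xp
            w3 = self._w3()
            y = np.empty((B, L, self.filters), dtype=x.dtype)
            y[...] = self.b
            tmp = np.empty_like(y)
            for j in range(k):
                np.matmul(xp[:, j : j + L, :], w3[j], out=tmp)
                y += tmp
            return self._unfold(y, x.shape, self.filters)
        pads = [(0, 0)] + _same_pads(self.kernel) + [(0, 0)]
        xp = np.pad(x, pads)
        self._xp = xp
        cols = _im2col(xp, self.kernel)
        out = cols @ self.W + self.b
        return out.reshape(x.shape[:-1] + (self.filters,))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._folded:
            dyf, k, _ = self._fold(dy)  # same folding applies to gradients
            B, L, _ = dyf.shape
            xp = self._xp
            w3 = self._w3()
            dw3 = self.grads[0].reshape(w3.shape)
            for j in range(k):
                dw3[j] = np.matmul(xp[:, j : j + L, :].transpose(0, 2, 1), dyf).sum(axis=0)
            self.grads[1][...] = dyf.sum(axis=(0, 1))
            # input gradient = correlation of dy with the flipped kernel
            pl, pr = (k - 1) // 2, k // 2
            dyp = np.pad(dyf, [(0, 0), (pr, pl), (0, 0)])
            dxf = np.empty((B, L, self.in_channels), dtype=dy.dtype)
            dxf[...] = 0
            tmp = np.empty_like(dxf)
            for m in range(k):
                np.matmul(dyp[:, m : m + L, :], w3[k - 1 - m].T, out=tmp)
                dxf += tmp
            self._xp = None
            dx = self._unfold(dxf, self._in_shape, self.in_channels)
            return dx.reshape(self._in_shape)
        dy2 = dy.reshape(-1, self.filters)
        cols = _im2col(self._xp, self.kernel)
        self.grads[0][...] = cols.T @ dy2
        self.grads[1][...] = dy2.sum(axis=0)
        pads = [(0, 0)] + [(k // 2, (k - 1) // 2) for k in self.kernel] + [(0, 0)]
        cols_dy = _im2col(np.pad(dy, pads), self.kernel)
        dx = cols_dy @ self._flipped_weight()
        self._xp = None
        return dx.reshape(self._in_shape)

    def _flipped_weight(self) -> np.ndarray:
        """Weight rearranged for the gradient correlation: the input
        gradient is itself a "same"-padded convolution of dy with the
        spatially flipped kernel and in/out channels swapped."""
        nd = len(self.kernel)
        w = self.W.reshape(self.kernel + (self.in_channels, self.filters))
        for ax in range(nd):
            w = np.flip(w, axis=ax)
        w = w.transpose(tuple(range(nd)) + (nd + 1, nd))
        return np.ascontiguousarray(w).reshape(-1, self.in_channels)


def _im2col(xp: np.ndarray, kernel: tuple[int, ...]) -> np.ndarray:
    """im2col matrix (n * prod(spatial_out), prod(kernel) * features),
    kernel-offset-major columns with the feature axis innermost."""
    nd = len(kernel)
    axes = tuple(range(1, 1 + nd))
    win = sliding_window_view(xp, kernel, axis=axes)
    # (n, *S, F, *kernel) -> (n, *S, *kernel, F)
    feat_ax = 1 + nd
    perm = tuple(range(feat_ax)) + tuple(range(feat_ax + 1, win.ndim)) + (feat_ax,)
    win = np.ascontiguousarray(win.transpose(perm))
    n_out = int(np.prod(win.shape[: 1 + nd]))
    return win.reshape(n_out, -1)


class SeparableConv(Layer):
    """Depthwise-separable convolution: per-channel spatial kernel, then
    1x1 pointwise mixing.  Bias on the pointwise stage only."""

    name = "separable_conv"

    def __init__(
        self,
        kernel: tuple[int, ...],
        in_channels: int,
        filters: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.kernel = tuple(int(k) for k in kernel)
        if len(self.kernel) not in (1, 2):
            raise ValueError("kernel must have 1 or 2 extents")
        self.in_channels = int(in_channels)
        self.filters = int(filters)
        ksize = int(np.prod(self.kernel))
        self.Wd = glorot_uniform(rng, ksize, 1, (ksize, in_channels), dtype)
        self.Wp = glorot_uniform(rng, in_channels, filters, (in_channels, filters), dtype)
        self.b = np.zeros(filters, dtype=dtype)
        self.params = [self.Wd, self.Wp, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def describe(self) -> dict:
        return {
            "kind": self.name,
            "kernel": self.kernel,
            "in_channels": self.in_channels,
            "filters": self.filters,
            "params": self.n_params,
        }

    def _windows(self, xp: np.ndarray) -> np.ndarray:
        nd = len(self.kernel)
        axes = tuple(range(1, 1 + nd))
        win = sliding_window_view(xp, self.kernel, axis=axes)
        # (n, *S, Cin, *kernel) -> flatten kernel axes into one
        return win.reshape(win.shape[: 1 + nd + 1] + (-1,))

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        nd = len(self.kernel)
        if x.ndim != nd + 2:
            raise ValueError(f"expected {nd + 2}-axis input; got {x.ndim}")
        pads = [(0, 0)] + _same_pads(self.kernel) + [(0, 0)]
        xp = np.pad(x, pads)
        self._xp = xp
        self._in_shape = x.shape
        win = self._windows(xp)  # (n, *S, Cin, ksize)
        # depthwise: out[..., c] = sum_k win[..., c, k] * Wd[k, c]
        depth = np.einsum("...ck,kc->...c", win, self.Wd)
        self._depth = depth
        return depth @ self.Wp + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        nd = len(self.kernel)
        dy2 = dy.reshape(-1, self.filters)
        depth2 = self._depth.reshape(-1, self.in_channels)
        self.grads[1][...] = depth2.T @ dy2
        self.grads[2][...] = dy2.sum(axis=0)
        ddepth = (dy2 @ self.Wp.T).reshape(self._depth.shape)  # (n, *S, Cin)
        win = self._windows(self._xp)
        win2 = win.reshape(-1, self.in_channels, win.shape[-1])
        dd2 = ddepth.reshape(-1, self.in_channels)
        self.grads[0][...] = np.einsum("nck,nc->kc", win2, dd2)
        dxp = np.zeros_like(self._xp)
        spatial = self._in_shape[1 : 1 + nd]
        if nd == 1:
            (L,) = spatial
            for j in range(self.kernel[0]):
                dxp[:, j : j + L, :] += ddepth * self.Wd[j]
        else:
            H, W = spatial
            for i in range(self.kernel[0]):
                for j in range(self.kernel[1]):
                    dxp[:, i : i + H, j : j + W, :] += ddepth * self.Wd[i * self.kernel[1] + j]
        sl = tuple(
            [slice(None)]
            + [slice(p[0], p[0] + s) for p, s in zip(_same_pads(self.kernel), spatial)]
            + [slice(None)]
        )
        self._xp = None
        self._depth = None
        return dxp[sl]


class BatchNorm(Layer):
    """Per-feature batch normalisation over batch + spatial axes."""

    name = "batch_norm"

    def __init__(
        self,
        n_features: int,
        momentum: float = 0.1,
        epsilon: float = 1e-5,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.n_features = int(n_features)
        self.momentum = float(momentum)
        self.epsilon = float(epsilon)
        self.gamma = np.ones(n_features, dtype=dtype)
        self.beta = np.zeros(n_features, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n_features, dtype=np.float64)
        self.running_var = np.ones(n_features, dtype=np.float64)

    def describe(self) -> dict:
        return {"kind": self.name, "features": self.n_features, "params": self.n_params}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv_std = 1.0 / np.sqrt(var + self.epsilon)
        xhat = (x - mean) * inv_std
        self._xhat = xhat if training else None
        self._inv_std = inv_std
        self._axes = axes
        return (self.gamma * xhat + self.beta).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        axes = self._axes
        m = float(np.prod([dy.shape[a] for a in axes]))
        self.grads[0][...] = (dy * xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / m
        ) * self._inv_std
        self._xhat = None
        return dx.astype(dy.dtype)


class Elu(Layer):
    name = "elu"

    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        if alpha <= 0:
            raise ValueError(f"alpha must be > 0; got {alpha}")
        self.alpha = float(alpha)

    def describe(self) -> dict:
        return {"kind": self.name, "alpha": self.alpha, "params": 0}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0.0))).astype(x.dtype)
        self._x = x
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * np.where(self._x > 0, 1.0, self._y + self.alpha).astype(dy.dtype)
        self._x = None
        self._y = None
        return dx


class AvgPoolHalf(Layer):
    """Halve the leading spatial axis by mean pooling (floor; skip at 1)."""

    name = "avg_pool"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        L = x.shape[1]
        self._L = L
        if L <= 1:
            return x
        half = L // 2
        trimmed = x[:, : 2 * half]
        out = trimmed.reshape((x.shape[0], half, 2) + x.shape[2:]).mean(axis=2)
        return out.astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        L = self._L
        if L <= 1:
            return dy
        half = L // 2
        up = np.repeat(dy, 2, axis=1) * 0.5
        if 2 * half < L:
            pad = [(0, 0)] * dy.ndim
            pad[1] = (0, L - 2 * half)
            up = np.pad(up, pad)
        return up.astype(dy.dtype)


class Dropout(Layer):
    """Inverted dropout; active only during training."""

    name = "dropout"

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1); got {rate}")
        self.rate = float(rate)
        self.rng = rng

    def describe(self) -> dict:
        return {"kind": self.name, "rate": self.rate, "params": 0}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        draws = self.rng.random(size=x.shape, dtype=np.float32)
        mask = (draws < keep).astype(x.dtype) / np.asarray(keep, dtype=x.dtype)
        self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        out = dy * self._mask
        self._mask = None
        return out


class Flatten(Layer):
    name = "flatten"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    name = "dense"

    def __init__(
        self, in_features: int, out_features: int, rng: np.random.Generator, dtype=np.float32
    ) -> None:
        super().__init__()
        self.in_features = int(in_features)
        self.out_features = int(out_features)
        self.W = glorot_uniform(rng, in_features, out_features, (in_features, out_features), dtype)
        self.b = np.zeros(out_features, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def describe(self) -> dict:
        return {
            "kind": self.name,
            "in_features": self.in_features,
            "units": self.out_features,
            "params": self.n_params,
        }

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        dx = dy @ self.W.T
        self._x = None
        return dx


class Softmax(Layer):
    name = "softmax"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        self._p = p
        return p

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p = self._p
        dx = p * (dy - (dy * p).sum(axis=-1, keepdims=True))
        self._p = None
        return dx.astype(dy.dtype)
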