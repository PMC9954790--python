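"""The eight input-tensor layouts and convolution parameter-count formulas.

Every epoched trial carries ``T x C`` raw scalars (timestamps by
electrodes).  How those scalars are arranged before entering a
convolutional network — which axis slides under the kernel, which axis is
treated as feature channels — changes both the learned features and the
parameter budget.  This module implements the eight layouts as exact,
invertible rearrangements of the canonical time-major ``(T, C)`` trial:

======== =============== ==========================================
code     extents         axis binding
======== =============== ==========================================
TxC      (T, C)          canonical, rank 2
CxT      (C, T)          transpose, rank 2
TxCx1    (T, C, 1)       trailing singleton feature axis
CxTx1    (C, T, 1)       transpose + trailing singleton
1xTxC    (1, T, C)       singleton leading axis, channels as features
1xCxT    (1, C, T)       singleton leading axis, timestamps as features
Tx1xC    (T, 1, C)       singleton middle axis, channels as features
Cx1xT    (C, 1, T)       singleton middle axis, timestamps as features
======== =============== ==========================================

For rank-3 codes the axes follow the (height, width, channel) convention:
the last axis is always the one a 2-D convolution treats as feature
channels.  All transforms are pure rearrangements — bijective, value
preserving and bit-exact.

Parameter counts of a convolution layer follow the standard closed form
``W = prod(kernel) * C_in * N`` weights plus ``B = N`` biases, generalised
here to rectangular kernels (the architecture uses ``[k x 1]`` kernels
throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "ShapeCode",
    "ALL_SHAPES",
    "ParamCount",
    "to_input_shape",
    "from_input_shape",
    "batch_to_input_shape",
    "shape_extents",
    "conv_param_count",
    "separable_param_count",
]


class ShapeCode(str, Enum):
    """Identifier of one of the eight input layouts.

    The enum *value* is the literal serialisation used in configs and on
    the command line (``"TxC"`` ... ``"Cx1xT"``).
    """

    TxC = "TxC"
    CxT = "CxT"
    TxCx1 = "TxCx1"
    CxTx1 = "CxTx1"
    OnexTxC = "1xTxC"
    OnexCxT = "1xCxT"
    Tx1xC = "Tx1xC"
    Cx1xT = "Cx1xT"

    @property
    def axes(self) -> tuple[str, ...]:
        """Axis labels, e.g. ``('C', '1', 'T')`` for Cx1xT."""
        return tuple(self.value.split("x"))

    @property
    def rank(self) -> int:
        return len(self.axes)

    @classmethod
    def parse(cls, text: "str | ShapeCode") -> "ShapeCode":
        if isinstance(text, cls):
            return text
        try:
            return cls(text)
        except ValueError:
            valid = ", ".join(s.value for s in cls)
            raise ValueError(f"unknown shape code {text!r}; valid codes: {valid}") from None


#: Canonical report ordering of the eight layouts.
ALL_SHAPES: tuple[ShapeCode, ...] = (
    ShapeCode.TxC,
    ShapeCode.CxT,
    ShapeCode.TxCx1,
    ShapeCode.CxTx1,
    ShapeCode.OnexTxC,
    ShapeCode.OnexCxT,
    ShapeCode.Tx1xC,
    ShapeCode.Cx1xT,
)


def shape_extents(shape: ShapeCode | str, T: int, C: int) -> tuple[int, ...]:
    """Extent tuple of a layout for a ``T x C`` trial (product is T*C)."""
    shape = ShapeCode.parse(shape)
    if T < 1 or C < 1:
        raise ValueError(f"T and C must be >= 1; got T={T}, C={C}")
    lut = {"T": int(T), "C": int(C), "1": 1}
    return tuple(lut[a] for a in shape.axes)


def _plan(shape: ShapeCode) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """(transpose order over (T, C), positions of singleton axes)."""
    axes = shape.axes
    labelled = [a for a in axes if a != "1"]
    perm = (0, 1) if labelled == ["T", "C"] else (1, 0)
    singles = tuple(i for i, a in enumerate(axes) if a == "1")
    return perm, singles


def to_input_shape(trial: np.ndarray, shape: ShapeCode | str) -> np.ndarray:
    """Rearrange one canonical ``(T, C)`` trial into the named layout.

    Element ``(t, c)`` of the canonical trial lands at the position whose
    T-labelled index is ``t`` and whose C-labelled index is ``c`` (singleton
    axes at index 0).  Pure rearrangement; no value is altered.
    """
    shape = ShapeCode.parse(shape)
    trial = np.asarray(trial)
    if trial.ndim != 2:
        raise ValueError(f"trial must be 2-axis (T, C); got ndim={trial.ndim}")
    perm, singles = _plan(shape)
    out = trial.transpose(perm)
    for pos in singles:
        out = np.expand_dims(out, axis=pos)
    return out


def from_input_shape(
    x: np.ndarray, shape: ShapeCode | str, T: int, C: int
) -> np.ndarray:
    """Exact inverse of :func:`to_input_shape`."""
    shape = ShapeCode.parse(shape)
    x = np.asarray(x)
    expected = shape_extents(shape, T, C)
    if x.shape != expected:
        raise ValueError(
            f"extents {x.shape} inconsistent with {shape.value} at T={T}, C={C}"
            f" (expected {expected})"
        )
    perm, singles = _plan(shape)
    out = x
    for pos in reversed(singles):
        out = np.squeeze(out, axis=pos)
    return out.transpose(np.argsort(perm))


def batch_to_input_shape(trials: np.ndarray, shape: ShapeCode | str) -> np.ndarray:
    """Vectorised :func:`to_input_shape` over a leading trial axis."""
    shape = ShapeCode.parse(shape)
    trials = np.asarray(trials)
    if trials.ndim != 3:
        raise ValueError(f"trials must be (n, T, C); got ndim={trials.ndim}")
    perm, singles = _plan(shape)
    out = trials.transpose((0,) + tuple(p + 1 for p in perm))
    for pos in singles:
        out = np.expand_dims(out, axis=pos + 1)
    return out


@dataclass(frozen=True)
class ParamCount:
    """Weight/bias/total parameter counts of a convolution layer."""

    weights: int
    biases: int

    @property
    def total(self) -> int:
        return self.weights + self.biases


def _check_positive(**kwargs: int) -> None:
    for name, v in kwargs.items():
        if v < 1:
            raise ValueError(f"{name} must be >= 1; got {v}")


def conv_param_count(
    kernel_extents: tuple[int, ...] | list[int] | int,
    in_channels: int,
    n_kernels: int,
) -> ParamCount:
    """Parameter count of a plain convolution layer.

    ``weights = prod(kernel_extents) * in_channels * n_kernels`` and
    ``biases = n_kernels``; a square kernel ``(K, K)`` recovers the familiar
    ``K^2 * C * N`` form.
    """
    if isinstance(kernel_extents, int):
        kernel_extents = (kernel_extents,)
    kernel_extents = tuple(int(k) for k in kernel_extents)
    _check_positive(in_channels=in_channels, n_kernels=n_kernels)
    for k in kernel_extents:
        _check_positive(kernel_extent=k)
    w = math.prod(kernel_extents) * in_channels * n_kernels
    return ParamCount(weights=w, biases=n_kernels)


def separable_param_count(
    kernel_extents: tuple[int, ...] | list[int] | int,
    in_channels: int,
    n_kernels: int,
) -> ParamCount:
    """Parameter count of a depthwise-separable convolution layer.

    The kernel factorises into a per-channel (depthwise) spatial stage of
    ``prod(kernel) * in_channels`` weights and a 1x1 pointwise mixing stage
    of ``in_channels * n_kernels`` weights; the bias sits on the pointwise
    stage only.
    """
    if isinstance(kernel_extents, int):
        kernel_extents = (kernel_extents,)
    kernel_extents = tuple(int(k) for k in kernel_extents)
    _check_positive(in_channels=in_channels, n_kernels=n_kernels)
    for k in kernel_extents:
        _check_positive(kernel_extent=k)
    w = math.prod(kernel_extents) * in_channels + in_channels * n_kernels
    return ParamCount(weights=w, biases=n_kernels)
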