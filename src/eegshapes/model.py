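"""The two-variant compact CNN for raw motor-imagery trials.

One architecture, two builds: layouts of rank 2 get a one-dimensional
convolutional network whose second axis is the feature-channel axis;
layouts of rank 3 get a two-dimensional convolutional network whose third
axis is the feature-channel axis.  Both share the same layer schedule and
hyperparameters:

    input batch-norm
    3 x [ (conv + BN) x 3, separable conv, BN, ELU, avg-pool(1/2), dropout ]
    flatten, dense(n_classes), softmax

Default block schedule: conv kernels (30,1)/(15,1)/(15,1) with 64/32/16
filters, separable kernels (15,1)/(7,1)/(7,1) with matching filters.
Dropout 0.7, batch-norm momentum 0.1 / epsilon 1e-5, ELU alpha 1.0 (alpha
is a user constant in (0, 1]).  All convolutions use zero-padded "same"
extents; average pooling halves the leading spatial axis (floor), and is
skipped on an axis of extent 1 — necessary e.g. for a 3-channel montage
after one halving, or for layouts with a singleton leading axis.

The network starts with batch normalisation (and renormalises after every
convolution) so that raw, unscaled EEG can be fed directly: each batch is
standardised inside the model, which also counters the covariate shift
that non-stationary EEG exhibits between batches and sessions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .nn import (
    AvgPoolHalf,
    BatchNorm,
    Conv,
    Dense,
    Dropout,
    Elu,
    Flatten,
    Network,
    SeparableConv,
    Softmax,
)
from .nn.layers import elu  # noqa: F401  (re-exported scalar ELU)
from .shapes import ShapeCode, conv_param_count, separable_param_count, shape_extents

__all__ = [
    "BlockSpec",
    "ModelConfig",
    "ModelSpec",
    "build_model",
    "count_parameters",
    "default_blocks",
    "elu",
]


@dataclass(frozen=True)
class BlockSpec:
    """Kernel/filter schedule of one conv block."""

    conv_kernel: tuple[int, int]
    conv_filters: int
    sep_kernel: tuple[int, int]
    sep_filters: int

    def __post_init__(self) -> None:
        for name in ("conv_kernel", "sep_kernel"):
            k = tuple(int(v) for v in getattr(self, name))
            object.__setattr__(self, name, k)
            if len(k) != 2 or min(k) < 1:
                raise ValueError(f"{name} must be a pair of extents >= 1; got {k}")
        if self.conv_filters < 1 or self.sep_filters < 1:
            raise ValueError("filter counts must be >= 1")


def default_blocks() -> tuple[BlockSpec, BlockSpec, BlockSpec]:
    return (
        BlockSpec((30, 1), 64, (15, 1), 64),
        BlockSpec((15, 1), 32, (7, 1), 32),
        BlockSpec((15, 1), 16, (7, 1), 16),
    )


@dataclass(frozen=True)
class ModelConfig:
    """Architecture configuration for one input layout and trial geometry."""

    n_classes: int
    input_shape: ShapeCode
    T: int
    C: int
    blocks: tuple[BlockSpec, ...] = field(default_factory=default_blocks)
    elu_alpha: float = 1.0
    dropout_rate: float = 0.7
    bn_momentum: float = 0.1
    bn_epsilon: float = 1e-5

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_shape", ShapeCode.parse(self.input_shape))
        blocks = tuple(
            b if isinstance(b, BlockSpec) else BlockSpec(**b) for b in self.blocks
        )
        object.__setattr__(self, "blocks", blocks)
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2; got {self.n_classes}")
        if self.T < 1 or self.C < 1:
            raise ValueError(f"T and C must be >= 1; got T={self.T}, C={self.C}")
        if not 0 < self.elu_alpha <= 1:
            raise ValueError(f"elu_alpha must be in (0, 1]; got {self.elu_alpha}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1); got {self.dropout_rate}")
        if not 0 < self.bn_momentum < 1:
            raise ValueError(f"bn_momentum must be in (0, 1); got {self.bn_momentum}")
        if self.bn_epsilon <= 0:
            raise ValueError("bn_epsilon must be > 0")

    @property
    def input_extents(self) -> tuple[int, ...]:
        return shape_extents(self.input_shape, self.T, self.C)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_shape"] = self.input_shape.value
        d["blocks"] = [asdict(b) for b in self.blocks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "blocks" in d:
            d["blocks"] = tuple(BlockSpec(**b) for b in d["blocks"])
        return cls(**d)


@dataclass
class ModelSpec:
    """Ordered layer descriptions and the total trainable parameter count."""

    layers: list[dict]
    total_params: int
    input_extents: tuple[int, ...]
    output_classes: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.layers):
            rows.append(
                {
                    "layer": i,
                    "kind": d["kind"],
                    "kernel": "x".join(map(str, d.get("kernel", ()))) or "",
                    "filters": d.get("filters", d.get("units", "")),
                    "output": "x".join(map(str, d["output_extents"])),
                    "params": d["params"],
                }
            )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        header = (
            f"input extents {('x'.join(map(str, self.input_extents)))} -> "
            f"{self.output_classes} classes; "
            f"{self.total_params:,} trainable parameters"
        )
        return header + "\n" + self.to_frame().to_string(index=False)


def _pooled(spatial: tuple[int, ...]) -> tuple[int, ...]:
    lead = spatial[0]
    return ((lead // 2 if lead > 1 else lead),) + spatial[1:]


def build_model(cfg: ModelConfig, seed: int = 0) -> Network:
    """Build the network for a config; returns a :class:`Network` whose
    ``spec`` attribute carries the :class:`ModelSpec` layer table.

    Initial weights are Glorot-uniform draws from a generator seeded with
    ``seed``, so identical (config, seed) pairs give identical networks.
    """
    extents = cfg.input_extents
    rank = len(extents)
    spatial = extents[:-1]
    features = extents[-1]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE3]))
    drop_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD0]))

    def kern(pair: tuple[int, int]) -> tuple[int, ...]:
        # rank-2 inputs use 1-D convolution: a [k x 1] kernel slides its
        # k-extent along the single spatial axis.
        return (pair[0],) if rank == 2 else pair

    layers: list = []
    rows: list[dict] = []

    def add(layer, out_spatial: tuple[int, ...], out_features: int) -> None:
        layers.append(layer)
        d = layer.describe()
        d["output_extents"] = out_spatial + (out_features,)
        rows.append(d)

    add(BatchNorm(features, cfg.bn_momentum, cfg.bn_epsilon), spatial, features)
    for block in cfg.blocks:
        for _ in range(3):
            add(
                Conv(kern(block.conv_kernel), features, block.conv_filters, rng),
                spatial,
                block.conv_filters,
            )
            features = block.conv_filters
            add(BatchNorm(features, cfg.bn_momentum, cfg.bn_epsilon), spatial, features)
        add(
            SeparableConv(kern(block.sep_kernel), features, block.sep_filters, rng),
            spatial,
            block.sep_filters,
        )
        features = block.sep_filters
        add(BatchNorm(features, cfg.bn_momentum, cfg.bn_epsilon), spatial, features)
        add(Elu(cfg.elu_alpha), spatial, features)
        spatial = _pooled(spatial)
        add(AvgPoolHalf(), spatial, features)
        add(Dropout(cfg.dropout_rate, drop_rng), spatial, features)
    flat = int(np.prod(spatial)) * features
    add(Flatten(), (), flat)
    add(Dense(flat, cfg.n_classes, rng), (), cfg.n_classes)
    add(Softmax(), (), cfg.n_classes)

    net = Network(layers, extents)
    net.spec = ModelSpec(
        layers=rows,
        total_params=net.n_params,
        input_extents=extents,
        output_classes=cfg.n_classes,
    )
    net.config = cfg
    net.seed_dropout(int(seed))
    return net


def count_parameters(model: Network) -> int:
    """Total trainable parameters, summed layer by layer.

    Every plain convolution layer contributes exactly
    ``conv_param_count(kernel, in_channels, filters).total`` and every
    separable convolution ``separable_param_count(...).total``; the sum
    equals the container's own ``n_params``.
    """
    total = 0
    for layer in model.layers:
        if isinstance(layer, SeparableConv):
            total += separable_param_count(layer.kernel, layer.in_channels, layer.filters).total
        elif isinstance(layer, Conv):
            total += conv_param_count(layer.kernel, layer.in_channels, layer.filters).total
        else:
            total += layer.n_params
    return total
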