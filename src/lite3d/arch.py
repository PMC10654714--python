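"""Symbolic arithmetic over a 3D conv/pool stack.

Lite3D is a full-convolution video classifier: a stack of valid (unpadded)
3D convolutions and non-overlapping max-pooling layers that reduces a
``k`` x ``c`` @ ``n`` x ``n`` clip (frames x channels @ height x width) to a
1 x ``l`` @ 1 x 1 map, where ``l`` is the number of behavior categories.
Because every layer shrinks its input deterministically, the admissible
input sizes, the per-layer shapes and the trainable-parameter budget are
all closed-form functions of the layer configuration.  This module computes
them without building the network.

Conventions (fixed across the package):

* convolutions use stride 1 and no padding, so each axis shrinks by
  ``kernel - 1``;
* pooling uses stride equal to the pool kernel with *ceiling* division,
  so each axis maps ``d -> ceil(d / kernel)`` (a partial window at the
  border still produces an output element);
* kernels are given as ``spatial x spatial x temporal`` — spatial kernels
  are square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence


class InvalidConfigError(ValueError):
    """A layer stack is inconsistent with its input or target size."""


@dataclass(frozen=True)
class LayerSpec:
    """One conv or pool layer of the stack.

    Parameters
    ----------
    kind:
        ``"conv"`` or ``"pool"``.
    spatial_kernel:
        Square spatial kernel side (c_n for conv, p_n for pool).
    temporal_kernel:
        Kernel extent along the frame axis (c_p / p_p).
    n_kernels:
        Number of convolution kernels (output channels); conv only.
    """

    kind: Literal["conv", "pool"]
    spatial_kernel: int
    temporal_kernel: int
    n_kernels: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "pool"):
            raise InvalidConfigError(f"unknown layer kind {self.kind!r}")
        if self.spatial_kernel < 1 or self.temporal_kernel < 1:
            raise InvalidConfigError("kernel extents must be >= 1")
        if (self.n_kernels is not None) != (self.kind == "conv"):
            raise InvalidConfigError("n_kernels must be given iff kind == 'conv'")
        if self.n_kernels is not None and self.n_kernels < 1:
            raise InvalidConfigError("n_kernels must be >= 1")


@dataclass(frozen=True)
class Shape:
    """A feature-map shape: ``depth`` frames x ``channels`` @ ``height`` x ``width``."""

    depth: int
    channels: int
    height: int
    width: int

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.depth, self.channels, self.height, self.width)


@dataclass(frozen=True)
class ShapeTrace:
    """Per-layer output shapes, input first."""

    shapes: tuple[Shape, ...]

    @property
    def final(self) -> Shape:
        return self.shapes[-1]

    def __iter__(self) -> Iterator[Shape]:
        return iter(self.shapes)

    def __getitem__(self, i: int) -> Shape:
        return self.shapes[i]


@dataclass(frozen=True)
class ArchConfig:
    """A full network configuration.

    ``input_width`` must equal ``input_height`` (square clips); the target
    final shape defaults to the fully-reduced 1x1x1 map of the reference
    design.
    """

    layers: tuple[LayerSpec, ...]
    input_width: int = 64
    input_height: int = 64
    input_depth: int = 10
    input_channels: int = 3
    n_categories: int = 5
    target_final_shape: tuple[int, int, int] = (1, 1, 1)  # (w', h', k')

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.input_width != self.input_height:
            raise InvalidConfigError("input must be square (w == h)")
        if self.n_categories < 1:
            raise InvalidConfigError("need at least one category")
        if not self.layers:
            raise InvalidConfigError("empty layer stack")

    @property
    def input_shape(self) -> Shape:
        return Shape(self.input_depth, self.input_channels,
                     self.input_height, self.input_width)


def reference_layers(n_categories: int) -> tuple[LayerSpec, ...]:
    """The reference Lite3D stack: C1 16@3x3x1, S1 3x3x1, C2 32@3x3x3,
    S2 3x3x1, C3 64@3x3x3, S3 2x2x2, C4 l@3x3x3.

    C1's temporal kernel is deliberately 1: the first layer is a per-frame
    2D convolution, so temporal mixing starts at C2.
    """
    return (
        LayerSpec("conv", 3, 1, 16),
        LayerSpec("pool", 3, 1),
        LayerSpec("conv", 3, 3, 32),
        LayerSpec("pool", 3, 1),
        LayerSpec("conv", 3, 3, 64),
        LayerSpec("pool", 2, 2),
        LayerSpec("conv", 3, 3, n_categories),
    )


def reference_config(n_categories: int = 5, input_size: int = 64,
                     input_depth: int = 10) -> ArchConfig:
    """The canonical Lite3D architecture (10x3@64x64 input)."""
    return ArchConfig(
        layers=reference_layers(n_categories),
        input_width=input_size,
        input_height=input_size,
        input_depth=input_depth,
        input_channels=3,
        n_categories=n_categories,
    )


def _apply_layer(shape: Shape, layer: LayerSpec, index: int) -> Shape:
    if layer.kind == "conv":
        d = shape.depth - (layer.temporal_kernel - 1)
        h = shape.height - (layer.spatial_kernel - 1)
        w = shape.width - (layer.spatial_kernel - 1)
        c = layer.n_kernels  # type: ignore[assignment]
    else:
        d = math.ceil(shape.depth / layer.temporal_kernel)
        h = math.ceil(shape.height / layer.spatial_kernel)
        w = math.ceil(shape.width / layer.spatial_kernel)
        c = shape.channels
    if d < 1 or h < 1 or w < 1:
        raise InvalidConfigError(
            f"layer {index} ({layer.kind}) yields non-positive shape "
            f"{d}x{c}@{h}x{w} from {shape.depth}x{shape.channels}@"
            f"{shape.height}x{shape.width}"
        )
    return Shape(d, c, h, w)


def propagate_shapes(config: ArchConfig) -> ShapeTrace:
    """Propagate the input shape through every layer.

    Returns the trace (input shape first, one entry per layer after) and
    raises :class:`InvalidConfigError`, naming the offending layer, as soon
    as any dimension would drop below 1.
    """
    shapes = [config.input_shape]
    for i, layer in enumerate(config.layers):
        shapes.append(_apply_layer(shapes[-1], layer, i))
    return ShapeTrace(tuple(shapes))


def _backward_interval(layers: Sequence[LayerSpec], axis: str,
                       target: int) -> tuple[int, int]:
    """Exact preimage interval of a target size under the layer stack.

    Walk the stack backwards: a conv layer adds ``kernel - 1`` to both
    endpoints; a pool layer with kernel ``p`` maps the output interval
    [lo, hi] to [(lo - 1) * p + 1, hi * p] because ceil(x / p) = v exactly
    for x in ((v-1)*p, v*p].  Both maps are monotone, so the preimage of an
    interval is an interval and the endpoints are exact.
    """
    lo = hi = target
    for layer in reversed(layers):
        k = layer.spatial_kernel if axis == "spatial" else layer.temporal_kernel
        if layer.kind == "conv":
            lo += k - 1
            hi += k - 1
        else:
            lo = (lo - 1) * k + 1
            hi = hi * k
    return lo, hi


def admissible_spatial_range(config: ArchConfig) -> tuple[int, int]:
    """Closed interval of square input sizes reaching the target final
    spatial size exactly (reference stack: 63..80 for a 1x1 target)."""
    w_target = config.target_final_shape[0]
    lo, hi = _backward_interval(config.layers, "spatial", w_target)
    if lo > hi or lo < 1:
        raise InvalidConfigError("empty admissible spatial interval")
    return lo, hi


def admissible_depth_range(config: ArchConfig) -> tuple[int, int]:
    """Closed interval of input frame counts reaching the target final
    depth exactly (reference stack: 9..10 for a depth-1 target)."""
    k_target = config.target_final_shape[2]
    lo, hi = _backward_interval(config.layers, "temporal", k_target)
    if lo > hi or lo < 1:
        raise InvalidConfigError("empty admissible depth interval")
    return lo, hi


@dataclass(frozen=True)
class ParameterCount:
    """Trainable-parameter budget: one entry per block.

    A block is a conv layer together with any pooling layers that follow
    it (pooling is parameter-free).
    """

    per_block: tuple[int, ...] = field(default=())
    total: int = 0

    @property
    def millions(self) -> float:
        """Total in millions, rounded to two decimals (reporting convention)."""
        return round(self.total / 1e6, 2)


def count_parameters(config: ArchConfig) -> ParameterCount:
    """Exact trainable-parameter counts per conv block and in total.

    A conv layer with ``n`` kernels of ``s x s x t`` over ``c_in`` input
    channels holds ``s^2 * t * c_in * n`` weights plus ``n`` biases; pool
    layers contribute nothing.  The reference stack gives 448 / 13,856 /
    55,360 for the three backbone blocks and 1728*l + l for the head.
    """
    per_block: list[int] = []
    c_in = config.input_channels
    for layer in config.layers:
        if layer.kind != "conv":
            continue
        n = layer.n_kernels  # type: ignore[assignment]
        weights = layer.spatial_kernel ** 2 * layer.temporal_kernel * c_in * n
        per_block.append(weights + n)
        c_in = n
    return ParameterCount(tuple(per_block), sum(per_block))
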