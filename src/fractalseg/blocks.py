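"""Architecture building blocks.

* ``ConvUnit`` — 3x3 convolution + batch normalization + ReLU.
* ``FractalBlock`` — the recursive fractal expansion
  f_1 = conv_unit, f_{C+1} = join(conv_unit, f_C ∘ f_C), where the join
  is the elementwise mean of the parallel paths.  An order-C block
  contains exactly 2^C − 1 conv units and widens the receptive field by
  running paths of different depths in parallel.
* ``AttentionGate`` — additive attention over a skip connection: a
  one-channel sigmoid weight map computed from the skip features and a
  coarser decoder gating signal, multiplied into the skip features.
* ``Down`` / ``Up`` — 2x2 max pooling and nearest-neighbour upsampling
  followed by a 2x2 convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import ops

__all__ = [
    "ConvUnitSpec",
    "FractalSpec",
    "AttentionGateSpec",
    "ConvUnit",
    "FractalBlock",
    "AttentionGate",
    "Down",
    "Up",
    "fractal_conv_unit_count",
]


@dataclass(frozen=True)
class ConvUnitSpec:
    width: int
    kernel: int = 3
    batch_norm: bool = True

    def __post_init__(self):
        if self.width < 1:
            raise ValueError("width must be >= 1")


@dataclass(frozen=True)
class FractalSpec:
    order: int
    width: int

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("fractal order must be >= 1")
        if self.width < 1:
            raise ValueError("width must be >= 1")


@dataclass(frozen=True)
class AttentionGateSpec:
    skip_channels: int
    gate_channels: int
    inter_channels: int

    def __post_init__(self):
        if self.inter_channels < 1:
            raise ValueError("inter_channels must be >= 1")


def fractal_conv_unit_count(order: int) -> int:
    """Number of conv units in an order-C fractal block: 2^C − 1."""
    if order < 1:
        raise ValueError("fractal order must be >= 1")
    return 2 ** order - 1


class ConvUnit(nn.Module):
    """3x3 same-padding convolution, batch norm, ReLU."""

    def __init__(self, in_channels: int, width: int,
                 rng: np.random.Generator | None = None, batch_norm: bool = True):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, width, 3, rng=rng)
        self.bn = nn.BatchNorm2d(width) if batch_norm else None
        self.width = width

    def forward(self, x):
        x = self.conv(x)
        if self.bn is not None:
            x = self.bn(x)
        return ops.relu(x)


class FractalBlock(nn.Module):
    """Order-C fractal expansion of a conv unit.

    The block runs a single conv unit in parallel with two chained
    order-(C−1) blocks and joins the two paths by elementwise mean.
    Output channels equal ``width``; spatial dims are preserved.
    """

    def __init__(self, in_channels: int, width: int, order: int,
                 rng: np.random.Generator | None = None, batch_norm: bool = True):
        super().__init__()
        if order < 1:
            raise ValueError("fractal order must be >= 1")
        self.order = order
        self.width = width
        if order == 1:
            self.unit = ConvUnit(in_channels, width, rng=rng, batch_norm=batch_norm)
        else:
            self.shallow = ConvUnit(in_channels, width, rng=rng, batch_norm=batch_norm)
            self.deep_a = FractalBlock(in_channels, width, order - 1, rng=rng, batch_norm=batch_norm)
            self.deep_b = FractalBlock(width, width, order - 1, rng=rng, batch_norm=batch_norm)

    def forward(self, x):
        if self.order == 1:
            return self.unit(x)
        return ops.mean_stack([self.shallow(x), self.deep_b(self.deep_a(x))])

    def conv_units(self) -> list[ConvUnit]:
        """All conv units in the expansion (for structural introspection)."""
        return [m for m in self.modules() if isinstance(m, ConvUnit)]


class AttentionGate(nn.Module):
    """Additive attention gate over a skip connection.

    The gating signal comes from the next-coarser decoder level and is
    nearest-upsampled to the skip resolution.  Both inputs are projected
    to ``inter_channels`` with 1x1 convolutions, summed, rectified and
    reduced to a one-channel sigmoid weight map that rescales the skip
    features pixelwise.
    """

    def __init__(self, skip_channels: int, gate_channels: int,
                 inter_channels: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if inter_channels is None:
            inter_channels = max(skip_channels // 2, 1)
        self.spec = AttentionGateSpec(skip_channels, gate_channels, inter_channels)
        self.w_x = nn.Conv2d(skip_channels, inter_channels, 1, rng=rng)
        self.w_g = nn.Conv2d(gate_channels, inter_channels, 1, rng=rng)
        self.psi = nn.Conv2d(inter_channels, 1, 1, rng=rng)
        self.last_alpha: np.ndarray | None = None

    def forward(self, skip, gate):
        if gate.shape[2] * 2 == skip.shape[2] and gate.shape[3] * 2 == skip.shape[3]:
            gate = ops.upsample_nearest2(gate)
        if gate.shape[2:] != skip.shape[2:]:
            raise ValueError(
                f"gate spatial dims {gate.shape[2:]} incompatible with skip {skip.shape[2:]}"
            )
        a = ops.relu(ops.add(self.w_x(skip), self.w_g(gate)))
        alpha = ops.sigmoid(self.psi(a))
        self.last_alpha = alpha.data
        return ops.mul_gate(skip, alpha)


class Down(nn.Module):
    """2x2 max pooling (halves spatial dims; requires even input dims)."""

    def __init__(self):
        super().__init__()

    def forward(self, x):
        return ops.maxpool2(x)


class Up(nn.Module):
    """Nearest-neighbour 2x upsampling followed by a 2x2 convolution."""

    def __init__(self, in_channels: int, width: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, width, 2, rng=rng, padding=((0, 1), (0, 1)))

    def forward(self, x):
        return self.conv(ops.upsample_nearest2(x))
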