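"""The four encoder–decoder architectures and their capacity calibration.

Architectures (all 2D, single-channel in, sigmoid single-channel out):

* ``unet`` — baseline U-Net: double conv units per level, 2x2 max-pool
  encoder, nearest-upsample + 2x2 conv decoder, identity skip
  concatenation.
* ``fractalspinet`` — every double-conv group replaced by a fractal
  block of order C in both encoder and decoder.
* ``att_fractalspinet`` — FractalSpiNet with an additive attention gate
  on every skip connection, gated by the coarser decoder feature.
* ``con_fractalunet`` — baseline U-Net whose skip tensors pass through a
  fractal block before concatenation.

The reference publication for this model family prints only total
parameter counts (31.4 / 109.9 / 115.8 / 53.3 million), not widths or
fractal order.  ``calibrate_capacity`` therefore fixes the free
bottleneck width, starting from the canonical (64, 128, 256, 512, 1024)
geometry at fractal order 3, so that the built model's count matches
the printed total at one-decimal rounding.  The calibrated widths are
released as the default configurations (``default_config``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .nn import ops
from .blocks import AttentionGate, ConvUnit, Down, FractalBlock, Up

__all__ = [
    "ArchitectureConfig",
    "SegmentationModel",
    "ARCH_NAMES",
    "CAPACITY_TARGETS_M",
    "CalibrationError",
    "build_model",
    "build_unet",
    "build_fractalspinet",
    "build_att_fractalspinet",
    "build_con_fractalunet",
    "count_parameters",
    "calibrate_capacity",
    "default_config",
]

ARCH_NAMES = ("unet", "fractalspinet", "att_fractalspinet", "con_fractalunet")

#: published total parameter counts, in millions, used for calibration
CAPACITY_TARGETS_M = {
    "unet": 31.4,
    "fractalspinet": 109.9,
    "att_fractalspinet": 115.8,
    "con_fractalunet": 53.3,
}

#: bottleneck widths found by the one-time ``calibrate_capacity`` search
#: from the canonical (64, 128, 256, 512, 1024) geometry (see
#: ``default_config``); a regression test re-runs the search.
CALIBRATED_BOTTLENECK_WIDTHS = {
    "unet": 1037,
    "fractalspinet": 1096,
    "att_fractalspinet": 1151,
    "con_fractalunet": 1035,
}


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ArchitectureConfig:
    """Every free hyperparameter of a model builder."""

    arch_name: str = "unet"
    input_size: tuple[int, int, int] = (256, 256, 1)
    depth: int = 4
    stage_widths: tuple[int, ...] = (64, 128, 256, 512, 1024)
    fractal_order: int = 3
    dropout_rate: float = 0.5
    attention: bool = False
    batch_norm: bool = True
    output_activation: str = "sigmoid"
    seed: int = 0

    def __post_init__(self):
        if self.arch_name not in ARCH_NAMES:
            raise ValueError(f"unknown architecture {self.arch_name!r}; choose from {ARCH_NAMES}")
        h, w, c = self.input_size
        if h % (2 ** self.depth) or w % (2 ** self.depth):
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth = {2 ** self.depth}"
            )
        if c != 1:
            raise ValueError("only single-channel input is supported")
        if len(self.stage_widths) != self.depth + 1:
            raise ValueError(
                f"need depth+1 = {self.depth + 1} stage widths, got {len(self.stage_widths)}"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.fractal_order < 1:
            raise ValueError("fractal_order must be >= 1")


class _DoubleConv(nn.Module):
    def __init__(self, cin, width, rng, batch_norm=True):
        super().__init__()
        self.a = ConvUnit(cin, width, rng=rng, batch_norm=batch_norm)
        self.b = ConvUnit(width, width, rng=rng, batch_norm=batch_norm)

    def forward(self, x):
        return self.b(self.a(x))


class SegmentationModel(nn.Module):
    """A built architecture: an ordered layer graph with a forward pass.

    The forward pass maps an (N, 1, H, W) batch to per-pixel foreground
    probabilities in (0, 1); ``forward_logits`` exposes the pre-sigmoid
    map for numerically stable loss computation.
    """

    def __init__(self, cfg: ArchitectureConfig, init: bool = True):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed) if init else None
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)
        w = cfg.stage_widths
        d = cfg.depth
        bn = cfg.batch_norm
        fractal_backbone = cfg.arch_name in ("fractalspinet", "att_fractalspinet")

        def stage_block(cin, width):
            if fractal_backbone:
                return FractalBlock(cin, width, cfg.fractal_order, rng=rng, batch_norm=bn)
            return _DoubleConv(cin, width, rng, batch_norm=bn)

        cin = cfg.input_size[2]
        self.encoder = [stage_block(cin if i == 0 else w[i - 1], w[i]) for i in range(d)]
        self.pool = Down()
        self.bottleneck = stage_block(w[d - 1], w[d])
        self.dropout = nn.Dropout(cfg.dropout_rate, rng=self._dropout_rng)

        if cfg.arch_name == "con_fractalunet":
            self.skip_blocks = [
                FractalBlock(w[i], w[i], cfg.fractal_order, rng=rng, batch_norm=bn)
                for i in range(d)
            ]
        else:
            self.skip_blocks = []

        if cfg.arch_name == "att_fractalspinet" or cfg.attention:
            self.gates = [
                AttentionGate(w[i], w[i + 1], rng=rng) for i in range(d)
            ]
        else:
            self.gates = []

        self.ups = [Up(w[i + 1], w[i], rng=rng) for i in range(d)]
        self.decoder = [stage_block(2 * w[i], w[i]) for i in range(d)]
        self.head = nn.Conv2d(w[0], 1, 1, rng=rng)

    # -- forward ---------------------------------------------------------
    def forward_logits(self, x):
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        cfg = self.cfg
        d = cfg.depth
        skips = []
        for i, block in enumerate(self.encoder):
            x = block(x)
            if i == d - 1 and cfg.dropout_rate > 0:
                x = self.dropout(x)  # deepest encoder level
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        if cfg.dropout_rate > 0:
            x = self.dropout(x)
        for i in reversed(range(d)):
            skip = skips[i]
            if self.skip_blocks:
                skip = self.skip_blocks[i](skip)
            if self.gates:
                skip = self.gates[i](skip, x)  # gate = coarser decoder feature
            x = self.ups[i](x)
            x = ops.concat_channels([skip, x])
            x = self.decoder[i](x)
        return self.head(x)

    def forward(self, x):
        return ops.sigmoid(self.forward_logits(x))

    # -- introspection ---------------------------------------------------
    @property
    def total_parameters(self) -> int:
        return self.num_parameters()

    def layer_table(self) -> list[dict]:
        """Ordered per-layer listing: name, type, parameter shapes, count."""
        rows = []
        for name, module in self._named_modules():
            own = getattr(module, "_params", {})
            if not own:
                continue
            rows.append(
                {
                    "layer": name,
                    "type": type(module).__name__,
                    "shapes": {k: tuple(p.data.shape) for k, p in own.items()},
                    "parameters": sum(p.size for p in own.values()),
                }
            )
        return rows

    def summary(self) -> str:
        lines = [f"{'layer':<60} {'type':<14} {'params':>12}"]
        for row in self.layer_table():
            lines.append(f"{row['layer']:<60} {row['type']:<14} {row['parameters']:>12,}")
        lines.append(f"{'TOTAL':<75} {self.total_parameters:>12,}")
        return "\n".join(lines)


def _build(cfg: ArchitectureConfig, init: bool = True) -> SegmentationModel:
    return SegmentationModel(cfg, init=init)


def build_model(cfg: ArchitectureConfig, init: bool = True) -> SegmentationModel:
    """Dispatch to the right builder for ``cfg.arch_name``."""
    return _build(cfg, init=init)


def build_unet(cfg: ArchitectureConfig) -> SegmentationModel:
    if cfg.arch_name != "unet":
        raise ValueError(f"expected arch_name 'unet', got {cfg.arch_name!r}")
    return _build(cfg)


def build_fractalspinet(cfg: ArchitectureConfig) -> SegmentationModel:
    if cfg.arch_name != "fractalspinet":
        raise ValueError(f"expected arch_name 'fractalspinet', got {cfg.arch_name!r}")
    return _build(cfg)


def build_att_fractalspinet(cfg: ArchitectureConfig) -> SegmentationModel:
    if cfg.arch_name != "att_fractalspinet":
        raise ValueError(f"expected arch_name 'att_fractalspinet', got {cfg.arch_name!r}")
    return _build(cfg)


def build_con_fractalunet(cfg: ArchitectureConfig) -> SegmentationModel:
    if cfg.arch_name != "con_fractalunet":
        raise ValueError(f"expected arch_name 'con_fractalunet', got {cfg.arch_name!r}")
    return _build(cfg)


def count_parameters(model: SegmentationModel) -> int:
    """Exact count of trainable scalars in a built model."""
    return model.num_parameters()


def _base_config(arch_name: str) -> ArchitectureConfig:
    return ArchitectureConfig(
        arch_name=arch_name,
        attention=(arch_name == "att_fractalspinet"),
    )


def _count_for_bottleneck(cfg: ArchitectureConfig, w_bottleneck: int) -> int:
    widths = (*cfg.stage_widths[:-1], int(w_bottleneck))
    return _build(replace(cfg, stage_widths=widths), init=False).num_parameters()


def calibrate_capacity(
    arch_name: str,
    target_millions: float,
    base_cfg: ArchitectureConfig | None = None,
    w_min: int = 8,
    w_max: int = 8192,
) -> ArchitectureConfig:
    """Fix the free bottleneck width so the parameter count matches a target.

    Deterministic and monotone: the count grows with the bottleneck
    width, so a binary search finds the crossing of the rounding window
    [target − 0.05, target + 0.05) million, then the smallest width
    whose count rounds to ``target_millions`` is returned.
    """
    if target_millions <= 0:
        raise ValueError("target must be positive")
    cfg = base_cfg if base_cfg is not None else _base_config(arch_name)
    if cfg.arch_name != arch_name:
        raise ValueError("base_cfg.arch_name does not match arch_name")

    # the default config may already satisfy the target
    default_count = _build(cfg, init=False).num_parameters()
    if round(default_count / 1e6, 1) == round(target_millions, 1):
        return cfg

    lo_target = (target_millions - 0.05) * 1e6
    lo, hi = w_min, w_max
    if _count_for_bottleneck(cfg, hi) < lo_target or _count_for_bottleneck(cfg, lo) >= lo_target + 1e5:
        raise CalibrationError(
            f"target {target_millions}M unreachable for {arch_name} within "
            f"bottleneck widths [{w_min}, {w_max}]"
        )
    while lo < hi:  # smallest w with count >= lo_target
        mid = (lo + hi) // 2
        if _count_for_bottleneck(cfg, mid) >= lo_target:
            hi = mid
        else:
            lo = mid + 1
    nearest = []
    for w in range(lo, min(lo + 64, w_max + 1)):
        count = _count_for_bottleneck(cfg, w)
        if round(count / 1e6, 1) == round(target_millions, 1):
            widths = (*cfg.stage_widths[:-1], w)
            return replace(cfg, stage_widths=widths)
        nearest.append((w, count))
        if count >= (target_millions + 0.05) * 1e6:
            break
    raise CalibrationError(
        f"no bottleneck width rounds to {target_millions}M for {arch_name}; "
        f"nearest counts: {nearest[:3]} ... {nearest[-3:]}"
    )


def default_config(arch_name: str) -> ArchitectureConfig:
    """The released, capacity-calibrated default configuration."""
    if arch_name not in ARCH_NAMES:
        raise ValueError(f"unknown architecture {arch_name!r}")
    cfg = _base_config(arch_name)
    w5 = CALIBRATED_BOTTLENECK_WIDTHS[arch_name]
    return replace(cfg, stage_widths=(*cfg.stage_widths[:-1], w5))
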