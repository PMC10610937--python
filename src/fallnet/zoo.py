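"""Declarative 1-D architecture zoo for pre-impact fall detection.

Every network is described by a :class:`ModelSpec` — an ordered list of
:class:`BlockSpec` plus a classifier head — from which both the runnable
network (:mod:`fallnet.nn`) and closed-form parameter/memory figures derive.

Three families are covered:

* **conv_lstm** — the benchmark: three Conv1D units (64 filters, kernel 7,
  batch norm, ReLU, pool 2) feeding two 64-unit LSTM layers; 9-axis, 6-axis
  and a deeper kernel-3 variant.
* **vgg1d** — VGG16/19 transplanted to 1-D (kernel-3 convs, pool-2 stages,
  channel doubling 64→512), optionally with batch norm, LSTM layers, and a
  uniform 64-filter override.
* **resnet1d** — bottleneck residual networks: ResNet50 with filter scaling,
  and the ResNet24 derived from the VGG19 layout by replacing each pair of
  conv layers with one residual block.  Removing identity blocks (which never
  change tensor shapes) one at a time yields the lightweighting ladder
  ResNet24 → 21 → 18 → 15, and dropping one 1×1 reduce conv gives ResNet14,
  the final lightweight model ("TinyFallNet").

Residual bottlenecks use reduce → conv → expand widths with expand = 4 ×
reduce; "filters = 64" for these families means a 64-wide block output
(reduce width 16).  Convolutions use "same" padding, so only pools and
strides change the temporal length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

from .errors import ConfigError

CONV_UNIT = "conv_unit"
VGG_BLOCK = "vgg_block"
IDENTITY_BLOCK = "identity_block"
CONVOLUTIONAL_BLOCK = "convolutional_block"
LSTM_UNIT = "lstm_unit"
MAX_POOL = "max_pool"

_BLOCK_KINDS = (
    CONV_UNIT, VGG_BLOCK, IDENTITY_BLOCK, CONVOLUTIONAL_BLOCK, LSTM_UNIT, MAX_POOL,
)

FLATTEN_DENSE = "flatten_dense"
LSTM_DENSE = "lstm_dense"
GAP_DENSE = "global_avg_pool_dense"
_HEADS = (FLATTEN_DENSE, LSTM_DENSE, GAP_DENSE)


@dataclass(frozen=True)
class BlockSpec:
    """One architectural block.

    ``filters`` is an int for plain conv/LSTM blocks and a
    (reduce, conv, expand) triple for bottleneck residual blocks
    (invariant: expand = 4 × reduce).  ``slim`` marks a bottleneck whose
    1×1 reduce conv has been removed (the kernel-``k`` conv then reads the
    block input directly) — the final lightweighting step.
    """

    kind: str
    filters: int | tuple[int, int, int] = 64
    kernel: int = 3
    stride: int = 1
    with_bn: bool = True
    pool_size: int | None = None
    dropout: float = 0.0
    slim: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _BLOCK_KINDS:
            raise ConfigError(f"unknown block kind {self.kind!r}")
        if self.kind in (IDENTITY_BLOCK, CONVOLUTIONAL_BLOCK):
            if not (isinstance(self.filters, tuple) and len(self.filters) == 3):
                raise ConfigError("bottleneck blocks need a (reduce, conv, expand) triple")
            r, c, e = self.filters
            if min(r, c, e) < 1:
                raise ConfigError("filter counts must be >= 1")
            if e != 4 * r:
                raise ConfigError(f"bottleneck expand must be 4 x reduce, got {r}->{e}")
        else:
            if not isinstance(self.filters, int) or self.filters < 1:
                raise ConfigError("filters must be a positive integer")
        if self.kernel % 2 != 1:
            raise ConfigError("kernel size must be odd (same padding)")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")
        if self.slim and self.kind not in (IDENTITY_BLOCK, CONVOLUTIONAL_BLOCK):
            raise ConfigError("slim applies to bottleneck blocks only")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative architecture: blocks + head, for a (frames × channels) input."""

    family: str  # conv_lstm | vgg1d | resnet1d
    input_channels: int
    blocks: tuple[BlockSpec, ...]
    head: str
    input_frames: int = 50
    n_classes: int = 2
    dropout: float = 0.0
    head_hidden: tuple[int, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.input_channels not in (3, 6, 9):
            raise ConfigError("input_channels must be 3, 6 or 9")
        if not self.blocks:
            raise ConfigError("block list must be non-empty")
        if self.head not in _HEADS:
            raise ConfigError(f"unknown head {self.head!r}")
        if self.n_classes != 2:
            raise ConfigError("binary fall/non-fall classification only")
        if not 0 <= self.dropout < 1:
            raise ConfigError("dropout must be in [0, 1)")
        propagate_shapes(self)  # raises if any intermediate length < 1

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        blocks = []
        for b in self.blocks:
            d = {
                "kind": b.kind,
                "filters": list(b.filters) if isinstance(b.filters, tuple) else b.filters,
                "kernel": b.kernel,
                "stride": b.stride,
                "with_bn": b.with_bn,
                "pool_size": b.pool_size,
                "dropout": b.dropout,
                "slim": b.slim,
            }
            blocks.append(d)
        return {
            "name": self.name,
            "family": self.family,
            "input_channels": self.input_channels,
            "input_frames": self.input_frames,
            "head": self.head,
            "head_hidden": list(self.head_hidden),
            "n_classes": self.n_classes,
            "dropout": self.dropout,
            "blocks": blocks,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        blocks = tuple(
            BlockSpec(
                kind=b["kind"],
                filters=tuple(b["filters"]) if isinstance(b["filters"], list) else b["filters"],
                kernel=b.get("kernel", 3),
                stride=b.get("stride", 1),
                with_bn=b.get("with_bn", True),
                pool_size=b.get("pool_size"),
                dropout=b.get("dropout", 0.0),
                slim=b.get("slim", False),
            )
            for b in d["blocks"]
        )
        return cls(
            family=d["family"],
            input_channels=d["input_channels"],
            blocks=blocks,
            head=d["head"],
            input_frames=d.get("input_frames", 50),
            n_classes=d.get("n_classes", 2),
            dropout=d.get("dropout", 0.0),
            head_hidden=tuple(d.get("head_hidden", ())),
            name=d.get("name", ""),
        )


# ---------------------------------------------------------------------------
# shape propagation
# ---------------------------------------------------------------------------

def _conv_len(length: int, stride: int) -> int:
    return -(-length // stride)  # ceil: "same" padding


def _pool_len(length: int, pool: int) -> int:
    return length // pool  # valid pooling, trailing remainder dropped


def propagate_shapes(spec: ModelSpec) -> list[tuple[int, int]]:
    """(length, channels) after each block; raises if a length collapses to 0."""
    length, channels = spec.input_frames, spec.input_channels
    out = []
    for i, b in enumerate(spec.blocks):
        if b.kind in (CONV_UNIT, VGG_BLOCK):
            length = _conv_len(length, b.stride)
            channels = b.filters
            if b.pool_size:
                length = _pool_len(length, b.pool_size)
        elif b.kind == MAX_POOL:
            length = _pool_len(length, b.pool_size or 2)
        elif b.kind in (IDENTITY_BLOCK, CONVOLUTIONAL_BLOCK):
            r, c, e = b.filters
            if b.kind == IDENTITY_BLOCK:
                if channels != e or b.stride != 1:
                    raise ConfigError(
                        f"block {i}: identity block must preserve shape "
                        f"({channels} ch in, {e} out, stride {b.stride})"
                    )
            else:
                length = _conv_len(length, b.stride)
            channels = e
        elif b.kind == LSTM_UNIT:
            channels = b.filters  # sequence length unchanged
        if length < 1:
            raise ConfigError(f"block {i} collapses temporal length to {length}")
        out.append((length, channels))
    return out


# ---------------------------------------------------------------------------
# parameter counting (closed forms)
# ---------------------------------------------------------------------------

def _conv_params(c_in: int, k: int, c_out: int) -> int:
    return c_in * k * c_out + c_out


def _lstm_params(c_in: int, hidden: int) -> int:
    return 4 * ((c_in + hidden) * hidden + hidden)


def _dense_params(c_in: int, c_out: int) -> int:
    return c_in * c_out + c_out


def count_parameters(spec: ModelSpec, include_running_stats: bool = False) -> int:
    """Trainable parameter total from the layer closed forms.

    conv = C_in·k·C_out + C_out; LSTM = 4·((C_in+H)·H + H);
    dense = C_in·C_out + C_out; batch norm = 2·C trainable (scale, shift) plus
    2·C running statistics counted only when ``include_running_stats``.
    """
    bn_factor = 4 if include_running_stats else 2
    total = 0
    channels = spec.input_channels
    for b in spec.blocks:
        if b.kind in (CONV_UNIT, VGG_BLOCK):
            total += _conv_params(channels, b.kernel, b.filters)
            if b.with_bn:
                total += bn_factor * b.filters
            channels = b.filters
        elif b.kind == MAX_POOL:
            pass
        elif b.kind in (IDENTITY_BLOCK, CONVOLUTIONAL_BLOCK):
            r, c, e = b.filters
            if b.slim:
                total += _conv_params(channels, b.kernel, c)  # k-conv reads input
            else:
                total += _conv_params(channels, 1, r)  # 1x1 reduce
                total += _conv_params(r, b.kernel, c)
            total += _conv_params(c, 1, e)  # 1x1 expand
            n_bn = 2 if b.slim else 3
            total += bn_factor * ((0 if b.slim else r) + c + e)
            if b.kind == CONVOLUTIONAL_BLOCK:
                total += _conv_params(channels, 1, e)  # projection shortcut
                total += bn_factor * e
            channels = e
        elif b.kind == LSTM_UNIT:
            total += _lstm_params(channels, b.filters)
            channels = b.filters
    # classifier head
    length = propagate_shapes(spec)[-1][0]
    if spec.head == FLATTEN_DENSE:
        feat = length * channels
        for h in spec.head_hidden:
            total += _dense_params(feat, h)
            feat = h
        total += _dense_params(feat, spec.n_classes)
    elif spec.head in (GAP_DENSE, LSTM_DENSE):
        total += _dense_params(channels, spec.n_classes)
    return total


@dataclass(frozen=True)
class MemoryEstimate:
    """Parameter memory at float32: a lower bound on any saved-file size."""

    trainable_parameters: int
    bytes_per_parameter: int = 4

    @property
    def megabytes(self) -> float:
        return self.trainable_parameters * self.bytes_per_parameter / 1024**2


def estimate_memory_mb(spec: ModelSpec) -> MemoryEstimate:
    """Float32 parameter memory in MiB (excludes any container overhead)."""
    return MemoryEstimate(count_parameters(spec))


def count_conv_layers(spec: ModelSpec) -> int:
    """Main-path weighted conv layers — the number in ResNet-style names."""
    n = 0
    for b in spec.blocks:
        if b.kind in (CONV_UNIT, VGG_BLOCK):
            n += 1
        elif b.kind in (IDENTITY_BLOCK, CONVOLUTIONAL_BLOCK):
            n += 2 if b.slim else 3
    return n


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_conv_lstm(
    input_channels: int = 9,
    kernel: int = 7,
    n_conv_units: int = 3,
    filters: int = 64,
    lstm_units: int = 64,
    lstm_dropout: float = 0.5,
) -> ModelSpec:
    """The benchmark conv + LSTM model.

    ``n_conv_units`` Conv1D units (batch norm, ReLU, pool 2) followed by two
    LSTM layers with dropout and a 2-way softmax.  The kernel-3 variant uses
    one extra conv unit, mirroring the "narrower kernels, deeper stack" trade.
    """
    blocks = [
        BlockSpec(CONV_UNIT, filters=filters, kernel=kernel, pool_size=2,
                  dropout=lstm_dropout)
        for _ in range(n_conv_units)
    ]
    blocks += [
        BlockSpec(LSTM_UNIT, filters=lstm_units, kernel=1, with_bn=False,
                  dropout=lstm_dropout)
        for _ in range(2)
    ]
    suffix = f"{input_channels}axis" + ("_vgg" if kernel == 3 else "")
    return ModelSpec(
        family="conv_lstm",
        input_channels=input_channels,
        blocks=tuple(blocks),
        head=LSTM_DENSE,
        name=f"conv_lstm_{suffix}",
    )


_VGG_STAGES = {16: (2, 2, 3, 3, 3), 19: (2, 2, 4, 4, 4)}
_VGG_FILTERS = (64, 128, 256, 512, 512)


def build_vgg1d(
    depth: int = 16,
    with_bn: bool = False,
    with_lstm: bool = False,
    filters_override: int | None = None,
    input_channels: int = 6,
) -> ModelSpec:
    """VGG16/19 in 1-D: kernel-3 conv stages with pool-2 transitions.

    Channel widths double 64→512 per stage unless ``filters_override`` fixes
    every conv at one width.  ``with_lstm`` appends two 64-unit LSTM layers in
    place of the classic two-4096 dense head.
    """
    if depth not in _VGG_STAGES:
        raise ConfigError("depth must be 16 or 19")
    if filters_override is not None and filters_override < 1:
        raise ConfigError("filters_override must be >= 1")
    blocks: list[BlockSpec] = []
    for n_convs, width in zip(_VGG_STAGES[depth], _VGG_FILTERS):
        f = filters_override if filters_override is not None else width
        blocks += [BlockSpec(VGG_BLOCK, filters=f, kernel=3, with_bn=with_bn)
                   for _ in range(n_convs)]
        blocks.append(BlockSpec(MAX_POOL, filters=1, kernel=1, with_bn=False, pool_size=2))
    if with_lstm:
        blocks += [BlockSpec(LSTM_UNIT, filters=64, kernel=1, with_bn=False, dropout=0.5)
                   for _ in range(2)]
        head, hidden = LSTM_DENSE, ()
    else:
        head, hidden = FLATTEN_DENSE, (4096, 4096)
    name = f"vgg{depth}" + ("_bn" if with_bn else "") + ("_lstm" if with_lstm else "")
    if filters_override is not None:
        name += f"_f{filters_override}"
    return ModelSpec(
        family="vgg1d",
        input_channels=input_channels,
        blocks=tuple(blocks),
        head=head,
        head_hidden=hidden,
        dropout=0.5 if not with_lstm else 0.0,
        name=name,
    )


def _bottleneck(reduce: int, kind: str, kernel: int = 3, stride: int = 1) -> BlockSpec:
    return BlockSpec(kind, filters=(reduce, reduce, 4 * reduce),
                     kernel=kernel, stride=stride)


_RESNET50_STAGES = ((3, 64, 1), (4, 128, 2), (6, 256, 2), (3, 512, 2))


def build_resnet50_1d(
    filter_scale: float = 1.0,
    uniform_filters: int | None = None,
    input_channels: int = 6,
) -> ModelSpec:
    """50-layer bottleneck residual network in 1-D.

    Stem conv (64·scale filters, kernel 7, stride 2) + pool, then stages of
    (3, 4, 6, 3) bottleneck blocks with reduce widths (64, 128, 256, 512)
    scaled by ``filter_scale`` (ceil, minimum 1).  ``uniform_filters`` instead
    fixes every block's output width (reduce = width / 4).
    """
    if filter_scale <= 0:
        raise ConfigError("filter_scale must be positive")

    def scaled(f: int) -> int:
        if uniform_filters is not None:
            return max(1, uniform_filters // 4)
        return max(1, math.ceil(f * filter_scale))

    stem = scaled(64) * 4 if uniform_filters is None else uniform_filters
    blocks: list[BlockSpec] = [
        BlockSpec(CONV_UNIT, filters=stem, kernel=7, stride=2, pool_size=2)
    ]
    for n_blocks, reduce, stride in _RESNET50_STAGES:
        r = scaled(reduce)
        blocks.append(_bottleneck(r, CONVOLUTIONAL_BLOCK, stride=stride))
        blocks += [_bottleneck(r, IDENTITY_BLOCK) for _ in range(n_blocks - 1)]
    if uniform_filters is not None:
        name = f"resnet50_f{uniform_filters}"
    elif filter_scale == 1.0:
        name = "resnet50_s1"
    else:
        name = f"resnet50_s{filter_scale:g}"
    return ModelSpec(
        family="resnet1d",
        input_channels=input_channels,
        blocks=tuple(blocks),
        head=GAP_DENSE,
        name=name,
    )


def derive_resnet24_from_vgg19(
    input_channels: int = 6, block_width: int = 64
) -> ModelSpec:
    """Replace each pair of VGG19 conv layers with one residual block.

    VGG19's five stages hold (2, 2, 4, 4, 4) conv layers — an even 16, which
    pairs into 8 bottleneck blocks of 3 convs each (24 weighted conv layers).
    Each stage opens with a convolutional block whose stride-2 projection
    stands in for the VGG pool; remaining pairs become identity blocks.
    Block output width is 64 (reduce 16), with a global-average-pool head.
    """
    reduce = block_width // 4
    blocks: list[BlockSpec] = []
    for n_convs in _VGG_STAGES[19]:
        n_res = n_convs // 2
        blocks.append(_bottleneck(reduce, CONVOLUTIONAL_BLOCK, stride=2))
        blocks += [_bottleneck(reduce, IDENTITY_BLOCK) for _ in range(n_res - 1)]
    return ModelSpec(
        family="resnet1d",
        input_channels=input_channels,
        blocks=tuple(blocks),
        head=GAP_DENSE,
        name="resnet24",
    )


def lighten(spec: ModelSpec, remove: int) -> ModelSpec:
    """Delete ``remove`` identity blocks, deepest stage first.

    Identity blocks never change tensor shapes, so every downstream length is
    untouched; the parameter count strictly decreases per removal.
    """
    if remove < 0:
        raise ConfigError("remove must be >= 0")
    identity_positions = [i for i, b in enumerate(spec.blocks) if b.kind == IDENTITY_BLOCK]
    if remove > len(identity_positions):
        raise ConfigError(
            f"cannot remove {remove} identity blocks; spec has {len(identity_positions)}"
        )
    drop = set(identity_positions[len(identity_positions) - remove:])
    blocks = tuple(b for i, b in enumerate(spec.blocks) if i not in drop)
    new = replace(spec, blocks=blocks)
    return replace(new, name=f"resnet{count_conv_layers(new)}") if spec.family == "resnet1d" else new


def slim_entry_conv_block(spec: ModelSpec) -> ModelSpec:
    """Final lightweighting step: drop the entry block's 1×1 reduce conv.

    The first convolutional block reads the narrow sensor input (≤ 9
    channels), so its 1×1 reduce conv compresses nothing; removing it (the
    kernel-3 conv then reads the input directly) keeps every output shape,
    drops the weighted-layer count by exactly one, and strictly decreases
    the parameter total.
    """
    idx = min(
        (i for i, b in enumerate(spec.blocks) if b.kind == CONVOLUTIONAL_BLOCK),
        default=None,
    )
    if idx is None:
        raise ConfigError("spec has no convolutional block to slim")
    blocks = list(spec.blocks)
    blocks[idx] = replace(blocks[idx], slim=True)
    new = replace(spec, blocks=tuple(blocks))
    return replace(new, name=f"resnet{count_conv_layers(new)}") if spec.family == "resnet1d" else new


def build_tinyfallnet(input_channels: int = 6) -> ModelSpec:
    """The final lightweight model: ResNet24 minus its identity blocks, with
    the deepest block slimmed — a 14-conv-layer bottleneck residual network."""
    spec = slim_entry_conv_block(lighten(derive_resnet24_from_vgg19(input_channels), 3))
    return replace(spec, name="tinyfallnet")


# ---------------------------------------------------------------------------
# named registry
# ---------------------------------------------------------------------------

MODEL_BUILDERS: dict[str, Callable[[], ModelSpec]] = {
    "conv_lstm_9axis": lambda: build_conv_lstm(9),
    "conv_lstm_6axis": lambda: build_conv_lstm(6),
    "conv_lstm_6axis_vgg": lambda: build_conv_lstm(6, kernel=3, n_conv_units=4),
    "vgg16": lambda: build_vgg1d(16),
    "vgg16_bn": lambda: build_vgg1d(16, with_bn=True),
    "vgg16_bn_lstm": lambda: build_vgg1d(16, with_bn=True, with_lstm=True),
    "vgg16_bn_lstm_f64": lambda: build_vgg1d(16, True, True, 64),
    "vgg19_bn_lstm_f64": lambda: build_vgg1d(19, True, True, 64),
    "resnet50_s1": lambda: build_resnet50_1d(1.0),
    "resnet50_f64": lambda: build_resnet50_1d(uniform_filters=64),
    "resnet24": lambda: derive_resnet24_from_vgg19(),
    "resnet21": lambda: lighten(derive_resnet24_from_vgg19(), 1),
    "resnet18": lambda: lighten(derive_resnet24_from_vgg19(), 2),
    "resnet15": lambda: lighten(derive_resnet24_from_vgg19(), 3),
    "resnet14": lambda: build_tinyfallnet(),
    "tinyfallnet": lambda: build_tinyfallnet(),
    "tinyfallnet_acc3": lambda: replace(build_tinyfallnet(3), name="tinyfallnet_acc3"),
}


def list_models() -> list[str]:
    return sorted(MODEL_BUILDERS)


def load_spec_yaml(path) -> ModelSpec:
    """Read a serialized architecture config (as shipped under configs/)."""
    import yaml

    with open(path) as fh:
        return ModelSpec.from_dict(yaml.safe_load(fh))


def shipped_config_path(name: str):
    """Path of the bundled YAML config for a named variant."""
    from importlib import resources
    from pathlib import Path

    p = Path(resources.files("fallnet") / "configs" / f"{name}.yaml")
    if not p.exists():
        raise ConfigError(f"no shipped config for {name!r}")
    return p


def get_model_spec(name: str) -> ModelSpec:
    try:
        return MODEL_BUILDERS[name]()
    except KeyError:
        raise ConfigError(
            f"unknown model {name!r}; available: {', '.join(list_models())}"
        ) from None
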