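"""Declarative network descriptions.

A :class:`NetworkSpec` is an ordered list of ``(name, layer-spec)`` pairs that
fully determines the architecture: convolutions, SqueezeNet-style fire
modules, pooling, a flatten/dense tail (baseline variant only), global
average pooling and the softmax head.  Specs are plain dataclasses so they
serialize to JSON and support exact parameter accounting without ever
instantiating weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Union


@dataclass(frozen=True)
class ConvLayerSpec:
    """A standard 2-D convolution (stride 1 unless stated), optional ReLU.

    ``pad_mode`` "edge" replicates border pixels instead of zero-padding;
    it is used for the stem convolution so that padding commutes with the
    per-channel input standardization folded into its weights.
    """

    in_channels: int
    out_channels: int
    kernel: int
    stride: int = 1
    padding: int = 0
    has_bias: bool = True
    relu: bool = True
    pad_mode: str = "zeros"

    def __post_init__(self) -> None:
        if min(self.in_channels, self.out_channels, self.kernel, self.stride) < 1:
            raise ValueError("conv channel/kernel/stride counts must be >= 1")
        if self.padding < 0:
            raise ValueError("padding must be >= 0")
        if self.pad_mode not in ("zeros", "edge"):
            raise ValueError(f"unknown pad_mode {self.pad_mode!r}")

    @property
    def weight_count(self) -> int:
        return self.in_channels * self.out_channels * self.kernel**2

    @property
    def bias_count(self) -> int:
        return self.out_channels if self.has_bias else 0


@dataclass(frozen=True)
class FireModuleSpec:
    """Squeeze (1x1) convolution feeding parallel 1x1 and 3x3 expand branches.

    The branch outputs are concatenated channel-wise, 1x1 branch first.
    All three constituent convolutions carry biases and ReLU activations.
    """

    in_channels: int
    squeeze_channels: int
    expand1x1_channels: int
    expand3x3_channels: int

    def __post_init__(self) -> None:
        if min(self.in_channels, self.squeeze_channels,
               self.expand1x1_channels, self.expand3x3_channels) < 1:
            raise ValueError("fire module channel counts must be >= 1")

    @property
    def out_channels(self) -> int:
        return self.expand1x1_channels + self.expand3x3_channels

    @property
    def weight_count(self) -> int:
        return (self.in_channels * self.squeeze_channels
                + self.squeeze_channels * self.expand1x1_channels
                + 9 * self.squeeze_channels * self.expand3x3_channels)

    @property
    def bias_count(self) -> int:
        return self.squeeze_channels + self.out_channels


@dataclass(frozen=True)
class PoolLayerSpec:
    """Spatial pooling; ``ceil`` output sizing so 32 -> 16 -> 8 -> 4 with window 3, stride 2."""

    kind: str  # "max" | "average"
    window: int = 3
    stride: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("max", "average"):
            raise ValueError(f"unknown pool kind {self.kind!r}")
        if not self.window >= self.stride >= 1:
            raise ValueError("require window >= stride >= 1")

    weight_count = 0
    bias_count = 0


@dataclass(frozen=True)
class DenseLayerSpec:
    """Fully connected layer (baseline variant only)."""

    in_features: int
    out_features: int
    has_bias: bool = True
    relu: bool = True

    def __post_init__(self) -> None:
        if min(self.in_features, self.out_features) < 1:
            raise ValueError("dense feature counts must be >= 1")

    @property
    def weight_count(self) -> int:
        return self.in_features * self.out_features

    @property
    def bias_count(self) -> int:
        return self.out_features if self.has_bias else 0


@dataclass(frozen=True)
class FlattenSpec:
    weight_count = 0
    bias_count = 0


@dataclass(frozen=True)
class GlobalAvgPoolSpec:
    weight_count = 0
    bias_count = 0


@dataclass(frozen=True)
class SoftmaxSpec:
    weight_count = 0
    bias_count = 0


LayerSpec = Union[ConvLayerSpec, FireModuleSpec, PoolLayerSpec,
                  DenseLayerSpec, FlattenSpec, GlobalAvgPoolSpec, SoftmaxSpec]

_SPEC_KINDS = {
    "conv": ConvLayerSpec,
    "fire": FireModuleSpec,
    "pool": PoolLayerSpec,
    "dense": DenseLayerSpec,
    "flatten": FlattenSpec,
    "global_avg_pool": GlobalAvgPoolSpec,
    "softmax": SoftmaxSpec,
}
_KIND_OF = {cls: kind for kind, cls in _SPEC_KINDS.items()}


@dataclass
class NetworkSpec:
    """Ordered, named layers plus the class count and nominal input size."""

    layers: list[tuple[str, LayerSpec]]
    num_classes: int
    input_size: int = 32
    name: str = "network"

    def __post_init__(self) -> None:
        names = [n for n, _ in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")

    def layer(self, name: str) -> LayerSpec:
        for n, spec in self.layers:
            if n == name:
                return spec
        raise KeyError(name)

    def validate_channels(self) -> None:
        """Check that channel/feature counts chain consistently layer to layer."""
        channels = 3
        flat: int | None = None
        size = self.input_size
        for name, spec in self.layers:
            if isinstance(spec, ConvLayerSpec):
                if spec.in_channels != channels:
                    raise ValueError(f"{name}: expects {spec.in_channels} channels, gets {channels}")
                channels = spec.out_channels
                size = (size + 2 * spec.padding - spec.kernel) // spec.stride + 1
            elif isinstance(spec, FireModuleSpec):
                if spec.in_channels != channels:
                    raise ValueError(f"{name}: expects {spec.in_channels} channels, gets {channels}")
                channels = spec.out_channels
            elif isinstance(spec, PoolLayerSpec):
                size = -(-(size - spec.window) // spec.stride) + 1  # ceil mode
            elif isinstance(spec, FlattenSpec):
                flat = channels * size * size
            elif isinstance(spec, DenseLayerSpec):
                expected = flat if flat is not None else channels
                if spec.in_features != expected:
                    raise ValueError(f"{name}: expects {spec.in_features} features, gets {expected}")
                flat = spec.out_features
            elif isinstance(spec, GlobalAvgPoolSpec):
                flat = channels
        final = flat if flat is not None else channels
        if final != self.num_classes:
            raise ValueError(f"final output dimension {final} != num_classes {self.num_classes}")

    # -- JSON round trip (sidecar format for weight archives) -----------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "num_classes": self.num_classes,
            "input_size": self.input_size,
            "layers": [
                {"name": n, "type": _KIND_OF[type(s)], **vars(s)}
                for n, s in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        layers = []
        for entry in d["layers"]:
            entry = dict(entry)
            name = entry.pop("name")
            kind = entry.pop("type")
            layers.append((name, _SPEC_KINDS[kind](**entry)))
        return cls(layers=layers, num_classes=d["num_classes"],
                   input_size=d["input_size"], name=d.get("name", "network"))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        return cls.from_dict(json.loads(text))
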