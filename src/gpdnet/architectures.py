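"""GPDNet architectures and exact parameter accounting.

Two fixed variants are provided:

* the **fire variant** — two traditional convolutions and two SqueezeNet
  fire modules with a fully convolutional head (1x1 classifier convolution
  + global average pooling + softmax), 14,368 kernel weights at 3 classes;
* the **baseline** — the Caffe CIFAR-10-quick network (three 5x5
  convolutions and two dense layers) with its output resized to the target
  class count, 144,928 kernel weights at 3 classes.

Parameter counts are reported bias-free by default (the convention that the
published totals follow); pass ``include_bias=True`` for the full tally.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ._layers import Network
from .specs import (ConvLayerSpec, DenseLayerSpec, FireModuleSpec, FlattenSpec,
                    GlobalAvgPoolSpec, NetworkSpec, PoolLayerSpec, SoftmaxSpec)


class WeightStore:
    """Named learnable arrays (kernels ``<layer>.W``, biases ``<layer>.b``).

    This is the object that training updates in place and that the pruning
    and sensitivity procedures transform.  Keys mirror the NetworkSpec layer
    names; fire modules contribute three sub-convolutions
    (``fire2.squeeze.W`` etc.).
    """

    def __init__(self, arrays: dict[str, np.ndarray]):
        self.arrays = dict(arrays)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.arrays[key]

    def __setitem__(self, key: str, value: np.ndarray) -> None:
        self.arrays[key] = value

    def __contains__(self, key: str) -> bool:
        return key in self.arrays

    def __iter__(self):
        return iter(self.arrays)

    def keys(self):
        return self.arrays.keys()

    def items(self):
        return self.arrays.items()

    def kernel_items(self):
        """(key, array) pairs for convolution/dense kernels only."""
        return [(k, v) for k, v in self.arrays.items() if k.endswith(".W")]

    def bias_items(self):
        return [(k, v) for k, v in self.arrays.items() if k.endswith(".b")]

    def copy(self) -> "WeightStore":
        return WeightStore({k: v.copy() for k, v in self.arrays.items()})

    def equals(self, other: "WeightStore") -> bool:
        return (self.arrays.keys() == other.arrays.keys()
                and all(np.array_equal(v, other.arrays[k]) for k, v in self.arrays.items()))

    def validate(self, spec: NetworkSpec) -> None:
        """Check shapes against the spec and that every value is finite."""
        expected = _expected_shapes(spec)
        if set(expected) != set(self.arrays):
            missing = set(expected) - set(self.arrays)
            extra = set(self.arrays) - set(expected)
            raise ValueError(f"weight keys mismatch: missing {sorted(missing)}, extra {sorted(extra)}")
        for key, shape in expected.items():
            if self.arrays[key].shape != shape:
                raise ValueError(f"{key}: shape {self.arrays[key].shape} != expected {shape}")
            if not np.isfinite(self.arrays[key]).all():
                raise ValueError(f"{key}: contains non-finite values")

    # -- serialization: .npz archive + JSON sidecar describing the spec ------

    def save(self, path: str | Path, spec: NetworkSpec | None = None) -> Path:
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        np.savez(path, **self.arrays)
        if spec is not None:
            path.with_suffix(".json").write_text(spec.to_json())
        return path

    @classmethod
    def load(cls, path: str | Path) -> tuple["WeightStore", NetworkSpec | None]:
        path = Path(path)
        with np.load(path) as npz:
            store = cls({k: npz[k] for k in npz.files})
        sidecar = path.with_suffix(".json")
        spec = NetworkSpec.from_json(sidecar.read_text()) if sidecar.exists() else None
        return store, spec


def _expected_shapes(spec: NetworkSpec) -> dict[str, tuple[int, ...]]:
    shapes: dict[str, tuple[int, ...]] = {}

    def add_conv(name: str, c: ConvLayerSpec) -> None:
        shapes[f"{name}.W"] = (c.out_channels, c.in_channels, c.kernel, c.kernel)
        if c.has_bias:
            shapes[f"{name}.b"] = (c.out_channels,)

    for name, lspec in spec.layers:
        if isinstance(lspec, ConvLayerSpec):
            add_conv(name, lspec)
        elif isinstance(lspec, FireModuleSpec):
            add_conv(f"{name}.squeeze",
                     ConvLayerSpec(lspec.in_channels, lspec.squeeze_channels, 1))
            add_conv(f"{name}.expand1x1",
                     ConvLayerSpec(lspec.squeeze_channels, lspec.expand1x1_channels, 1))
            add_conv(f"{name}.expand3x3",
                     ConvLayerSpec(lspec.squeeze_channels, lspec.expand3x3_channels, 3, padding=1))
        elif isinstance(lspec, DenseLayerSpec):
            shapes[f"{name}.W"] = (lspec.out_features, lspec.in_features)
            if lspec.has_bias:
                shapes[f"{name}.b"] = (lspec.out_features,)
    return shapes


def build_gpdnet(num_classes: int, use_fire: bool) -> NetworkSpec:
    """Build the fire-module GPDNet or the CIFAR-10-quick-derived baseline.

    Fire variant: conv(3->32, 5x5, pad 2) -> maxpool(3,2) ->
    fire(32; squeeze 16; expand 32+32) -> avgpool -> fire(64; 16; 32+32) ->
    avgpool -> conv(64->num_classes, 1x1) -> global average pool -> softmax.

    Baseline: three 5x5 convolutions (3->32->32->64) with max/avg/avg pooling,
    then dense 1024->64 and dense 64->num_classes, softmax.
    """
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    if use_fire:
        layers = [
            ("conv1", ConvLayerSpec(3, 32, 5, padding=2, pad_mode="edge")),
            ("pool1", PoolLayerSpec("max")),
            ("fire2", FireModuleSpec(32, 16, 32, 32)),
            ("pool2", PoolLayerSpec("average")),
            ("fire3", FireModuleSpec(64, 16, 32, 32)),
            ("pool3", PoolLayerSpec("average")),
            ("conv4", ConvLayerSpec(64, num_classes, 1, relu=False)),
            ("gap", GlobalAvgPoolSpec()),
            ("prob", SoftmaxSpec()),
        ]
        name = "gpdnet-fire"
    else:
        layers = [
            ("conv1", ConvLayerSpec(3, 32, 5, padding=2, pad_mode="edge")),
            ("pool1", PoolLayerSpec("max")),
            ("conv2", ConvLayerSpec(32, 32, 5, padding=2)),
            ("pool2", PoolLayerSpec("average")),
            ("conv3", ConvLayerSpec(32, 64, 5, padding=2)),
            ("pool3", PoolLayerSpec("average")),
            ("flatten", FlattenSpec()),
            ("fc4", DenseLayerSpec(1024, 64)),
            ("fc5", DenseLayerSpec(64, num_classes, relu=False)),
            ("prob", SoftmaxSpec()),
        ]
        name = "gpdnet-baseline"
    spec = NetworkSpec(layers=layers, num_classes=num_classes, input_size=32, name=name)
    spec.validate_channels()
    return spec


def count_parameters(spec: NetworkSpec, include_bias: bool = False) -> int:
    """Sum of learnable array sizes; biases included only on request."""
    spec.validate_channels()
    total = sum(lspec.weight_count for _, lspec in spec.layers)
    if include_bias:
        total += sum(lspec.bias_count for _, lspec in spec.layers)
    return total


def initialize_weights(spec: NetworkSpec, seed: int,
                       dtype: np.dtype = np.float32) -> WeightStore:
    """Xavier/Glorot-uniform kernels, zero biases; deterministic per seed.

    Kernels are drawn from U(-a, a) with a = sqrt(6 / (fan_in + fan_out));
    for a convolution the fans are ``in_channels*k^2`` and
    ``out_channels*k^2``.
    """
    rng = np.random.default_rng(seed)
    arrays: dict[str, np.ndarray] = {}
    for key, shape in _expected_shapes(spec).items():
        if key.endswith(".b"):
            arrays[key] = np.zeros(shape, dtype=dtype)
        elif len(shape) == 4:  # conv kernel (F, C, k, k)
            f, c, k, _ = shape
            bound = np.sqrt(6.0 / (c * k * k + f * k * k))
            arrays[key] = rng.uniform(-bound, bound, size=shape).astype(dtype)
        else:  # dense kernel (out, in)
            out, inp = shape
            bound = np.sqrt(6.0 / (inp + out))
            arrays[key] = rng.uniform(-bound, bound, size=shape).astype(dtype)
    return WeightStore(arrays)


def _as_nchw(batch: np.ndarray) -> np.ndarray:
    batch = np.asarray(batch)
    if batch.ndim == 3:
        batch = batch[None]
    if batch.ndim != 4 or batch.shape[-1] != 3:
        raise ValueError(f"expected RGB images shaped (N, H, W, 3), got {batch.shape}")
    return np.ascontiguousarray(batch.transpose(0, 3, 1, 2))


def forward(spec: NetworkSpec, weights: WeightStore, batch: np.ndarray) -> np.ndarray:
    """Class posteriors for a batch of RGB images in [0, 1].

    Accepts (N, H, W, 3) or a single (H, W, 3) image.  The fully
    convolutional fire variant accepts any spatial size >= the nominal input
    size; the baseline's dense layers pin the input to exactly 32x32.
    """
    x = _as_nchw(batch)
    has_dense = any(isinstance(s, DenseLayerSpec) for _, s in spec.layers)
    h, w = x.shape[2], x.shape[3]
    if has_dense:
        if (h, w) != (spec.input_size, spec.input_size):
            raise ValueError(f"baseline network requires exactly "
                             f"{spec.input_size}x{spec.input_size} inputs, got {h}x{w}")
    elif min(h, w) < spec.input_size:
        raise ValueError(f"input spatial size {h}x{w} below minimum {spec.input_size}")
    weights.validate(spec)
    net = Network(spec, weights.arrays)
    return net.forward(x.astype(np.float64 if x.dtype == np.float64 else np.float32))
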