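"""Runtime layers: NumPy forward/backward kernels for the network specs.

Convolutions use an im2col lowering so the heavy lifting is a single BLAS
matmul per layer; pooling uses ``sliding_window_view``.  Every layer caches
what its backward pass needs only when run in training mode, so inference
is allocation-light.  Parameters are *views into the owning WeightStore's
arrays* — updating them in place updates the store.

Only stride-1 convolutions are implemented (both network variants use
stride 1 everywhere); pooling supports arbitrary window/stride with
ceil-mode output sizing and edge padding, matching the Caffe pooling the
CIFAR-10-quick reference net uses (32 -> 16 -> 8 -> 4 with window 3,
stride 2).  Average pooling divides by the number of valid (non-padded)
pixels in each window.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .specs import (ConvLayerSpec, DenseLayerSpec, FireModuleSpec, FlattenSpec,
                    GlobalAvgPoolSpec, NetworkSpec, PoolLayerSpec, SoftmaxSpec)


def _im2col(x: np.ndarray, kernel: int, padding: int, pad_mode: str = "zeros"):
    """Lower (N,C,H,W) to (N, OH*OW, C*k*k) patch rows (stride 1)."""
    if padding:
        pads = ((0, 0), (0, 0), (padding, padding), (padding, padding))
        x = np.pad(x, pads) if pad_mode == "zeros" else np.pad(x, pads, mode="edge")
    view = sliding_window_view(x, (kernel, kernel), axis=(2, 3))  # N,C,OH,OW,k,k
    n, c, oh, ow, _, _ = view.shape
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kernel * kernel)
    return cols, (oh, ow)


class Conv2D:
    def __init__(self, name: str, spec: ConvLayerSpec, params: dict[str, np.ndarray]):
        if spec.stride != 1:
            raise NotImplementedError("only stride-1 convolutions are supported")
        self.name, self.spec = name, spec
        self.W = params[f"{name}.W"]  # (F, C, k, k)
        self.b = params[f"{name}.b"] if spec.has_bias else None
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        s = self.spec
        if x.shape[1] != s.in_channels:
            raise ValueError(f"{self.name}: expected {s.in_channels} input channels, got {x.shape[1]}")
        cols, (oh, ow) = _im2col(x, s.kernel, s.padding, s.pad_mode)
        wmat = self.W.reshape(s.out_channels, -1)
        out = cols @ wmat.T
        if self.b is not None:
            out += self.b
        out = out.transpose(0, 2, 1).reshape(x.shape[0], s.out_channels, oh, ow)
        if s.relu:
            np.maximum(out, 0, out=out)
        if train:
            self._cache = (cols, x.shape, out if s.relu else None)
        return out

    def backward(self, dout: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        cols, xshape, activated = self._cache
        s = self.spec
        n, f, oh, ow = dout.shape
        if activated is not None:
            dout = np.where(activated > 0, dout, 0)
        dflat = dout.reshape(n, f, oh * ow).transpose(0, 2, 1)  # N, OHOW, F
        self.grads[f"{self.name}.W"] = np.tensordot(
            dflat, cols, axes=([0, 1], [0, 1])).reshape(self.W.shape)
        if self.b is not None:
            self.grads[f"{self.name}.b"] = dflat.sum(axis=(0, 1))
        self._cache = None
        if not need_dx:
            return None
        if s.pad_mode != "zeros":
            raise NotImplementedError(
                "input gradients for edge-padded convolutions are not "
                "implemented (edge padding is reserved for the stem layer)")
        # dx as a transposed convolution: full-correlate dout with the
        # spatially flipped, channel-swapped kernel (stride 1 throughout).
        k, p = s.kernel, s.padding
        wflip = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, F, k, k)
        dcols, (h, w) = _im2col(np.ascontiguousarray(dout), k, k - 1 - p)
        dx = dcols @ wflip.reshape(s.in_channels, -1).T
        return dx.transpose(0, 2, 1).reshape(n, s.in_channels, h, w)


class Fire:
    """Squeeze 1x1 conv -> parallel expand 1x1 / 3x3 convs -> channel concat."""

    def __init__(self, name: str, spec: FireModuleSpec, params: dict[str, np.ndarray]):
        self.name, self.spec = name, spec
        self.squeeze = Conv2D(f"{name}.squeeze", ConvLayerSpec(
            spec.in_channels, spec.squeeze_channels, 1), params)
        self.expand1x1 = Conv2D(f"{name}.expand1x1", ConvLayerSpec(
            spec.squeeze_channels, spec.expand1x1_channels, 1), params)
        self.expand3x3 = Conv2D(f"{name}.expand3x3", ConvLayerSpec(
            spec.squeeze_channels, spec.expand3x3_channels, 3, padding=1), params)
        self.grads = _MergedGrads((self.squeeze, self.expand1x1, self.expand3x3))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        s = self.squeeze.forward(x, train)
        return np.concatenate(
            [self.expand1x1.forward(s, train), self.expand3x3.forward(s, train)], axis=1)

    def backward(self, dout: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        c1 = self.spec.expand1x1_channels
        ds = self.expand1x1.backward(np.ascontiguousarray(dout[:, :c1]))
        ds += self.expand3x3.backward(np.ascontiguousarray(dout[:, c1:]))
        return self.squeeze.backward(ds, need_dx)


class _MergedGrads:
    """Read-only dict-like view over the gradients of several sub-layers."""

    def __init__(self, layers):
        self._layers = layers

    def items(self):
        for layer in self._layers:
            yield from layer.grads.items()


class Pool:
    def __init__(self, name: str, spec: PoolLayerSpec):
        self.name, self.spec = name, spec
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    @staticmethod
    def _geometry(h: int, w: int, window: int, stride: int):
        oh = -(-(h - window) // stride) + 1
        ow = -(-(w - window) // stride) + 1
        ph = (oh - 1) * stride + window - h
        pw = (ow - 1) * stride + window - w
        return oh, ow, ph, pw

    @staticmethod
    def _offset_slices(xp: np.ndarray, win: int, st: int, oh: int, ow: int):
        """The win*win strided slices of the padded input, each (..., OH, OW)."""
        return [xp[:, :, i:i + (oh - 1) * st + 1:st, j:j + (ow - 1) * st + 1:st]
                for i in range(win) for j in range(win)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        win, st = self.spec.window, self.spec.stride
        n, c, h, w = x.shape
        oh, ow, ph, pw = self._geometry(h, w, win, st)
        if self.spec.kind == "max":
            xp = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)),
                        constant_values=-np.inf) if ph or pw else x
            stacked = np.stack(self._offset_slices(xp, win, st, oh, ow), axis=-1)
            out = stacked.max(axis=-1)
            if train:
                self._cache = (stacked.argmax(axis=-1), None, (h, w), (ph, pw))
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw))) if ph or pw else x
            stacked = np.stack(self._offset_slices(xp, win, st, oh, ow), axis=-1)
            ones = np.pad(np.ones((1, 1, h, w), dtype=x.dtype),
                          ((0, 0), (0, 0), (0, ph), (0, pw)))
            cnt = sum(self._offset_slices(ones, win, st, oh, ow))
            out = stacked.sum(axis=-1) / cnt
            if train:
                self._cache = (None, cnt, (h, w), (ph, pw))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        win, st = self.spec.window, self.spec.stride
        n, c, oh, ow = dout.shape
        idx, cnt, (h, w), (ph, pw) = self._cache
        self._cache = None
        dxp = np.zeros((n, c, h + ph, w + pw), dtype=dout.dtype)
        slices = self._offset_slices(dxp, win, st, oh, ow)
        if self.spec.kind == "max":
            for k, target in enumerate(slices):
                target += np.where(idx == k, dout, 0)
        else:
            g = dout / cnt
            for target in slices:
                target += g
        return dxp[:, :, :h, :w]


class Flatten:
    def __init__(self, name: str, spec: FlattenSpec):
        self.name = name
        self.grads: dict[str, np.ndarray] = {}
        self._shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, name: str, spec: DenseLayerSpec, params: dict[str, np.ndarray]):
        self.name, self.spec = name, spec
        self.W = params[f"{name}.W"]  # (out, in)
        self.b = params[f"{name}.b"] if spec.has_bias else None
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.spec.in_features:
            raise ValueError(f"{self.name}: expected {self.spec.in_features} features, got {x.shape[1]}")
        out = x @ self.W.T
        if self.b is not None:
            out += self.b
        if self.spec.relu:
            np.maximum(out, 0, out=out)
        if train:
            self._cache = (x, out if self.spec.relu else None)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, activated = self._cache
        self._cache = None
        if activated is not None:
            dout = np.where(activated > 0, dout, 0)
        self.grads[f"{self.name}.W"] = dout.T @ x
        if self.b is not None:
            self.grads[f"{self.name}.b"] = dout.sum(axis=0)
        return dout @ self.W


class GlobalAvgPool:
    def __init__(self, name: str, spec: GlobalAvgPoolSpec):
        self.name = name
        self.grads: dict[str, np.ndarray] = {}
        self._shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).copy()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A spec + weight store compiled into runnable layers.

    ``forward`` returns class posteriors; ``backward`` takes the gradient of
    the loss with respect to the *logits* (the softmax input), which is how
    the fused softmax / cross-entropy gradient is applied during training.
    """

    def __init__(self, spec: NetworkSpec, params: dict[str, np.ndarray]):
        spec.validate_channels()
        self.spec = spec
        self.layers = []
        for name, lspec in spec.layers:
            if isinstance(lspec, ConvLayerSpec):
                self.layers.append(Conv2D(name, lspec, params))
            elif isinstance(lspec, FireModuleSpec):
                self.layers.append(Fire(name, lspec, params))
            elif isinstance(lspec, PoolLayerSpec):
                self.layers.append(Pool(name, lspec))
            elif isinstance(lspec, FlattenSpec):
                self.layers.append(Flatten(name, lspec))
            elif isinstance(lspec, DenseLayerSpec):
                self.layers.append(Dense(name, lspec, params))
            elif isinstance(lspec, GlobalAvgPoolSpec):
                self.layers.append(GlobalAvgPool(name, lspec))
            elif isinstance(lspec, SoftmaxSpec):
                pass  # applied functionally at the head
            else:  # pragma: no cover
                raise TypeError(f"unhandled layer spec {type(lspec)}")

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return softmax(self.logits(x, train))

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        d = dlogits
        for i, layer in enumerate(reversed(self.layers)):
            if i == len(self.layers) - 1 and isinstance(layer, (Conv2D, Fire)):
                layer.backward(d, need_dx=False)  # input gradient never consumed
            else:
                d = layer.backward(d)
            for key, g in layer.grads.items():
                grads[key] = g
        return grads
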