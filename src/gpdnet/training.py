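"""Mini-batch SGD training with the step learning-rate policy.

The loss is the summed negative log-likelihood of the true class over the
dataset (so reported epoch losses follow the sum convention); the optimizer
scales gradients by 1/N per mini-batch.  SGD uses momentum 0.9 and L2
weight decay 0.004 on kernels (the CIFAR-10-quick convention), with the
learning rate multiplied by ``gamma`` every ``step_size`` epochs.  Runs are
bit-reproducible for a fixed seed on a fixed BLAS configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._layers import Network, softmax
from .architectures import WeightStore, initialize_weights
from .datasets import LabeledImageSet
from .specs import NetworkSpec

_PROB_FLOOR = 1e-12


def _first_conv_name(spec: NetworkSpec) -> str:
    name, lspec = spec.layers[0]
    from .specs import ConvLayerSpec
    if not isinstance(lspec, ConvLayerSpec):
        raise ValueError("network must start with a convolution")
    return name


def _fold_standardization(store: WeightStore, conv: str,
                          mu: np.ndarray, sd: np.ndarray) -> None:
    """Rewrite the first conv so raw inputs x behave like (x - mu) / sd.

    W'[f,c,:,:] = W[f,c,:,:] / sd_c and b'_f = b_f - sum_cij W'[f,c,i,j] mu_c,
    an exact identity, so stored weights always operate on raw [0,1] images.
    """
    w = store[f"{conv}.W"]
    w /= sd[None, :, None, None].astype(w.dtype)
    store[f"{conv}.b"] -= (w * mu[None, :, None, None].astype(w.dtype)).sum(axis=(1, 2, 3))


def _unfold_standardization(store: WeightStore, conv: str,
                            mu: np.ndarray, sd: np.ndarray) -> None:
    """Inverse of :func:`_fold_standardization` (exact up to rounding)."""
    w = store[f"{conv}.W"]
    store[f"{conv}.b"] += (w * mu[None, :, None, None].astype(w.dtype)).sum(axis=(1, 2, 3))
    w *= sd[None, :, None, None].astype(w.dtype)


@dataclass
class TrainConfig:
    batch_size: int = 32
    base_lr: float = 0.001
    lr_policy: str = "step"
    step_size: int = 20
    gamma: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 0.004
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_policy != "step":
            raise ValueError("only the 'step' learning-rate policy is supported")

    def replace(self, **kwargs) -> "TrainConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "TrainConfig":
        """Load from YAML (or JSON — a YAML subset); keyword overrides win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class TrainResult:
    weights: WeightStore
    history: pd.DataFrame  # columns: epoch, loss, accuracy

    def save_history(self, path: str | Path) -> None:
        self.history.to_csv(path, index=False)


def cross_entropy_loss(posteriors: np.ndarray, labels: np.ndarray) -> float:
    """Summed negative log-probability of the true classes.

    Probabilities are floored at 1e-12 so a confidently wrong prediction
    yields a large finite loss rather than infinity.
    """
    posteriors = np.asarray(posteriors, dtype=np.float64)
    labels = np.asarray(labels)
    if posteriors.ndim == 1:
        posteriors = posteriors[None]
        labels = np.atleast_1d(labels)
    if labels.min() < 0 or labels.max() >= posteriors.shape[1]:
        raise ValueError(f"labels must lie in [0, {posteriors.shape[1]})")
    p = np.maximum(posteriors[np.arange(len(labels)), labels], _PROB_FLOOR)
    return float(-np.log(p).sum())


def _lr_at(config: TrainConfig, epoch: int) -> float:
    return config.base_lr * config.gamma ** (epoch // config.step_size)


def train(spec: NetworkSpec, train_set: LabeledImageSet, config: TrainConfig,
          init: WeightStore | None = None,
          test_set: LabeledImageSet | None = None) -> TrainResult:
    """SGD with momentum over shuffled mini-batches of size N.

    When ``init`` is given, optimization starts from it (pretrained-model
    semantics) — otherwise from Xavier initialization seeded by the config.
    ``test_set``, if provided, is scored every epoch; otherwise the accuracy
    column is NaN.

    Inputs are standardized per channel with training-set statistics for
    optimization conditioning; the standardization is folded exactly into
    the first convolution afterwards, so the returned weights (like any
    ``init`` passed in) operate directly on raw [0, 1] images.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    mu = train_set.images.mean(axis=(0, 1, 2)).astype(np.float64)
    sd = np.maximum(train_set.images.std(axis=(0, 1, 2)).astype(np.float64), 1e-3)
    conv0 = _first_conv_name(spec)
    if init is not None:
        init.validate(spec)
        store = init.copy()
        _unfold_standardization(store, conv0, mu, sd)
    else:
        store = initialize_weights(spec, config.seed)
    net = Network(spec, store.arrays)
    x_all = np.ascontiguousarray(
        ((train_set.images - mu) / sd).transpose(0, 3, 1, 2).astype(np.float32))
    y_all = train_set.labels
    n = len(y_all)
    num_classes = spec.num_classes
    velocity = {k: np.zeros_like(v) for k, v in store.items()}
    rng = np.random.default_rng(config.seed)
    xt = (np.ascontiguousarray(
        ((test_set.images - mu) / sd).transpose(0, 3, 1, 2).astype(np.float32))
        if test_set is not None else None)
    rows = []
    for epoch in range(config.epochs):
        lr = _lr_at(config, epoch)
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            take = perm[start:start + config.batch_size]
            xb, yb = x_all[take], y_all[take]
            logits = net.logits(xb, train=True)
            probs = softmax(logits)
            epoch_loss += cross_entropy_loss(probs, yb)
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = net.backward(dlogits.astype(logits.dtype))
            for key, w in store.items():
                g = grads[key]
                if config.weight_decay and key.endswith(".W"):
                    g = g + config.weight_decay * w
                v = velocity[key]
                v *= config.momentum
                v -= lr * g
                w += v
        if xt is not None:
            pred = np.concatenate([net.logits(xt[s:s + 256]).argmax(axis=1)
                                   for s in range(0, len(xt), 256)])
            acc = float((pred == test_set.labels).mean())
        else:
            acc = float("nan")
        rows.append({"epoch": epoch, "loss": epoch_loss, "accuracy": acc})
    _fold_standardization(store, conv0, mu, sd)
    return TrainResult(weights=store, history=pd.DataFrame(rows))


def evaluate_accuracy(spec: NetworkSpec, weights: WeightStore,
                      test_set: LabeledImageSet, batch_size: int = 256) -> float:
    """Top-1 accuracy; argmax ties resolve to the lowest class index."""
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    net = Network(spec, weights.arrays)
    x_all = np.ascontiguousarray(
        test_set.images.transpose(0, 3, 1, 2).astype(np.float32))
    correct = 0
    for start in range(0, len(x_all), batch_size):
        logits = net.logits(x_all[start:start + batch_size])
        correct += int((logits.argmax(axis=1)
                        == test_set.labels[start:start + batch_size]).sum())
    return correct / len(test_set)
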