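"""Weight-magnitude sensitivity analysis.

Kernel weights are histogrammed by absolute value into ten uneven
half-open sub-ranges (uneven because trained weights concentrate near
zero), then each range is zeroed *independently* — starting from the intact
model every time — and test accuracy of the ablated model is re-measured.
The resulting count/accuracy profile shows how much each magnitude range
contributes: large-magnitude weights are few but ablating them is far more
damaging than ablating the many near-zero weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architectures import WeightStore
from .datasets import LabeledImageSet
from .specs import NetworkSpec
from .training import evaluate_accuracy

logger = logging.getLogger(__name__)

DEFAULT_EDGES = (0.0, 0.001, 0.005, 0.01, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, np.inf)


@dataclass(frozen=True)
class MagnitudeBins:
    """Half-open magnitude intervals [e_i, e_{i+1}) covering [0, inf)."""

    edges: tuple[float, ...] = DEFAULT_EDGES

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or e[0] != 0 or not np.isinf(e[-1]):
            raise ValueError("edges must start at 0 and end at infinity")
        if not (np.diff(e) > 0).all():
            raise ValueError("edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def intervals(self) -> list[tuple[float, float]]:
        return list(zip(self.edges[:-1], self.edges[1:]))

    def labels(self) -> list[str]:
        return [f"[{lo:g},{'inf' if np.isinf(hi) else f'{hi:g}'})"
                for lo, hi in self.intervals()]


@dataclass
class SensitivityReport:
    bins: MagnitudeBins
    counts: np.ndarray          # weights per bin
    accuracies: np.ndarray      # post-ablation accuracy per bin
    baseline_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": self.bins.labels(),
            "lo": [lo for lo, _ in self.bins.intervals()],
            "hi": [hi for _, hi in self.bins.intervals()],
            "count": self.counts,
            "accuracy": self.accuracies,
            "baseline_accuracy": self.baseline_accuracy,
            "drop": self.baseline_accuracy - self.accuracies,
        })


def _all_kernel_magnitudes(weights: WeightStore) -> np.ndarray:
    return np.abs(np.concatenate(
        [arr.ravel() for _, arr in weights.kernel_items()]))


def bin_weight_magnitudes(weights: WeightStore,
                          bins: MagnitudeBins | None = None) -> np.ndarray:
    """Per-bin counts of kernel weights by |w|; counts sum to the kernel total."""
    bins = bins or MagnitudeBins()
    mags = _all_kernel_magnitudes(weights)
    if (mags > 1).any():
        logger.warning("%d kernel weights exceed magnitude 1", int((mags > 1).sum()))
    counts, _ = np.histogram(mags, bins=np.asarray(bins.edges))
    return counts


def ablate_magnitude_range(weights: WeightStore, lo: float,
                           hi: float) -> WeightStore:
    """Copy of the store with every kernel weight lo <= |w| < hi set to zero."""
    if not 0 <= lo < hi:
        raise ValueError("require 0 <= lo < hi")
    out = weights.copy()
    for _, arr in out.kernel_items():
        mags = np.abs(arr)
        arr[(lo <= mags) & (mags < hi)] = 0
    return out


def sensitivity_curve(spec: NetworkSpec, weights: WeightStore,
                      test_set: LabeledImageSet,
                      bins: MagnitudeBins | None = None) -> SensitivityReport:
    """Ablate each magnitude bin independently and score the ablated model."""
    bins = bins or MagnitudeBins()
    counts = bin_weight_magnitudes(weights, bins)
    baseline = evaluate_accuracy(spec, weights, test_set)
    accuracies = np.empty(bins.n_bins)
    for i, (lo, hi) in enumerate(bins.intervals()):
        if counts[i] == 0:
            accuracies[i] = baseline  # zero-member ablation is the identity
            continue
        ablated = ablate_magnitude_range(weights, lo, hi)
        accuracies[i] = evaluate_accuracy(spec, ablated, test_set)
    return SensitivityReport(bins, counts, accuracies, baseline)


def plot_sensitivity(report: SensitivityReport, path) -> None:
    """Two-panel figure: per-bin weight counts (bars) and post-ablation
    accuracy (line), sharing the bin axis."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_counts, ax_acc) = plt.subplots(
        2, 1, figsize=(8, 6), sharex=True,
        gridspec_kw={"height_ratios": [2, 1]})
    x = np.arange(report.bins.n_bins)
    ax_counts.bar(x, report.counts, color="#6a3d9a")
    ax_counts.set_ylabel("weights in bin")
    ax_counts.set_yscale("log")
    ax_acc.plot(x, report.accuracies, "o-", color="#33a02c", label="ablated")
    ax_acc.axhline(report.baseline_accuracy, ls="--", color="gray", label="baseline")
    ax_acc.set_ylabel("test accuracy")
    ax_acc.set_xlabel("|w| magnitude bin")
    ax_acc.set_xticks(x, report.bins.labels(), rotation=45, ha="right")
    ax_acc.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
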