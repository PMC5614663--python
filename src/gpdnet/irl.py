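"""Iterative reinforced learning (IRL): prune-small, then retrain, repeated.

Each iteration sets every kernel weight with |w| <= threshold to exactly
zero and retrains with the modified model as the pretrained start.  Zeroed
weights are free to relearn — no sparsity mask is maintained, which is the
deliberate difference from dense-sparse-dense training's masked sparse
stage.  Retraining reuses the full training budget with a per-iteration
derived seed (base seed + iteration) so runs are reproducible but data
order differs across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architectures import WeightStore
from .datasets import LabeledImageSet
from .specs import NetworkSpec
from .training import TrainConfig, evaluate_accuracy, train


@dataclass
class IRLConfig:
    threshold: float = 0.001
    iterations: int = 1
    apply_to_biases: bool = False

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class IRLRecord:
    iteration: int          # 0 = the scratch training
    zeroed: int             # weights newly zeroed before this iteration's training
    accuracy: float
    weights: WeightStore    # checkpoint after this iteration's training


@dataclass
class IRLTrace:
    records: list[IRLRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def final_weights(self) -> WeightStore:
        return self.records[-1].weights

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"iteration": r.iteration, "zeroed": r.zeroed,
                              "accuracy": r.accuracy} for r in self.records])


def zero_small_weights(weights: WeightStore, threshold: float,
                       apply_to_biases: bool = False) -> tuple[WeightStore, int]:
    """Zero every weight with |w| <= threshold (inclusive); count new zeros.

    Returns a modified copy — weights above the cutoff are bit-identical to
    the input.  Biases are untouched unless ``apply_to_biases``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = weights.copy()
    zeroed = 0
    targets = out.items() if apply_to_biases else out.kernel_items()
    for _, arr in targets:
        mask = np.abs(arr) <= threshold
        zeroed += int((mask & (arr != 0)).sum())
        arr[mask] = 0
    return out, zeroed


def run_irl(spec: NetworkSpec, train_set: LabeledImageSet,
            test_set: LabeledImageSet, train_config: TrainConfig,
            irl_config: IRLConfig,
            scratch: WeightStore | None = None) -> IRLTrace:
    """Scratch training (iteration 0) followed by prune-and-retrain rounds.

    ``scratch`` lets a caller reuse one shared scratch-trained model across
    several IRL runs (as the threshold sweep does); when omitted, iteration
    0 trains from Xavier initialization.
    """
    trace = IRLTrace()
    if scratch is None:
        scratch = train(spec, train_set, train_config).weights
    trace.records.append(IRLRecord(
        0, 0, evaluate_accuracy(spec, scratch, test_set), scratch))
    current = scratch
    for k in range(1, irl_config.iterations + 1):
        pruned, zeroed = zero_small_weights(
            current, irl_config.threshold, irl_config.apply_to_biases)
        result = train(spec, train_set,
                       train_config.replace(seed=train_config.seed + k),
                       init=pruned)
        current = result.weights
        trace.records.append(IRLRecord(
            k, zeroed, evaluate_accuracy(spec, current, test_set), current))
    return trace


def sweep_irl(spec: NetworkSpec, train_set: LabeledImageSet,
              test_set: LabeledImageSet, train_config: TrainConfig,
              thresholds: list[float], iterations: int) -> pd.DataFrame:
    """Accuracy by (iteration, threshold): one IRL run per threshold.

    All thresholds share a single scratch-trained model, so the iteration-0
    row is constant across columns.  Returns a DataFrame indexed by
    iteration 0..K with one column per threshold.
    """
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if len(set(thresholds)) != len(thresholds):
        raise ValueError("duplicate thresholds")
    scratch = train(spec, train_set, train_config).weights
    columns = {}
    for t in thresholds:
        trace = run_irl(spec, train_set, test_set, train_config,
                        IRLConfig(threshold=t, iterations=iterations),
                        scratch=scratch)
        columns[t] = trace.to_frame().set_index("iteration")["accuracy"]
    table = pd.DataFrame(columns)
    table.index.name = "iteration"
    table.columns.name = "threshold"
    return table
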