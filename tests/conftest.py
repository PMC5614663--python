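"""Shared fixtures: tiny specs, small synthetic splits, and the medium-preset
IRL study (3 seeds) reused by the fine-tuning and sensitivity checks."""

from __future__ import annotations

import numpy as np
import pytest

from gpdnet import (IRLConfig, SynthConfig, TrainConfig, build_gpdnet,
                    generate_synthetic_gpd, run_irl, split_train_test, train)

# Study conditions for the prune-and-retrain experiments: medium-difficulty
# synthetic data with a reduced problem size (200 images/class, 15-epoch
# budget) so the full 3-seed, 6-iteration study runs on one CPU in minutes.
IRL_N_PER_CLASS = 200
IRL_PER_CLASS_TEST = 100
IRL_EPOCHS = 15
IRL_ITERATIONS = 6
IRL_THRESHOLD = 0.001
IRL_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def fire_spec():
    return build_gpdnet(3, True)


@pytest.fixture(scope="session")
def baseline_spec():
    return build_gpdnet(3, False)


@pytest.fixture(scope="session")
def small_easy_split():
    """Easy-preset split small enough for quick training smoke tests."""
    dataset = generate_synthetic_gpd(
        SynthConfig(n_per_class=120, seed=3, difficulty="easy"))
    return split_train_test(dataset, per_class_test=30, seed=0)


@pytest.fixture(scope="session")
def tiny_split():
    """Very small medium-preset split for contract-level training tests."""
    dataset = generate_synthetic_gpd(
        SynthConfig(n_per_class=40, seed=7, difficulty="medium"))
    return split_train_test(dataset, per_class_test=10, seed=1)


@pytest.fixture(scope="session")
def easy_trained(fire_spec):
    """Fire variant trained 10 epochs on the easy preset (the separability
    calibration run); returns (weights, history, test_set)."""
    dataset = generate_synthetic_gpd(
        SynthConfig(n_per_class=300, seed=1, difficulty="easy"))
    train_set, test_set = split_train_test(dataset, per_class_test=100, seed=1)
    result = train(fire_spec, train_set, TrainConfig(epochs=10, seed=1),
                   test_set=test_set)
    return result.weights, result.history, test_set


def run_medium_irl(seed: int):
    """One full IRL run under the study conditions; returns (trace, test_set)."""
    spec = build_gpdnet(3, True)
    dataset = generate_synthetic_gpd(
        SynthConfig(n_per_class=IRL_N_PER_CLASS, seed=seed, difficulty="medium"))
    train_set, test_set = split_train_test(
        dataset, per_class_test=IRL_PER_CLASS_TEST, seed=seed)
    trace = run_irl(spec, train_set, test_set,
                    TrainConfig(epochs=IRL_EPOCHS, seed=seed),
                    IRLConfig(threshold=IRL_THRESHOLD, iterations=IRL_ITERATIONS))
    return trace, test_set


@pytest.fixture(scope="session")
def medium_irl_runs():
    """The 3-seed medium-preset IRL study (the expensive shared fixture)."""
    return [run_medium_irl(seed) for seed in IRL_SEEDS]
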