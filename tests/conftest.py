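import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from afuq.network import NetworkConfig, build
from afuq.synthetic import generate_cohort
from afuq.training import LabeledDataset, TrainConfig, train


def tiny_network_config(**overrides) -> NetworkConfig:
    """4-block miniature of the architecture for fast unit tests."""
    defaults = dict(
        n_blocks=4,
        channels_per_block=(6, 6, 6, 6),
        dilation_schedule=(1, 2, 4, 8),
        pool_blocks=frozenset({2, 3}),
        dropout_rate=0.3,
    )
    defaults.update(overrides)
    return NetworkConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """Balanced clean-ish cohort used by several unit tests."""
    return generate_cohort(20, 6, {"sinus": 0.6, "af": 0.4},
                           noise_rate=0.1, seed=101)


@pytest.fixture(scope="session")
def tiny_trained_model(small_cohort):
    """A quickly trained miniature classifier that separates the classes
    reasonably; shared by uncertainty and weak-label tests."""
    model = build(tiny_network_config(), seed=3)
    data = LabeledDataset.from_segments(small_cohort)
    cfg = TrainConfig(batch_size=32, max_epochs=12, patience=12,
                      val_fraction=0.2, monitor="train", seed=3)
    model, _ = train(model, data, cfg)
    return model


@pytest.fixture(scope="session")
def experiment_runs():
    """Three desk-scale end-to-end experiment replicates (distinct master
    seeds); the basis for the directional-replication and separation checks."""
    from afuq.pipeline import ExperimentConfig, run_experiment

    runs = []
    for seed in (0, 1, 2):
        cfg = ExperimentConfig(modes=("none", "epistemic"), n_passes=10,
                               seed=seed)
        runs.append(run_experiment(cfg))
    return runs


@pytest.fixture(scope="session")
def noise_recovery_runs():
    """Three replicates of training with label cleaning on the separable
    synthetic task (n=2000) with 20% symmetric label flips."""
    from afuq import confident_learning as cl
    from afuq.synthetic import LabelNoiseModel, corrupt_labels

    results = []
    for seed in (11, 12, 13):
        segments = generate_cohort(80, 25, {"sinus": 0.7, "af": 0.3},
                                   noise_rate=0.0, seed=seed)
        true_labels = np.array([s.label for s in segments])
        observed, flipped = corrupt_labels(
            true_labels, LabelNoiseModel.symmetric(0.20, seed=seed + 100))
        data = LabeledDataset.from_segments(segments, labels=observed)
        model = build(NetworkConfig(), seed=seed)
        cfg = TrainConfig(max_epochs=4, val_fraction=0.1, monitor="train",
                          seed=seed)
        hook = cl.cleaning_hook(cl.CleaningSchedule(interval=3))
        model, history = train(model, data, cfg, cleaner=hook)
        removed = np.flatnonzero(~data.active_mask)
        results.append({
            "flipped": flipped,
            "removed": removed,
            "n": len(segments),
            "history": history,
            "model": model,
            "data": data,
        })
    return results
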