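import numpy as np
import pytest
from hypothesis import settings

import ecnn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_config() -> ecnn.TrainConfig:
    """Small, fast training configuration for structural tests."""
    return ecnn.TrainConfig(
        hidden_sizes=(8, 4),
        epochs=12,
        n_snapshots=3,
        batch_size=16,
        alpha0=0.05,
        reg_lambda=0.01,
        seed=7,
        cv_k=3,
        cv_repeats=1,
    )


@pytest.fixture(scope="session")
def small_cohort() -> ecnn.EventMatrix:
    """120 x 30 planted-signal cohort, cheap to train on."""
    return ecnn.generate_cohort(
        ecnn.SimConfig(
            n_patients=120, n_features=30, n_informative=4,
            sparsity=0.7, signal_strength=4.0, interaction_fraction=0.0,
            count_dispersion=1.5, seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_ensemble(small_cohort, tiny_config) -> ecnn.SnapshotEnsemble:
    X, _ = ecnn.normalize(small_cohort)
    return ecnn.train_snapshots(X, small_cohort.labels, tiny_config)
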