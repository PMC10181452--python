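"""Shared fixtures: small synthetic subjects and scaled-down experiment
configurations reused across the test modules."""

import numpy as np
import pytest

from synspace import CohortConfig
from synspace.experiment import ExperimentConfig, build_subject_artifacts
from synspace.synthetic_motion import generate_cohort


def small_experiment_config(**overrides) -> ExperimentConfig:
    """A fast experiment configuration for unit-scale runs: short
    movements, few repetitions, a small network trained briefly."""
    cohort_kwargs = dict(
        n_subjects=1,
        n_train_trials_per_target=3,
        n_validation_movements=8,
        movement_duration=1.0,
        rest_duration=0.7,
        seed=7,
    )
    cohort_kwargs.update(overrides.pop("cohort", {}))
    cohort = CohortConfig(**cohort_kwargs)
    defaults = dict(
        hidden_units=16,
        epochs=12,
        early_stopping_patience=12,
        learning_rate=0.01,
        master_seed=7,
    )
    defaults.update(overrides)
    return ExperimentConfig(cohort=cohort, **defaults)


@pytest.fixture(scope="session")
def noise_free_subject():
    """One noise-free two-latent subject with full pipeline artifacts."""
    config = small_experiment_config(
        cohort=dict(noise_sd=0.0, n_train_trials_per_target=5, movement_duration=1.2)
    )
    truth, training, validation = generate_cohort(config.cohort)[0]
    artifacts = build_subject_artifacts(truth, training, validation, config)
    return config, truth, training, validation, artifacts


@pytest.fixture(scope="session")
def default_training_session():
    """A training session generated under the default study design
    (8 targets x 15 repetitions at 120 Hz)."""
    config = CohortConfig(n_subjects=1, seed=3)
    truth, training, validation = generate_cohort(config)[0]
    return config, truth, training, validation


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
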