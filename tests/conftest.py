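"""Shared fixtures: small simulated datasets and a quickly trained surrogate.

Everything is generated programmatically at session scope so expensive
artifacts (simulations, a trained model) are built once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from pvlnode import cardio0d
from pvlnode.lnode import SurrogateConfig
from pvlnode.training import TrainingConfig, train


@pytest.fixture(scope="session")
def full_space():
    return cardio0d.default_space()


@pytest.fixture(scope="session")
def reduced_space():
    return cardio0d.reduced_space()


@pytest.fixture(scope="session")
def ref_theta(full_space):
    return full_space.reference_vector()


@pytest.fixture(scope="session")
def ref_beats(ref_theta):
    """Ten beats at the reference point (limit-cycle checks need >= 8)."""
    return cardio0d.simulate(ref_theta, n_beats=10)


@pytest.fixture(scope="session")
def small_dataset(reduced_space):
    """A 10-record dataset over the 8 varied analogs (3 beats each)."""
    return cardio0d.generate_dataset(reduced_space, n=10, n_beats=3, seed=11)


@pytest.fixture(scope="session")
def tiny_surrogate(small_dataset):
    """A cheaply trained surrogate for API-level tests.

    The fit is rough (few optimization steps) but the object is a genuine
    product of the training pipeline, so downstream modules see realistic
    scalers, weights and metadata.
    """
    train_ds = small_dataset.subset(range(8))
    cfg = TrainingConfig(epochs=40, pretrain_epochs=400, lbfgs_polish=0,
                         seed=1, time_stride=4)
    model, report = train(train_ds, small_dataset.subset([8, 9]), cfg,
                          SurrogateConfig())
    model.meta["z0_mean"] = train_ds.trace_array()[:, 0, :].mean(axis=0)
    return model, report, train_ds
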