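"""Shared fixtures: the expensive trained models are session-scoped."""

import numpy as np
import pytest

from ecgvae import simulator as sim
from ecgvae.cvae import CVAE, ConditionSchema, ModelConfig
from ecgvae.workflow import (
    conditioning_fidelity_study,
    risk_recovery_study,
)

POSE_BLOCKS = ("heart_position", "heart_orientation")


@pytest.fixture(scope="session")
def recovery_result():
    """Joint cVAE + risk training on the default ECG-linked-hazard cohort."""
    return risk_recovery_study()


@pytest.fixture(scope="session")
def null_recovery_result():
    """Same pipeline on a cohort whose hazard ignores every feature."""
    return risk_recovery_study(
        seed=11, betas={"r_amp_ii": 0.0, "age": 0.0, "sex": 0.0}
    )


@pytest.fixture(scope="session")
def fidelity_result():
    """Pose-conditioned generation sweep vs the simulator's forward model."""
    return conditioning_fidelity_study()


@pytest.fixture(scope="session")
def pose_cvae_bundle():
    """A pose-conditioned cVAE trained on a smaller cohort, with held-out data.

    Used by the conditioning-effectiveness and posterior-collapse property
    tests, which need the model itself rather than summary numbers.
    """
    cohort = sim.simulate_cohort(1300, seed=17)
    conds = cohort.conditions(POSE_BLOCKS)
    n_train = 1000
    model = CVAE(ConditionSchema(POSE_BLOCKS), ModelConfig(epochs=15, seed=5))
    model.fit(cohort.beats[:n_train], conds[:n_train])
    return {
        "model": model,
        "beats_held": cohort.beats[n_train:],
        "conds_held": conds[n_train:],
    }
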