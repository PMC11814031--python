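"""Shared fixtures: small deterministic phantom cohorts and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from lcnm.synthetic_data import CognitionModel, PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def clean_config() -> PhantomConfig:
    """Noiseless, gain-free, no between-subject spread: truth is exact."""
    return PhantomConfig(
        noise_sd=0.0,
        slice_gain_range=(1.0, 1.0),
        contrast_subject_sd=0.0,
        n_per_group={"HC": 2, "MSA": 2, "PD": 2},
        cognition_model=CognitionModel(rostral_coef=0.0),
        seed=123,
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_config):
    return generate_cohort(clean_config)


@pytest.fixture(scope="session")
def noisy_config() -> PhantomConfig:
    """Default noise and slice gains, fixed group contrasts (no subject spread)."""
    return PhantomConfig(
        contrast_subject_sd=0.0,
        n_per_group={"HC": 3, "MSA": 3, "PD": 3},
        cognition_model=CognitionModel(rostral_coef=0.0),
        seed=456,
    )


@pytest.fixture(scope="session")
def noisy_cohort(noisy_config):
    return generate_cohort(noisy_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
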