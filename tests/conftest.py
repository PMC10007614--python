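"""Shared fixtures: small simulated datasets and processed samples."""

import numpy as np
import pytest

from sorsnet import (PreprocessConfig, SimulationConfig,
                     generate_dataset, generate_reference_spectra)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Two shrimp at full instrument geometry — cheap but realistic."""
    return SimulationConfig(n_shrimp=2, seed=7)


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """Noiseless, artifact-free configuration for closed-form checks."""
    return SimulationConfig(
        n_shrimp=1, seed=3, noise_sd=0.0, cosmic_ray_rate=0.0,
        anomaly_rate=0.0, gain_jitter_sd=0.0, shell_scale_jitter_sd=0.0,
        bio_day_jitter_sd=0.0)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def meat_reference(small_config):
    meat, _ = generate_reference_spectra(small_config)
    return meat


@pytest.fixture(scope="session")
def preprocess_config() -> PreprocessConfig:
    return PreprocessConfig()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
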