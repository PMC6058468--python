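import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from cicdls import (
    GroundTruthMixture,
    InstrumentConfig,
    NoiseModel,
    human_plasma_mixture,
    simulate_trace,
)

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config():
    return InstrumentConfig()


@pytest.fixture(scope="session")
def mono_trace():
    """Noise-free single-exponential trace of a 121 nm sample."""
    return simulate_trace(GroundTruthMixture(((121.0, 100.0),)))


@pytest.fixture(scope="session")
def premeal_mixture():
    """Pre-meal human plasma: 3.5 nm background + 5.9% food CICs."""
    return human_plasma_mixture(5.9, 121.0)


@pytest.fixture(scope="session")
def premeal_trace(premeal_mixture):
    return simulate_trace(premeal_mixture)


def make_noisy_trace(mixture, sigma0, seed):
    return simulate_trace(mixture, noise=NoiseModel(sigma0=sigma0, seed=seed))
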