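import numpy as np
import pytest

from capnopred import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort300():
    """Medium synthetic cohort with default (noisy) study conditions."""
    return generate_cohort(CohortConfig(n=300, seed=7))


@pytest.fixture(scope="session")
def cohort_noiseless():
    """Small cohort with noise-free traces for exact round-trip checks."""
    return generate_cohort(CohortConfig(n=12, seed=3, noise_sigma=0.0))


@pytest.fixture(scope="session")
def cohort_tiny():
    """Very small noisy cohort for interface-level tests."""
    return generate_cohort(CohortConfig(n=40, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
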