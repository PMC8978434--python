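import numpy as np
import pytest

from temsim.dgp import DGPCoefficients, generate_cohort


@pytest.fixture(scope="session")
def default_coeffs() -> DGPCoefficients:
    return DGPCoefficients()


@pytest.fixture(scope="session")
def interaction_coeffs() -> DGPCoefficients:
    """Largest moderator-confounder interaction scenario."""
    return DGPCoefficients(alpha_mx1=0.2, beta_mx1=0.4)


@pytest.fixture(scope="session")
def cohort(interaction_coeffs):
    return generate_cohort(interaction_coeffs, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
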