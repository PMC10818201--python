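import numpy as np
import pytest

from morphgreml.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort reused across read-only tests."""
    return simulate_cohort(SimulationConfig(
        n_subjects=150, n_snps=400, n_features=200, seed=7), with_core=True)


def random_pd_matrix(rng, n, jitter=0.5):
    """A well-conditioned random positive-definite matrix."""
    A = rng.standard_normal((n, 2 * n))
    return A @ A.T / (2 * n) + jitter * np.eye(n)
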