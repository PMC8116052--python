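import numpy as np
import pytest

from optimmune import AffinityKernel, DeliberationCost, get_table


@pytest.fixture(scope="session")
def gaussian_kernel() -> AffinityKernel:
    """The reference parameter set: Gaussian profiles, alpha_max=4."""
    return AffinityKernel(alpha=4.0, theta=2.0, alpha_max=4.0, e_max=1.0)


@pytest.fixture(scope="session")
def linear_cost() -> DeliberationCost:
    return DeliberationCost(form="linear", omega0_hat=0.1)


@pytest.fixture(scope="session")
def no_cost() -> DeliberationCost:
    return DeliberationCost(form="none")


@pytest.fixture(scope="session")
def gaussian_table():
    """Shared dissipation table (built once per session)."""
    return get_table(2.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
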