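import numpy as np
import pytest
from hypothesis import settings

import neqsense as nq

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def perfect_prior():
    """Perfectly correlated standard-normal prior at default resolution."""
    return nq.perfectly_correlated_prior()


@pytest.fixture(scope="session")
def perfect_prior_coarse():
    """Cheaper prior for tests that loop over many parameter draws."""
    return nq.perfectly_correlated_prior(101)


@pytest.fixture(scope="session")
def small_signal_prior():
    """A handful of signal values; for pointwise (per-h) joint-chain checks."""
    h = np.linspace(-1.5, 1.5, 5)
    return nq.custom_prior(np.column_stack([h, h]), np.full(h.size, 1 / h.size))


def random_params(rng, beta_max=10.0, J_max=5.0, t_max=8.0):
    return nq.SensorParams(
        beta=rng.uniform(0.0, beta_max),
        J=rng.uniform(-J_max, J_max),
        t=rng.uniform(-t_max, t_max),
    )
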