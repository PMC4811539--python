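import numpy as np
import pytest

from burstfit import ModelParams


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_valid_theta(rng: np.random.Generator) -> ModelParams:
    """A random parameter set in the physically sensible region: bursty
    exponent in (0.5, 3), lambda_inf a couple of orders below lambda0."""
    lam0 = 10.0 ** rng.uniform(-3, -0.5)
    t0 = 10.0 ** rng.uniform(0.5, 3)
    alpha = rng.uniform(0.5, 3.0)
    laminf = lam0 * 10.0 ** rng.uniform(-4, -1.5)
    return ModelParams(lambda0=lam0, t0=t0, alpha=alpha, lambda_inf=laminf)


@pytest.fixture(scope="session")
def theta_grid(rng):
    """20 random valid parameter sets shared by the property suites."""
    return [random_valid_theta(rng) for _ in range(20)]
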