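import numpy as np
import pytest

from latentid import (
    InterventionRegime,
    LCAParameters,
    cell_probabilities,
)

#: the running worked example: a majority latent class with strong item
#: loadings and a treatment that halves the prevalence
EXAMPLE = LCAParameters(delta=0.6, phi0=0.2, phi1=0.7, lambda0=0.1, lambda1=0.8)
EXAMPLE_REGIME = InterventionRegime(delta_prime=0.3, direction="reduced")


@pytest.fixture
def example_params() -> LCAParameters:
    return EXAMPLE


@pytest.fixture
def example_regime() -> InterventionRegime:
    return EXAMPLE_REGIME


@pytest.fixture
def exact_pre():
    """Exact pre-intervention cells of the worked example:
    (00, 01, 10, 11) = (0.324, 0.176, 0.156, 0.344)."""
    return cell_probabilities(EXAMPLE, EXAMPLE.delta)


@pytest.fixture
def exact_post():
    """Exact post-intervention cells: (0.522, 0.128, 0.168, 0.182)."""
    return cell_probabilities(EXAMPLE, EXAMPLE_REGIME.delta_prime)


def random_interior_params(rng: np.random.Generator, margin: float = 0.05):
    """A generator tuple with interior coordinates and the separation margins
    |phi1 - phi0| >= margin, |lambda1 - lambda0| >= margin."""
    while True:
        d, p0, p1, l0, l1 = rng.uniform(0.05, 0.95, size=5)
        if abs(p1 - p0) >= margin and abs(l1 - l0) >= margin:
            return LCAParameters(d, p0, p1, l0, l1)


def random_delta_prime(rng: np.random.Generator, delta: float, margin: float = 0.05):
    while True:
        dp = rng.uniform(0.05, 0.95)
        if abs(dp - delta) >= margin:
            return dp
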