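import numpy as np
import pytest

from triadmix.model import TraitSubset, VariantContext
from triadmix.params import MixtureParams


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_params():
    """Moderate, well-conditioned parameter set used across model tests."""
    return MixtureParams(
        pi=np.array([0.02, 0.03, 0.01, 0.015, 0.005, 0.01, 0.02]),
        sigma=np.array([0.12, 0.10, 0.15]),
        sigma0=np.array([1.0, 1.05, 0.95]),
        rho=np.array([0.3, -0.2, 0.1]),
        rho0=np.array([0.05, 0.0, -0.1]),
    )


@pytest.fixture
def simple_ctx():
    return VariantContext(nbr_weights=np.array([0.4, 0.25, 0.1]),
                          n=np.array([200.0, 300.0, 150.0]))


def random_valid_params(rng, max_rho=0.6):
    """Random parameter draw kept inside the PSD region."""
    while True:
        pi = rng.dirichlet(np.ones(8))[:7] * rng.uniform(0.2, 0.9)
        rho = rng.uniform(-max_rho, max_rho, 3)
        try:
            return MixtureParams(
                pi=pi,
                sigma=rng.uniform(0.05, 0.25, 3),
                sigma0=rng.uniform(0.85, 1.2, 3),
                rho=rho,
                rho0=rng.uniform(-0.3, 0.3, 3),
            )
        except Exception:
            continue


def random_ctx(rng, max_m=4):
    m = int(rng.integers(1, max_m + 1))
    return VariantContext(nbr_weights=rng.uniform(0.05, 0.5, m),
                          n=rng.uniform(50, 500, 3))


def random_subset(rng):
    d = int(rng.integers(1, 4))
    return TraitSubset(tuple(sorted(rng.choice(3, size=d, replace=False).tolist())))
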