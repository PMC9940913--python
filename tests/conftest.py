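"""Shared fixtures: small random models and enumerable systems."""

import numpy as np
import pytest

from crbm.model import CRBMParams


def random_params(n: int, m: int, seed: int = 0,
                  weight_scale: float = 0.5) -> CRBMParams:
    rng = np.random.default_rng(seed)
    return CRBMParams(
        weights=rng.normal(0.0, weight_scale, (n, m)),
        g=rng.normal(0.0, 1.0, n),
        gamma_plus=rng.uniform(0.5, 2.0, m),
        gamma_minus=rng.uniform(0.5, 2.0, m),
        theta_plus=rng.normal(0.0, 1.0, m),
        theta_minus=rng.normal(0.0, 1.0, m),
    )


def quadratic_params(n: int, m: int, seed: int = 0) -> CRBMParams:
    """gamma_+ = gamma_-, theta_+ = theta_-: the Hopfield-equivalent limit."""
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.6, 2.0, m)
    theta = rng.normal(0.0, 0.5, m)
    return CRBMParams(
        weights=rng.normal(0.0, 0.4, (n, m)),
        g=rng.normal(0.0, 1.0, n),
        gamma_plus=gamma, gamma_minus=gamma.copy(),
        theta_plus=theta, theta_minus=theta.copy(),
    )


@pytest.fixture
def small_params() -> CRBMParams:
    return random_params(8, 3, seed=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
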