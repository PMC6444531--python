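"""Shared fixtures: small synthetic curve populations and fitted densities."""

import numpy as np
import pytest

import chronopick as cp


@pytest.fixture(scope="session")
def unit_grid_101():
    return cp.TimeGrid(np.linspace(0.0, 1.0, 101))


@pytest.fixture(scope="session")
def unit_grid_21():
    return cp.TimeGrid(np.linspace(0.0, 1.0, 21))


@pytest.fixture(scope="session")
def gauss_bump(unit_grid_101):
    t = unit_grid_101.times
    return np.exp(-0.5 * ((t - 0.45) / 0.12) ** 2)


@pytest.fixture(scope="session")
def skew_population_small():
    """10 skew-Gaussian curves on a 21-point grid (fast to fit)."""
    cfg = cp.ScenarioConfig(family="skew_gaussian", n_curves=10, n_times=21, seed=2)
    return cp.skew_gaussian_curves(cfg)


@pytest.fixture(scope="session")
def fitted_samples(skew_population_small):
    """A fitted density and 200 Monte-Carlo draws from it."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dist = cp.fit_distribution(skew_population_small)
        samples = cp.sample_curves(dist, 200, 3)
    return dist, samples
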