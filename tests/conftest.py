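import numpy as np
import pytest

from lakethermal.curves import coefficient_matrix, fit_population, seasonal_profile
from lakethermal.synthetic import generate_population


@pytest.fixture(scope="session")
def default_population():
    """The default 732-lake synthetic population (seed 42)."""
    series, truth = generate_population(seed=42)
    return series, truth


@pytest.fixture(scope="session")
def default_fits(default_population):
    series, _ = default_population
    return fit_population(series)


@pytest.fixture(scope="session")
def default_coefs(default_fits):
    return coefficient_matrix(default_fits)


@pytest.fixture(scope="session")
def default_profiles(default_fits):
    return [seasonal_profile(f) for f in default_fits]


@pytest.fixture(scope="session")
def small_population():
    """A light three-region population for fast end-to-end tests."""
    series, truth = generate_population(
        {"NF": 10, "TH": 10, "SW": 10}, n_years=4, seed=7)
    return series, truth
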