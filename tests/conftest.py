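import numpy as np
import pytest

from adofp.core_io import CountryDemography, CountryMeta
from adofp.indicators import IndicatorSamples
from adofp.synthetic_data import SimulationConfig, simulate_surveys, simulate_truth


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_regions=2, n_subregions_per_region=2, n_countries_per_subregion=3,
        surveys_mean=4.0, zero_inflation=0.1,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config, seed=11)


@pytest.fixture(scope="session")
def small_observations(small_config, small_truth):
    return simulate_surveys(small_truth, small_config, seed=12)


@pytest.fixture
def three_country_meta():
    return {
        "AAA": CountryMeta("AAA", "A", "sub1", "reg1", activity_group=1),
        "BBB": CountryMeta("BBB", "B", "sub1", "reg1", activity_group=1),
        "CCC": CountryMeta("CCC", "C", "sub2", "reg2", activity_group=0),
    }


@pytest.fixture
def three_country_demog():
    years = np.arange(1970, 2031)
    out = {}
    for code, base, w0 in (("AAA", 1e6, 0.3), ("BBB", 2e6, 0.2), ("CCC", 5e5, 0.1)):
        out[code] = CountryDemography(
            country_code=code,
            years=years,
            pop_15_19=np.full(years.size, base),
            prop_married=np.linspace(w0, w0 / 2, years.size),
        )
    return out


def degenerate_samples(values, countries, years, marital_group="married", n_draws=200, jitter=0.0, seed=0):
    """IndicatorSamples with (near-)constant draws at the given values.

    ``values`` maps indicator -> scalar or (C, T) array.
    """
    rng = np.random.default_rng(seed)
    C, T = len(countries), len(years)
    data = {}
    for k, v in values.items():
        base = np.broadcast_to(np.asarray(v, dtype=float), (C, T))
        draws = np.tile(base, (n_draws, 1, 1))
        if jitter:
            draws = draws + jitter * rng.standard_normal(draws.shape)
        data[k] = draws
    return IndicatorSamples(
        marital_group=marital_group,
        countries=list(countries),
        years=np.asarray(years),
        scale="proportion",
        data=data,
    )
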