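import numpy as np
import pytest

from countyhale.synthetic_data import (
    EffectVariances,
    ObservationDesign,
    SyntheticConfig,
    make_geography,
    simulate_population,
    simulate_truth,
)

SMALL_AGES = (0.0, 1.0, 5.0, 15.0, 45.0, 65.0, 85.0)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_counties=12,
        n_states=3,
        n_races=2,
        n_causes=3,
        years=tuple(range(2009, 2013)),
        age_starts=SMALL_AGES,
    )


@pytest.fixture(scope="session")
def small_geography(small_config):
    return make_geography(
        small_config.n_counties, small_config.n_states, seed=0
    )


@pytest.fixture(scope="session")
def small_truth(small_geography, small_config):
    return simulate_truth(small_geography, small_config, seed=11)


@pytest.fixture(scope="session")
def small_population(small_geography, small_config):
    return simulate_population(small_geography, small_config, seed=11)


@pytest.fixture(scope="session")
def noise_free_truth(small_geography, small_config):
    """Truth with every random-effect variance at zero."""
    zero = EffectVariances()
    cfg = SyntheticConfig(
        n_counties=small_config.n_counties,
        n_states=small_config.n_states,
        n_races=small_config.n_races,
        n_causes=small_config.n_causes,
        years=small_config.years,
        age_starts=small_config.age_starts,
        prevalence_variances=zero,
        mortality_variances=zero,
        yld_variances=zero,
    )
    return simulate_truth(small_geography, cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
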