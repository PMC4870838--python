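import dataclasses

import pytest

from halysim.environment import SiteProfile, SyntheticClimateSpec, synthesize_weather
from halysim.life_history import LifeHistoryParams, SurvivalParams, FecundityParams


@pytest.fixture(scope="session")
def midlat_site():
    return SiteProfile("Bridgeton NJ", 39.43, -75.23)


@pytest.fixture(scope="session")
def warm_weather(midlat_site):
    """A warm mid-latitude synthetic year with freezing winters."""
    spec = SyntheticClimateSpec(
        annual_mean=12.0, annual_amplitude=14.0, diurnal_range=10.0,
        noise_sd=3.0, noise_autocorrelation=0.6, phase_day=200, seed=42,
    )
    return synthesize_weather(spec, midlat_site, 2007)


@pytest.fixture(scope="session")
def frostfree_weather(midlat_site):
    """A deterministic mild frost-free year (coolest tmin = 3 degC); with
    mortality disabled only about one generation fits the season, keeping
    populations bounded."""
    spec = SyntheticClimateSpec(
        annual_mean=14.0, annual_amplitude=6.0, diurnal_range=10.0,
        noise_sd=0.0, phase_day=200, seed=0,
    )
    return synthesize_weather(spec, midlat_site, 2007)


def no_mortality_params(**overrides) -> LifeHistoryParams:
    """Parameter set with every mortality channel closed: immature survival
    1.0, adult mortalities 0, hatch success 1 (hatched mean = clutch mean,
    zero spread)."""
    base = LifeHistoryParams()
    survival = SurvivalParams(
        immature_daily_survival={
            s: [(0.0, 1.0), (40.0, 1.0)]
            for s in ("EGG", "N1", "N2", "N3", "N4", "N5")
        },
        p_adult_daily_mortality=0.0,
        fx_adult_daily_mortality=0.0,
    )
    fecundity = FecundityParams(
        clutch_size_mean=26.0, clutch_size_spread=0.0,
        hatched_per_clutch_mean=26.0, hatched_per_clutch_spread=0.0,
        clutch_interval_spread=0.0, oviposition_events_spread=0.0,
    )
    return dataclasses.replace(base, survival=survival, fecundity=fecundity, **overrides)


@pytest.fixture()
def benign_params():
    return no_mortality_params()
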