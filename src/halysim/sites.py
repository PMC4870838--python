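"""Built-in site registry and synthetic climate presets.

The eight default sites span the latitudes of recent and potential invasion
across US horticultural production regions. The synthetic presets are named
for climate archetypes; they emulate realistic mid-latitude annual cycles but
do not reproduce any particular weather-station record.
"""

from __future__ import annotations

from .environment import SiteProfile, SyntheticClimateSpec

__all__ = ["DEFAULT_SITES", "SYNTHETIC_PRESETS", "get_site", "get_preset"]

#: Default multi-site registry (name, latitude N, longitude W).
DEFAULT_SITES: dict[str, SiteProfile] = {
    s.name: s
    for s in (
        SiteProfile("Wenatchee WA", 47.42, -102.33),
        SiteProfile("Salem OR", 44.93, -123.03),
        SiteProfile("Geneva NY", 42.88, -76.99),
        SiteProfile("Bridgeton NJ", 39.43, -75.23),
        SiteProfile("Davis CA", 38.55, -121.74),
        SiteProfile("Asheville NC", 35.58, -85.56),
        SiteProfile("Riverside CA", 33.95, -117.40),
        SiteProfile("Homestead FL", 25.47, -80.47),
    )
}

#: Synthetic climate archetypes (deg C). ``seed`` is overridden per run.
SYNTHETIC_PRESETS: dict[str, SyntheticClimateSpec] = {
    # humid continental mid-latitude: warm summers, freezing winters
    "warm-humid": SyntheticClimateSpec(
        annual_mean=12.0, annual_amplitude=14.0, diurnal_range=10.0,
        noise_sd=3.0, noise_autocorrelation=0.6, phase_day=200,
    ),
    # maritime west coast: mild summers, narrow annual swing
    "cool-maritime": SyntheticClimateSpec(
        annual_mean=11.0, annual_amplitude=7.0, diurnal_range=9.0,
        noise_sd=2.5, noise_autocorrelation=0.6, phase_day=210,
    ),
    # cold continental interior: short growing season
    "cold-continental": SyntheticClimateSpec(
        annual_mean=8.0, annual_amplitude=15.0, diurnal_range=11.0,
        noise_sd=3.5, noise_autocorrelation=0.6, phase_day=200,
    ),
    # hot interior valley: high summer maxima, large diurnal range
    "hot-arid": SyntheticClimateSpec(
        annual_mean=18.0, annual_amplitude=11.0, diurnal_range=15.0,
        noise_sd=2.5, noise_autocorrelation=0.6, phase_day=200,
    ),
    # frost-free subtropical lowland
    "subtropical": SyntheticClimateSpec(
        annual_mean=24.0, annual_amplitude=4.5, diurnal_range=9.0,
        noise_sd=2.0, noise_autocorrelation=0.6, phase_day=205,
    ),
}


def get_site(name: str) -> SiteProfile:
    try:
        return DEFAULT_SITES[name]
    except KeyError:
        raise KeyError(
            f"unknown site {name!r}; known sites: {sorted(DEFAULT_SITES)}"
        ) from None


def get_preset(name: str) -> SyntheticClimateSpec:
    try:
        return SYNTHETIC_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown synthetic preset {name!r}; known: {sorted(SYNTHETIC_PRESETS)}"
        ) from None
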