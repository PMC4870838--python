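"""Biological parameters and stage-specific development, survival and fecundity.

Stage durations come from linear regressions of duration (days) on daily mean
temperature for the six developmental processes (egg incubation, the four
inter-instar molts, and eclosion). All slopes are negative — warmer days mean
faster development — so the reciprocal of the predicted duration serves as the
daily Bernoulli probability of advancing one stage. Development halts outside
the [14.17, 35.76] deg C threshold band.

Fecundity is described by truncated-normal draws around published means
(clutch size 26.08, inter-clutch interval 4.32 d, 9.33 oviposition events,
21.30 hatched per clutch), with a 68 DD (base 12.7 deg C) pre-oviposition
requirement and a 1:1 sex ratio.

Immature survivorship and adult mortality schedules are not published in a
reusable form; the defaults shipped here are clearly-labelled synthetic
placeholders that users should replace for faithful site predictions (see
``SurvivalParams``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "STAGES",
    "PROCESSES",
    "DEVELOPMENT_HALTED",
    "StageDurationModel",
    "DevelopmentThresholds",
    "FecundityParams",
    "SurvivalParams",
    "DiapauseParams",
    "LifeHistoryParams",
    "stage_duration",
    "transition_probability",
    "draw_reproductive_schedule",
    "immature_survival",
    "load_params",
    "save_params",
]

#: Life stages in developmental order; ADULT is terminal.
STAGES = ("EGG", "N1", "N2", "N3", "N4", "N5", "ADULT")

#: The six developmental processes, indexed by the stage they leave.
PROCESSES = ("egg_n1", "n1_n2", "n2_n3", "n3_n4", "n4_n5", "n5_adult")

#: Sentinel returned when temperature is outside the development band.
DEVELOPMENT_HALTED = None

# duration(T) = slope*T + intercept, in days, per process
_DEFAULT_DURATION_MODELS: dict[str, tuple[float, float]] = {
    "egg_n1": (-0.9843, 33.438),
    "n1_n2": (-0.3728, 14.68),
    "n2_n3": (-0.6119, 25.249),
    "n3_n4": (-0.3986, 17.602),
    "n4_n5": (-0.4408, 19.036),
    "n5_adult": (-0.5332, 24.147),
}


@dataclass(frozen=True)
class StageDurationModel:
    """Linear duration-vs-temperature models for the six processes.

    ``models[process] = (slope day/degC, intercept day)``; evaluated duration
    is clamped to >= 1 day so the implied daily transition probability stays
    in [0, 1].
    """

    models: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_DURATION_MODELS)
    )

    def __post_init__(self) -> None:
        if set(self.models) != set(PROCESSES):
            raise ValueError(f"duration models must cover exactly {PROCESSES}")


@dataclass(frozen=True)
class DevelopmentThresholds:
    """Temperature band (inclusive) within which development proceeds."""

    t_min_dev: float = 14.17
    t_max_dev: float = 35.76

    def __post_init__(self) -> None:
        if self.t_min_dev >= self.t_max_dev:
            raise ValueError("t_min_dev must be below t_max_dev")


@dataclass(frozen=True)
class FecundityParams:
    """Reproductive parameters: pre-oviposition thermal requirement and the
    mean/spread of the per-female schedule draws.

    Means are the published colony statistics (clutch size 26.08 +/- 0.31,
    interval 4.32 +/- 0.41 d, 9.33 +/- 0.19 oviposition events, 21.30 +/-
    0.48 hatched per clutch, mean +/- SEM). ``spread`` is the SD of the
    per-female truncated normal. Only the SEMs of the means are published;
    the default spreads below are plausible individual-level SDs, chosen so
    that rounding each draw to an integer leaves the population means at the
    published values (an SD as small as the SEM concentrates draws on a
    single integer and biases the rounded mean). Set the spreads to the SEMs
    to reproduce near-deterministic schedules.
    """

    preovip_dd: float = 68.0
    preovip_base: float = 12.7
    clutch_size_mean: float = 26.08
    clutch_size_spread: float = 3.0
    clutch_interval_mean: float = 4.32
    clutch_interval_spread: float = 1.5
    oviposition_events_mean: float = 9.33
    oviposition_events_spread: float = 2.0
    hatched_per_clutch_mean: float = 21.30
    hatched_per_clutch_spread: float = 4.0
    sex_ratio_female: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "preovip_dd", "clutch_size_mean", "clutch_interval_mean",
            "oviposition_events_mean", "hatched_per_clutch_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "clutch_size_spread", "clutch_interval_spread",
            "oviposition_events_spread", "hatched_per_clutch_spread",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.hatched_per_clutch_mean > self.clutch_size_mean:
            raise ValueError("hatched_per_clutch mean cannot exceed clutch size mean")
        if not (0 <= self.sex_ratio_female <= 1):
            raise ValueError("sex_ratio_female must be in [0, 1]")


# Placeholder immature survival: per-stage (temperature, daily survival)
# interpolation nodes. SYNTHETIC placeholder values (the published
# stage-by-temperature table is external to this model description); chosen so
# that season-long egg-to-adult survival is of order 10^-2 and year-end
# populations from 1000 founders land at the 10^3 scale.
_PLACEHOLDER_IMMATURE_TABLE: dict[str, list[tuple[float, float]]] = {
    stage: [(14.0, 0.88), (20.0, 0.90), (30.0, 0.90), (36.0, 0.88)]
    for stage in ("EGG", "N1", "N2", "N3", "N4", "N5")
}


@dataclass(frozen=True)
class SurvivalParams:
    """Daily survival/mortality schedules.

    ``immature_daily_survival`` maps each immature stage to interpolation
    nodes ``(temperature degC, daily survival probability)``; lookups
    linearly interpolate and clamp at the end nodes. The shipped defaults are
    synthetic placeholders, as are the adult daily mortalities
    (``p_adult_daily_mortality`` applies to overwintered adults after diapause
    termination, ``fx_adult_daily_mortality`` to non-diapausing
    filial-generation adults).
    """

    immature_daily_survival: Mapping[str, list[tuple[float, float]]] = field(
        default_factory=lambda: {
            k: list(v) for k, v in _PLACEHOLDER_IMMATURE_TABLE.items()
        }
    )
    p_adult_daily_mortality: float = 0.005
    fx_adult_daily_mortality: float = 0.0

    def __post_init__(self) -> None:
        for stage, nodes in self.immature_daily_survival.items():
            for t, s in nodes:
                if not (0.0 <= s <= 1.0):
                    raise ValueError(
                        f"survival {s} for stage {stage} at {t} degC outside [0, 1]"
                    )
        for name in ("p_adult_daily_mortality", "fx_adult_daily_mortality"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be a probability")


@dataclass(frozen=True)
class DiapauseParams:
    """Photoperiod cue and frost-mortality settings.

    A single critical photoperiod both terminates overwintered-adult diapause
    in spring (on/before the summer solstice) and sets the diapause category
    of newly eclosed adults. After the autumnal equinox, days with
    ``tmin < frost_threshold`` kill all eggs, nymphs and vitellogenic adults.
    """

    critical_photoperiod: float = 13.5
    daylength_coefficient: float = 0.8333
    frost_threshold: float = 0.0
    frost_active_month_day: tuple[int, int] = (9, 22)  # autumnal equinox
    solstice_month_day: tuple[int, int] = (6, 21)

    def __post_init__(self) -> None:
        if not (0 < self.critical_photoperiod < 24):
            raise ValueError("critical_photoperiod must be in (0, 24)")


@dataclass(frozen=True)
class LifeHistoryParams:
    """Complete, file-loadable parameter set with literature defaults."""

    durations: StageDurationModel = field(default_factory=StageDurationModel)
    thresholds: DevelopmentThresholds = field(default_factory=DevelopmentThresholds)
    fecundity: FecundityParams = field(default_factory=FecundityParams)
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    diapause: DiapauseParams = field(default_factory=DiapauseParams)
    # diagnostic degree-day references (not used by the engine)
    egg_dd: float = 53.30
    egg_dd_base: float = 13.94
    life_cycle_dd: float = 537.63
    life_cycle_dd_base: float = 14.14
    initial_population: int = 1000
    replicates: int = 100


def stage_duration(
    process: str,
    tmean: float,
    model: StageDurationModel | None = None,
    thresholds: DevelopmentThresholds | None = None,
) -> float | None:
    """Expected stage duration (days) at daily mean temperature ``tmean``.

    Returns :data:`DEVELOPMENT_HALTED` (``None``) outside the inclusive
    threshold band; inside it, the linear prediction clamped below at 1 day.
    """
    model = model or StageDurationModel()
    thresholds = thresholds or DevelopmentThresholds()
    if process not in model.models:
        raise KeyError(f"unknown process {process!r}")
    if tmean < thresholds.t_min_dev or tmean > thresholds.t_max_dev:
        return DEVELOPMENT_HALTED
    slope, intercept = model.models[process]
    return max(1.0, slope * tmean + intercept)


def transition_probability(
    process: str,
    tmean: float,
    model: StageDurationModel | None = None,
    thresholds: DevelopmentThresholds | None = None,
) -> float:
    """Daily Bernoulli probability of completing ``process`` at ``tmean``.

    Zero outside the development band, else ``1/duration`` (duration clamp
    keeps this within [0, 1]).
    """
    d = stage_duration(process, tmean, model, thresholds)
    if d is DEVELOPMENT_HALTED:
        return 0.0
    return min(1.0, 1.0 / d)


def _truncnorm_draw(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    """Truncated-normal draws (lower-truncated, no upper bound)."""
    if sd == 0:
        return np.full(size, max(mean, lower))
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def draw_reproductive_schedule(
    params: FecundityParams, rng: np.random.Generator, size: int = 1
) -> dict[str, np.ndarray]:
    """Draw per-female reproductive schedules.

    Each female receives a number of oviposition events, a clutch size, a
    hatched-per-clutch count (capped at clutch size) and an inter-clutch
    interval (>= 1 day), each a rounded truncated-normal draw. Returns arrays
    of length ``size`` keyed ``n_events``, ``clutch_size``,
    ``hatched_per_clutch``, ``interval_days``.
    """
    n_events = np.rint(
        _truncnorm_draw(rng, params.oviposition_events_mean,
                        params.oviposition_events_spread, 0.0, size)
    ).astype(np.int64)
    clutch = np.rint(
        _truncnorm_draw(rng, params.clutch_size_mean,
                        params.clutch_size_spread, 0.0, size)
    ).astype(np.int64)
    hatched = np.rint(
        _truncnorm_draw(rng, params.hatched_per_clutch_mean,
                        params.hatched_per_clutch_spread, 0.0, size)
    ).astype(np.int64)
    hatched = np.minimum(hatched, clutch)
    interval = np.rint(
        _truncnorm_draw(rng, params.clutch_interval_mean,
                        params.clutch_interval_spread, 1.0, size)
    ).astype(np.int64)
    interval = np.maximum(interval, 1)
    return {
        "n_events": n_events,
        "clutch_size": clutch,
        "hatched_per_clutch": hatched,
        "interval_days": interval,
    }


def immature_survival(
    stage: str,
    tmean: float | np.ndarray,
    params: SurvivalParams,
) -> float | np.ndarray:
    """Daily survival probability for an immature stage at ``tmean``.

    Linear interpolation between the configured (temperature, survival)
    nodes, clamped at the end nodes.
    """
    if stage not in params.immature_daily_survival:
        raise KeyError(f"no survival schedule configured for stage {stage!r}")
    nodes = sorted(params.immature_daily_survival[stage])
    ts = np.array([t for t, _ in nodes])
    ss = np.array([s for _, s in nodes])
    out = np.interp(np.asarray(tmean, dtype=float), ts, ss)
    return float(out) if np.isscalar(tmean) else out


# ---------------------------------------------------------------------------
# parameter file I/O (YAML key-value sections mirroring the dataclasses)

def _params_to_dict(params: LifeHistoryParams) -> dict:
    return {
        "durations": {k: list(v) for k, v in params.durations.models.items()},
        "thresholds": dataclasses.asdict(params.thresholds),
        "fecundity": dataclasses.asdict(params.fecundity),
        "survival": {
            "immature_daily_survival": {
                k: [list(node) for node in v]
                for k, v in params.survival.immature_daily_survival.items()
            },
            "p_adult_daily_mortality": params.survival.p_adult_daily_mortality,
            "fx_adult_daily_mortality": params.survival.fx_adult_daily_mortality,
        },
        "diapause": {
            "critical_photoperiod": params.diapause.critical_photoperiod,
            "daylength_coefficient": params.diapause.daylength_coefficient,
            "frost_threshold": params.diapause.frost_threshold,
            "frost_active_month_day": list(params.diapause.frost_active_month_day),
            "solstice_month_day": list(params.diapause.solstice_month_day),
        },
        "dd_reference": {
            "egg_dd": params.egg_dd,
            "egg_dd_base": params.egg_dd_base,
            "life_cycle_dd": params.life_cycle_dd,
            "life_cycle_dd_base": params.life_cycle_dd_base,
        },
        "simulation": {
            "initial_population": params.initial_population,
            "replicates": params.replicates,
        },
    }


def _params_from_dict(data: dict) -> LifeHistoryParams:
    defaults = LifeHistoryParams()
    data = data or {}

    dur = data.get("durations")
    durations = (
        StageDurationModel({k: tuple(v) for k, v in dur.items()})
        if dur else defaults.durations
    )
    thresholds = (
        DevelopmentThresholds(**data["thresholds"])
        if "thresholds" in data else defaults.thresholds
    )
    fecundity = (
        dataclasses.replace(defaults.fecundity, **data["fecundity"])
        if "fecundity" in data else defaults.fecundity
    )
    if "survival" in data:
        s = data["survival"]
        table = s.get("immature_daily_survival")
        survival = SurvivalParams(
            immature_daily_survival=(
                {k: [tuple(n) for n in v] for k, v in table.items()}
                if table is not None
                else defaults.survival.immature_daily_survival
            ),
            p_adult_daily_mortality=s.get(
                "p_adult_daily_mortality", defaults.survival.p_adult_daily_mortality
            ),
            fx_adult_daily_mortality=s.get(
                "fx_adult_daily_mortality", defaults.survival.fx_adult_daily_mortality
            ),
        )
    else:
        survival = defaults.survival
    if "diapause" in data:
        d = dict(data["diapause"])
        for key in ("frost_active_month_day", "solstice_month_day"):
            if key in d:
                d[key] = tuple(d[key])
        diapause = dataclasses.replace(defaults.diapause, **d)
    else:
        diapause = defaults.diapause
    dd = data.get("dd_reference", {})
    sim = data.get("simulation", {})
    return LifeHistoryParams(
        durations=durations,
        thresholds=thresholds,
        fecundity=fecundity,
        survival=survival,
        diapause=diapause,
        egg_dd=dd.get("egg_dd", defaults.egg_dd),
        egg_dd_base=dd.get("egg_dd_base", defaults.egg_dd_base),
        life_cycle_dd=dd.get("life_cycle_dd", defaults.life_cycle_dd),
        life_cycle_dd_base=dd.get("life_cycle_dd_base", defaults.life_cycle_dd_base),
        initial_population=sim.get("initial_population", defaults.initial_population),
        replicates=sim.get("replicates", defaults.replicates),
    )


def save_params(params: LifeHistoryParams, path) -> None:
    """Write a parameter set to a YAML file (round-trips with load_params)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_params_to_dict(params), fh, sort_keys=False)


def load_params(path) -> LifeHistoryParams:
    """Load a parameter set; absent keys fall back to literature defaults."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed parameter file {path}: {exc}") from exc
    if data is not None and not isinstance(data, dict):
        raise ValueError(f"malformed parameter file {path}: expected a mapping")
    return _params_from_dict(data)
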