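"""Agent-based daily-step engine for one replicate year.

Every insect is an autonomous agent. Each simulated day applies, in fixed
order: (1) spring diapause termination of overwintered (P) adults on the
first day the critical photoperiod is reached on/before the summer solstice;
(2) mortality — background daily survival for immatures, post-termination
mortality for P adults, mortality for non-diapausing filial adults, and the
post-equinox frost rule; (3) development — an independent Bernoulli trial per
immature with success probability 1/duration(T), newly eclosed adults
classified into the vitellogenic or diapause track by the day length they
eclose under; (4) reproduction — vitellogenic females accumulate degree-days
(base 12.7 deg C) toward the 68 DD pre-oviposition requirement, then lay
clutches on their drawn schedule; (5) a census append.

The population is stored as a structure of numpy arrays so replicate years
with 10^5-10^6 agents run in seconds; the per-agent contracts (one Bernoulli
trial per day, at most one stage advance, irreversible reproductive state)
are unchanged by the vectorization.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import WeatherSeries
from .life_history import (
    PROCESSES,
    STAGES,
    DiapauseParams,
    LifeHistoryParams,
    draw_reproductive_schedule,
    immature_survival,
    transition_probability,
)

__all__ = [
    "REPRO_NONE",
    "REPRO_DIAPAUSE",
    "REPRO_VITELLOGENIC",
    "EnvDay",
    "EventLog",
    "PopulationState",
    "SimulationResult",
    "initialize_population",
    "classify_eclosion",
    "update_p_diapause",
    "apply_mortality",
    "apply_development",
    "apply_reproduction",
    "step",
    "run_year",
    "run_replicates",
]

# stage codes follow life_history.STAGES order
STAGE_EGG, STAGE_N1, STAGE_N2, STAGE_N3, STAGE_N4, STAGE_N5, STAGE_ADULT = range(7)

REPRO_NONE = 0  # immatures carry no reproductive state
REPRO_DIAPAUSE = 1
REPRO_VITELLOGENIC = 2

REPRO_NAMES = {REPRO_NONE: "NONE", REPRO_DIAPAUSE: "DIAPAUSE", REPRO_VITELLOGENIC: "VITELLOGENIC"}

_MAX_CENSUS_GEN = 9  # generations >= 9 are pooled in the census key


@dataclass(frozen=True)
class EnvDay:
    """One day's abiotic state handed to the engine."""

    doy: int
    tmean: float
    tmin: float
    tmax: float
    photoperiod: float
    dd_preovip: float  # that day's DD increment at the pre-oviposition base


class EventLog:
    """Append-only chronological log of agent events.

    Records are batched per (day, kind): each holds an array of agent ids and
    an optional detail mapping (e.g. death cause, generation of eclosing
    adults). ``to_frame()`` expands to a tidy DataFrame.
    """

    KINDS = (
        "eclosion",
        "diapause_termination",
        "vitellogenesis",
        "oviposition",
        "death",
        "stage_transition",
    )

    def __init__(self) -> None:
        self._records: list[tuple[int, str, np.ndarray, dict]] = []

    def append(self, doy: int, kind: str, ids: np.ndarray, **detail) -> None:
        if kind not in self.KINDS:
            raise ValueError(f"unknown event kind {kind!r}")
        if self._records and doy < self._records[-1][0]:
            raise ValueError("events must be appended chronologically")
        if len(ids):
            self._records.append((doy, kind, np.asarray(ids, dtype=np.int64), dict(detail)))

    def __len__(self) -> int:
        return sum(len(ids) for _, _, ids, _ in self._records)

    def iter_batches(self):
        yield from self._records

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for doy, kind, ids, detail in self._records:
            df = pd.DataFrame({"doy": doy, "agent_id": ids, "event": kind})
            for key, val in detail.items():
                df[key] = val
            rows.append(df)
        if not rows:
            return pd.DataFrame(columns=["doy", "agent_id", "event"])
        return pd.concat(rows, ignore_index=True)


class PopulationState:
    """Structure-of-arrays population for one replicate.

    Slots hold both living and (until compaction) dead agents; ``alive``
    masks the active population. Dead agents persist in the event log.
    """

    _FLOAT_FIELDS = ("preovip_dd", "hatch_p")
    _INT_FIELDS = (
        "stage", "generation", "repro", "n_events", "clutch_size",
        "hatched", "interval", "clutches_laid", "next_ovip_doy", "eclosion_doy",
    )

    def __init__(self, rng: np.random.Generator, capacity: int = 4096) -> None:
        self.rng = rng
        self.cap = capacity
        self.n = 0
        self._next_id = 0
        self.ids = np.zeros(capacity, dtype=np.int64)
        self.alive = np.zeros(capacity, dtype=bool)
        self.female = np.zeros(capacity, dtype=bool)
        for name in self._INT_FIELDS:
            setattr(self, name, np.zeros(capacity, dtype=np.int32))
        for name in self._FLOAT_FIELDS:
            setattr(self, name, np.zeros(capacity, dtype=np.float64))
        self.doy = 1
        self.terminated = False  # P diapause termination fired
        self.births = 0
        self.deaths = {}  # cause -> count
        self.log = EventLog()
        self.log_events = True
        self.daily_counters: list[tuple[int, int, int, int]] = []  # doy, births, deaths, alive
        self._eclosion_acc: list[tuple[int, np.ndarray, int]] = []
        self._first_ovip_acc: list[tuple[int, np.ndarray]] = []

    # -- slot management ----------------------------------------------------
    def _grow(self, need: int) -> None:
        new_cap = self.cap
        while self.n + need > new_cap:
            new_cap *= 2
        if new_cap == self.cap:
            return
        for name in ("ids", "alive", "female", *self._INT_FIELDS, *self._FLOAT_FIELDS):
            old = getattr(self, name)
            new = np.zeros(new_cap, dtype=old.dtype)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)
        self.cap = new_cap

    def compact(self) -> None:
        """Drop dead slots (their history stays in the event log)."""
        keep = self.alive[: self.n].copy()
        m = int(keep.sum())
        for name in ("ids", "alive", "female", *self._INT_FIELDS, *self._FLOAT_FIELDS):
            arr = getattr(self, name)
            arr[:m] = arr[: self.n][keep]
            setattr(self, name, arr)
        self.n = m

    def maybe_compact(self) -> None:
        if self.n > 20000 and self.alive[: self.n].sum() < self.n // 2:
            self.compact()

    def add_agents(
        self,
        count: int,
        *,
        stage: int,
        generation: int,
        female: np.ndarray | bool,
        repro: int,
        hatch_p: np.ndarray | float = 1.0,
    ) -> np.ndarray:
        """Append ``count`` new agents; returns their slot indices."""
        self._grow(count)
        sl = slice(self.n, self.n + count)
        idx = np.arange(self.n, self.n + count)
        self.ids[sl] = np.arange(self._next_id, self._next_id + count)
        self._next_id += count
        self.alive[sl] = True
        self.stage[sl] = stage
        self.generation[sl] = generation
        self.female[sl] = female
        self.repro[sl] = repro
        self.preovip_dd[sl] = 0.0
        self.hatch_p[sl] = hatch_p
        self.n_events[sl] = -1
        self.clutch_size[sl] = 0
        self.hatched[sl] = 0
        self.interval[sl] = 0
        self.clutches_laid[sl] = 0
        self.next_ovip_doy[sl] = -1
        self.eclosion_doy[sl] = -1
        self.n += count
        return idx

    # -- bookkeeping --------------------------------------------------------
    def kill(self, idx: np.ndarray, cause: str) -> None:
        if len(idx) == 0:
            return
        self.alive[idx] = False
        self.deaths[cause] = self.deaths.get(cause, 0) + len(idx)
        if self.log_events:
            self.log.append(self.doy, "death", self.ids[idx], cause=cause)

    def alive_count(self) -> int:
        return int(self.alive[: self.n].sum())

    def census_counts(self) -> pd.DataFrame:
        """Counts of living agents keyed by (stage, generation, repro_state)."""
        a = self.alive[: self.n]
        stage = self.stage[: self.n][a]
        gen = np.minimum(self.generation[: self.n][a], _MAX_CENSUS_GEN)
        repro = self.repro[: self.n][a]
        key = (stage * (_MAX_CENSUS_GEN + 1) + gen) * 3 + repro
        counts = np.bincount(key, minlength=7 * (_MAX_CENSUS_GEN + 1) * 3)
        nz = np.nonzero(counts)[0]
        return pd.DataFrame(
            {
                "stage": [STAGES[k // (3 * (_MAX_CENSUS_GEN + 1))] for k in nz],
                "generation": (nz // 3) % (_MAX_CENSUS_GEN + 1),
                "repro_state": [REPRO_NAMES[k % 3] for k in nz],
                "count": counts[nz],
            }
        )


@dataclass
class SimulationResult:
    """Daily census plus event log and summary artifacts for one replicate."""

    site_name: str
    year: int
    seed: int
    census: pd.DataFrame  # doy, stage, generation, repro_state, count
    events: EventLog
    eclosions: pd.DataFrame  # doy, generation, repro_state, count
    first_ovipositions: pd.DataFrame  # doy, generation, count
    births: int
    deaths: dict
    daily_counters: pd.DataFrame  # doy, births, deaths, alive
    final_state: PopulationState | None = None

    def census_pivot(self) -> pd.DataFrame:
        """Daily totals by stage (wide layout)."""
        return (
            self.census.pivot_table(
                index="doy", columns="stage", values="count", aggfunc="sum", fill_value=0
            )
            .reindex(columns=list(STAGES), fill_value=0)
        )

    def to_csv(self, census_path, events_path) -> None:
        self.census.to_csv(census_path, index=False)
        self.events.to_frame().to_csv(events_path, index=False)


def initialize_population(
    params: LifeHistoryParams, rng: np.random.Generator
) -> PopulationState:
    """Jan 1 state: ``initial_population`` overwintering pre-vitellogenic
    diapausing adult females, generation P (0)."""
    state = PopulationState(rng, capacity=max(4096, 2 * params.initial_population))
    state.add_agents(
        params.initial_population,
        stage=STAGE_ADULT,
        generation=0,
        female=True,
        repro=REPRO_DIAPAUSE,
    )
    return state


def classify_eclosion(day_length_hours: float, diapause: DiapauseParams) -> int:
    """Diapause category assigned to an adult on its eclosion day.

    Eclosing under a day length at or above the critical photoperiod places
    the adult on the vitellogenic track; below it, in diapause for the rest
    of the year (the assignment is permanent either way).
    """
    if day_length_hours >= diapause.critical_photoperiod:
        return REPRO_VITELLOGENIC
    return REPRO_DIAPAUSE


def update_p_diapause(
    state: PopulationState, env: EnvDay, diapause: DiapauseParams, solstice_doy: int
) -> None:
    """Terminate P-adult diapause on the first long-enough day before the
    solstice; irreversible (reproductive state is not plastic)."""
    if state.terminated:
        return
    if env.doy > solstice_doy:
        return
    if env.photoperiod < diapause.critical_photoperiod:
        return
    n = state.n
    mask = (
        state.alive[:n]
        & (state.stage[:n] == STAGE_ADULT)
        & (state.generation[:n] == 0)
        & (state.repro[:n] == REPRO_DIAPAUSE)
    )
    idx = np.nonzero(mask)[0]
    state.repro[idx] = REPRO_VITELLOGENIC
    state.terminated = True
    if state.log_events and len(idx):
        state.log.append(env.doy, "diapause_termination", state.ids[idx])
        state.log.append(env.doy, "vitellogenesis", state.ids[idx])


def apply_mortality(
    state: PopulationState,
    env: EnvDay,
    params: LifeHistoryParams,
    equinox_doy: int,
) -> None:
    """Daily survival draws plus the deterministic post-equinox frost rule."""
    n = state.n
    alive = state.alive[:n]
    stage = state.stage[:n]
    surv = params.survival

    # immature background mortality (stage x temperature table)
    imm = alive & (stage < STAGE_ADULT)
    idx = np.nonzero(imm)[0]
    if len(idx):
        p_surv = np.empty(len(idx))
        for code in range(STAGE_ADULT):
            m = stage[idx] == code
            if m.any():
                p_surv[m] = immature_survival(STAGES[code], env.tmean, surv)
        u = state.rng.random(len(idx))
        state.kill(idx[u >= p_surv], "immature_background")

    # adult background mortality: vitellogenic adults only; diapausing and
    # pre-termination P adults draw none
    alive = state.alive[:n]
    ad = alive & (stage == STAGE_ADULT) & (state.repro[:n] == REPRO_VITELLOGENIC)
    idx = np.nonzero(ad)[0]
    if len(idx):
        p_die = np.where(
            state.generation[idx] == 0,
            surv.p_adult_daily_mortality,
            surv.fx_adult_daily_mortality,
        )
        u = state.rng.random(len(idx))
        state.kill(idx[u < p_die], "adult_background")

    # frost: after the autumnal equinox, a sub-threshold tmin kills every
    # egg, nymph and vitellogenic adult; diapausing adults persist
    if env.doy > equinox_doy and env.tmin < params.diapause.frost_threshold:
        alive = state.alive[:n]
        frost = alive & (
            (stage < STAGE_ADULT) | (state.repro[:n] == REPRO_VITELLOGENIC)
        )
        state.kill(np.nonzero(frost)[0], "frost")


def apply_development(
    state: PopulationState, env: EnvDay, params: LifeHistoryParams
) -> None:
    """One Bernoulli development trial per living immature; N5 winners become
    adults, are logged as eclosions and classified by the day's photoperiod."""
    probs = np.array(
        [
            transition_probability(p, env.tmean, params.durations, params.thresholds)
            for p in PROCESSES
        ]
    )
    if not probs.any():
        return
    n = state.n
    alive = state.alive[:n]
    stage = state.stage[:n]
    imm = np.nonzero(alive & (stage < STAGE_ADULT))[0]
    if not len(imm):
        return
    u = state.rng.random(len(imm))
    success = u < probs[stage[imm]]
    winners = imm[success]
    if not len(winners):
        return

    # egg hatch success is applied at the egg -> N1 transition: an egg that
    # completes incubation hatches with probability hatched/clutch, else dies
    eggs = winners[stage[winners] == STAGE_EGG]
    if len(eggs):
        u2 = state.rng.random(len(eggs))
        failed = eggs[u2 >= state.hatch_p[eggs]]
        state.kill(failed, "unhatched")
        winners = winners[state.alive[winners]]

    state.stage[winners] += 1
    if state.log_events and len(winners):
        state.log.append(env.doy, "stage_transition", state.ids[winners],
                         to_stage=[STAGES[s] for s in state.stage[winners]])

    eclosed = winners[state.stage[winners] == STAGE_ADULT]
    if len(eclosed):
        state.eclosion_doy[eclosed] = env.doy
        repro = classify_eclosion(env.photoperiod, params.diapause)
        state.repro[eclosed] = repro
        if state.log_events:
            state.log.append(
                env.doy, "eclosion", state.ids[eclosed],
                generation=state.generation[eclosed].copy(),
                repro_state=REPRO_NAMES[repro],
            )
        state._eclosion_acc.append(
            (env.doy, state.generation[eclosed].copy(), repro)
        )


def apply_reproduction(
    state: PopulationState, env: EnvDay, params: LifeHistoryParams
) -> None:
    """Pre-oviposition degree-day accumulation, schedule draws and clutch
    deposition for vitellogenic females."""
    fec = params.fecundity
    n = state.n
    vit_f = (
        state.alive[:n]
        & (state.stage[:n] == STAGE_ADULT)
        & (state.repro[:n] == REPRO_VITELLOGENIC)
        & state.female[:n]
    )

    # females still in the pre-oviposition period accumulate DD (base 12.7)
    pre = np.nonzero(vit_f & (state.n_events[:n] < 0))[0]
    if len(pre):
        state.preovip_dd[pre] += env.dd_preovip
        ready = pre[state.preovip_dd[pre] >= fec.preovip_dd]
        if len(ready):
            sched = draw_reproductive_schedule(fec, state.rng, size=len(ready))
            state.n_events[ready] = sched["n_events"]
            state.clutch_size[ready] = sched["clutch_size"]
            state.hatched[ready] = sched["hatched_per_clutch"]
            state.interval[ready] = sched["interval_days"]
            # first oviposition occurs the day the requirement is met
            has_events = sched["n_events"] > 0
            state.next_ovip_doy[ready[has_events]] = env.doy
            state.next_ovip_doy[ready[~has_events]] = -1

    # oviposition events due today
    due = np.nonzero(vit_f & (state.next_ovip_doy[:n] == env.doy))[0]
    if len(due):
        first = state.clutches_laid[due] == 0
        clutches = state.clutch_size[due].astype(np.int64)
        total_eggs = int(clutches.sum())
        if total_eggs:
            mothers = np.repeat(due, clutches)
            gen = state.generation[mothers] + 1
            hatch_p = np.where(
                state.clutch_size[mothers] > 0,
                state.hatched[mothers] / np.maximum(state.clutch_size[mothers], 1),
                0.0,
            )
            female = state.rng.random(total_eggs) < fec.sex_ratio_female
            new_idx = state.add_agents(
                total_eggs,
                stage=STAGE_EGG,
                generation=0,  # filled below
                female=female,
                repro=REPRO_NONE,
                hatch_p=hatch_p,
            )
            state.generation[new_idx] = gen
            state.births += total_eggs
        state.clutches_laid[due] += 1
        if state.log_events:
            state.log.append(
                env.doy, "oviposition", state.ids[due],
                eggs=state.clutch_size[due].copy(),
                generation=state.generation[due].copy(),
            )
        firsts = due[first]
        if len(firsts):
            state._first_ovip_acc.append(
                (env.doy, state.generation[firsts].copy())
            )
        # schedule the next event or retire the schedule
        more = state.clutches_laid[due] < state.n_events[due]
        state.next_ovip_doy[due[more]] = env.doy + state.interval[due[more]]
        state.next_ovip_doy[due[~more]] = -1


def step(
    state: PopulationState,
    env: EnvDay,
    params: LifeHistoryParams,
    solstice_doy: int,
    equinox_doy: int,
) -> None:
    """Advance one day: diapause update, mortality, development,
    reproduction; the caller appends the census and advances the date."""
    if env.doy != state.doy:
        raise ValueError(f"environment day {env.doy} does not match state day {state.doy}")
    alive_before = state.alive_count()
    births_before = state.births
    deaths_before = sum(state.deaths.values())
    update_p_diapause(state, env, params.diapause, solstice_doy)
    apply_mortality(state, env, params, equinox_doy)
    apply_development(state, env, params)
    apply_reproduction(state, env, params)
    b = state.births - births_before
    d = sum(state.deaths.values()) - deaths_before
    # conservation: active(t+1) = active(t) + births - deaths
    assert state.alive_count() == alive_before + b - d
    state.daily_counters.append((env.doy, b, d, state.alive_count()))
    state.doy += 1
    state.maybe_compact()


def _env_days(weather: WeatherSeries, params: LifeHistoryParams) -> list[EnvDay]:
    dd_pre = weather.dd_increments(params.fecundity.preovip_base, None)
    return [
        EnvDay(
            doy=i + 1,
            tmean=weather.tmean[i],
            tmin=weather.tmin[i],
            tmax=weather.tmax[i],
            photoperiod=weather.photoperiod[i],
            dd_preovip=dd_pre[i],
        )
        for i in range(len(weather))
    ]


def run_year(
    weather: WeatherSeries,
    params: LifeHistoryParams,
    seed: int,
    *,
    log_events: bool = True,
    keep_final_state: bool = False,
) -> SimulationResult:
    """Run one replicate Jan 1 - Dec 31; no carry-over between years.

    Fully deterministic given (weather, params, seed).
    """
    rng = np.random.default_rng(seed)
    state = initialize_population(params, rng)
    state.log_events = log_events
    solstice_doy = dt.date(weather.year, *params.diapause.solstice_month_day).timetuple().tm_yday
    equinox_doy = dt.date(weather.year, *params.diapause.frost_active_month_day).timetuple().tm_yday

    census_parts = []
    for env in _env_days(weather, params):
        step(state, env, params, solstice_doy, equinox_doy)
        c = state.census_counts()
        c.insert(0, "doy", env.doy)
        census_parts.append(c)

    census = pd.concat(census_parts, ignore_index=True)

    ecl_rows = []
    for doy, gens, repro in state._eclosion_acc:
        vals, counts = np.unique(gens, return_counts=True)
        for g, c in zip(vals, counts):
            ecl_rows.append((doy, int(g), REPRO_NAMES[repro], int(c)))
    eclosions = pd.DataFrame(
        ecl_rows, columns=["doy", "generation", "repro_state", "count"]
    )
    fo_rows = []
    for doy, gens in state._first_ovip_acc:
        vals, counts = np.unique(gens, return_counts=True)
        for g, c in zip(vals, counts):
            fo_rows.append((doy, int(g), int(c)))
    first_ovip = pd.DataFrame(fo_rows, columns=["doy", "generation", "count"])

    return SimulationResult(
        site_name=weather.site.name,
        year=weather.year,
        seed=seed,
        census=census,
        events=state.log,
        eclosions=eclosions,
        first_ovipositions=first_ovip,
        births=state.births,
        deaths=dict(state.deaths),
        daily_counters=pd.DataFrame(
            state.daily_counters, columns=["doy", "births", "deaths", "alive"]
        ),
        final_state=state if keep_final_state else None,
    )


def run_replicates(
    weather: WeatherSeries,
    params: LifeHistoryParams,
    n_replicates: int,
    base_seed: int,
    *,
    log_events: bool = False,
) -> list[SimulationResult]:
    """``n_replicates`` independent replicates with per-replicate seeds
    ``base_seed + k``; replicate k rerun alone reproduces the batch entry."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return [
        run_year(weather, params, base_seed + k, log_events=log_events)
        for k in range(n_replicates)
    ]
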