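import dataclasses

import numpy as np
import pandas as pd
import pytest

from halysim.environment import SyntheticClimateSpec, synthesize_weather
from halysim.life_history import LifeHistoryParams
from halysim.simulator import (
    REPRO_DIAPAUSE,
    REPRO_NONE,
    REPRO_VITELLOGENIC,
    STAGE_ADULT,
    STAGE_EGG,
    STAGE_N1,
    STAGE_N5,
    EnvDay,
    apply_development,
    apply_mortality,
    apply_reproduction,
    classify_eclosion,
    initialize_population,
    run_replicates,
    run_year,
    step,
    update_p_diapause,
)
from conftest import no_mortality_params


def make_env(doy=180, tmean=25.0, tmin=20.0, tmax=30.0, photoperiod=14.5, dd_preovip=None):
    if dd_preovip is None:
        dd_preovip = max(0.0, (tmin + tmax) / 2 - 12.7)
    return EnvDay(doy=doy, tmean=tmean, tmin=tmin, tmax=tmax,
                  photoperiod=photoperiod, dd_preovip=dd_preovip)


def fresh_state(params=None, n=None, seed=0):
    params = params or LifeHistoryParams()
    if n is not None:
        params = dataclasses.replace(params, initial_population=n)
    return initialize_population(params, np.random.default_rng(seed)), params


class TestInitialization:
    def test_default_founders_are_diapausing_adult_females(self):
        state, params = fresh_state()
        n = state.n
        assert n == 1000
        assert state.alive[:n].all()
        assert (state.stage[:n] == STAGE_ADULT).all()
        assert (state.generation[:n] == 0).all()
        assert state.female[:n].all()
        assert (state.repro[:n] == REPRO_DIAPAUSE).all()
        assert (state.preovip_dd[:n] == 0).all()

    def test_custom_initial_population(self):
        state, _ = fresh_state(n=10)
        assert state.alive_count() == 10

    def test_initial_census(self):
        state, _ = fresh_state()
        census = state.census_counts()
        assert census["count"].sum() == 1000
        assert set(census["stage"]) == {"ADULT"}


class TestDiapauseTermination:
    def test_terminates_on_first_long_day_before_solstice(self):
        state, params = fresh_state(n=20)
        env = make_env(doy=107, photoperiod=13.6)
        update_p_diapause(state, env, params.diapause, solstice_doy=172)
        assert (state.repro[: state.n] == REPRO_VITELLOGENIC).all()
        assert state.terminated

    def test_short_day_does_not_terminate(self):
        state, params = fresh_state(n=20)
        env = make_env(doy=50, photoperiod=11.0)
        update_p_diapause(state, env, params.diapause, solstice_doy=172)
        assert (state.repro[: state.n] == REPRO_DIAPAUSE).all()

    def test_long_day_after_solstice_does_not_terminate(self):
        state, params = fresh_state(n=20)
        env = make_env(doy=200, photoperiod=14.0)
        update_p_diapause(state, env, params.diapause, solstice_doy=172)
        assert (state.repro[: state.n] == REPRO_DIAPAUSE).all()

    def test_termination_is_irreversible(self):
        state, params = fresh_state(n=20)
        update_p_diapause(state, make_env(doy=110, photoperiod=13.6),
                          params.diapause, solstice_doy=172)
        # a later short day must not revert anyone
        update_p_diapause(state, make_env(doy=111, photoperiod=12.0),
                          params.diapause, solstice_doy=172)
        assert (state.repro[: state.n] == REPRO_VITELLOGENIC).all()


class TestEclosionClassification:
    def test_long_day_eclosion_is_vitellogenic(self):
        params = LifeHistoryParams()
        assert classify_eclosion(14.2, params.diapause) == REPRO_VITELLOGENIC

    def test_short_day_eclosion_is_diapause(self):
        params = LifeHistoryParams()
        assert classify_eclosion(13.0, params.diapause) == REPRO_DIAPAUSE

    def test_boundary_is_inclusive(self):
        params = LifeHistoryParams()
        assert classify_eclosion(13.5, params.diapause) == REPRO_VITELLOGENIC


class TestMortality:
    def _mixed_state(self):
        """Eggs, nymphs, one vitellogenic adult and one diapausing adult."""
        params = no_mortality_params()
        state, _ = fresh_state(params, n=2)
        state.repro[0] = REPRO_VITELLOGENIC
        state.add_agents(5, stage=STAGE_EGG, generation=1, female=True, repro=REPRO_NONE)
        state.add_agents(5, stage=STAGE_N5, generation=1, female=False, repro=REPRO_NONE)
        return state, params

    def test_frost_after_equinox_kills_nondiapausing(self):
        state, params = self._mixed_state()
        state.doy = 270
        apply_mortality(state, make_env(doy=270, tmin=-1.0, tmean=5.0, tmax=11.0),
                        params, equinox_doy=265)
        n = state.n
        alive = state.alive[:n]
        assert alive.sum() == 1
        assert state.repro[:n][alive][0] == REPRO_DIAPAUSE
        assert state.deaths["frost"] == 11

    def test_subzero_before_equinox_kills_nothing(self):
        state, params = self._mixed_state()
        state.doy = 100
        apply_mortality(state, make_env(doy=100, tmin=-1.0, tmean=5.0, tmax=11.0),
                        params, equinox_doy=265)
        assert state.alive_count() == 12
        assert not state.deaths

    def test_frost_at_exactly_zero_does_not_trigger(self):
        state, params = self._mixed_state()
        state.doy = 270
        apply_mortality(state, make_env(doy=270, tmin=0.0, tmean=5.0, tmax=10.0),
                        params, equinox_doy=265)
        assert state.alive_count() == 12

    def test_certain_survival_means_no_deaths(self):
        state, params = self._mixed_state()
        apply_mortality(state, make_env(doy=180, tmean=25.0, tmin=20.0, tmax=30.0),
                        params, equinox_doy=265)
        assert state.alive_count() == 12

    def test_zero_egg_survival_blocks_all_hatching(self, midlat_site, frostfree_weather):
        params = no_mortality_params()
        table = {s: [(0.0, 1.0), (40.0, 1.0)] for s in ("N1", "N2", "N3", "N4", "N5")}
        table["EGG"] = [(0.0, 0.0), (40.0, 0.0)]
        params = dataclasses.replace(
            params,
            survival=dataclasses.replace(params.survival, immature_daily_survival=table),
            initial_population=50,
        )
        result = run_year(frostfree_weather, params, seed=3)
        assert len(result.eclosions) == 0  # no egg ever reached N1, let alone adult
        assert "N1" not in set(result.census["stage"])


class TestDevelopment:
    def test_no_transitions_below_threshold(self):
        params = no_mortality_params()
        state, _ = fresh_state(params, n=1)
        state.add_agents(100, stage=STAGE_EGG, generation=1, female=True, repro=REPRO_NONE)
        apply_development(state, make_env(tmean=10.0), params)
        assert (state.stage[1 : state.n] == STAGE_EGG).all()

    def test_at_most_one_stage_advance_per_day(self):
        params = no_mortality_params()
        state, _ = fresh_state(params, n=1)
        state.add_agents(5000, stage=STAGE_EGG, generation=1, female=True,
                         repro=REPRO_NONE, hatch_p=1.0)
        apply_development(state, make_env(tmean=30.0), params)
        assert set(np.unique(state.stage[1 : state.n])) <= {STAGE_EGG, STAGE_N1}

    def test_identical_agents_can_diverge(self):
        params = no_mortality_params()
        state, _ = fresh_state(params, n=1)
        state.add_agents(2000, stage=STAGE_EGG, generation=1, female=True,
                         repro=REPRO_NONE, hatch_p=1.0)
        apply_development(state, make_env(tmean=25.0), params)
        stages = state.stage[1 : state.n]
        assert (stages == STAGE_EGG).any() and (stages == STAGE_N1).any()

    def test_eclosion_classified_by_days_photoperiod(self):
        params = no_mortality_params()
        state, _ = fresh_state(params, n=1)
        state.add_agents(500, stage=STAGE_N5, generation=1, female=True, repro=REPRO_NONE)
        apply_development(state, make_env(tmean=30.0, photoperiod=12.0), params)
        adults = state.stage[1 : state.n] == STAGE_ADULT
        assert adults.any()
        assert (state.repro[1 : state.n][adults] == REPRO_DIAPAUSE).all()

    def test_geometric_residence_time(self):
        # under repeated daily Bernoulli trials the expected residence is 1/p
        params = no_mortality_params()
        tmean = 23.81  # egg duration ~10 d -> p ~ 0.1
        from halysim.life_history import transition_probability
        p = transition_probability("egg_n1", tmean)
        n = 5000
        state, _ = fresh_state(params, n=1)
        state.add_agents(n, stage=STAGE_EGG, generation=1, female=True,
                         repro=REPRO_NONE, hatch_p=1.0)
        days = np.zeros(n)
        remaining = np.ones(n, dtype=bool)
        env = make_env(tmean=tmean)
        for day in range(1, 3000):
            apply_development(state, env, params)
            now_egg = state.stage[1 : 1 + n] == STAGE_EGG
            days[remaining & ~now_egg] = day
            remaining &= now_egg
            if not remaining.any():
                break
        assert not remaining.any()
        se = np.sqrt((1 - p) / p**2 / n)
        assert abs(days.mean() - 1 / p) <= 3 * se


class TestReproduction:
    def test_diapausing_female_never_oviposits(self):
        params = no_mortality_params()
        state, _ = fresh_state(params, n=10)
        for doy in range(180, 220):
            apply_reproduction(state, make_env(doy=doy), params)
        assert state.births == 0

    def test_first_clutch_on_threshold_crossing_day(self):
        params = no_mortality_params()
        state, _ = fresh_state(params, n=1)
        state.repro[0] = REPRO_VITELLOGENIC
        state.preovip_dd[0] = 67.9
        apply_reproduction(state, make_env(doy=150, dd_preovip=5.0), params)
        assert state.births == 26  # clutch laid the day 68 DD is reached

    def test_degenerate_schedule_arithmetic(self):
        # spreads 0: exactly 9 clutches of 26 eggs at 4-day intervals (32 days)
        params = no_mortality_params()
        state, _ = fresh_state(params, n=1)
        state.repro[0] = REPRO_VITELLOGENIC
        state.preovip_dd[0] = 68.0
        lay_days = []
        for doy in range(100, 160):
            before = state.births
            apply_reproduction(state, make_env(doy=doy, tmean=10.0, tmin=5, tmax=15,
                                               dd_preovip=0.0), params)
            if state.births > before:
                lay_days.append(doy)
        assert state.births == 9 * 26
        assert lay_days == list(range(100, 133, 4))
        assert lay_days[-1] - lay_days[0] == 32

    def test_offspring_generation_increments(self):
        params = no_mortality_params()
        state, _ = fresh_state(params, n=1)
        state.repro[0] = REPRO_VITELLOGENIC
        state.preovip_dd[0] = 68.0
        apply_reproduction(state, make_env(doy=150, dd_preovip=1.0), params)
        assert (state.generation[1 : state.n] == 1).all()
        assert (state.stage[1 : state.n] == STAGE_EGG).all()

    def test_sex_ratio_near_half(self):
        params = no_mortality_params()
        state, _ = fresh_state(params, n=200)
        state.repro[:200] = REPRO_VITELLOGENIC
        state.preovip_dd[:200] = 68.0
        apply_reproduction(state, make_env(doy=150, dd_preovip=1.0), params)
        frac = state.female[200 : state.n].mean()
        assert 0.45 < frac < 0.55


class TestStepAndYear:
    def test_midwinter_step_changes_nothing(self, warm_weather):
        params = LifeHistoryParams()
        state, _ = fresh_state(params)
        env = EnvDay(doy=1, tmean=warm_weather.tmean[0], tmin=warm_weather.tmin[0],
                     tmax=warm_weather.tmax[0], photoperiod=warm_weather.photoperiod[0],
                     dd_preovip=0.0)
        step(state, env, params, solstice_doy=172, equinox_doy=265)
        assert state.alive_count() == 1000
        assert not state.terminated

    def test_step_requires_matching_day(self):
        params = LifeHistoryParams()
        state, _ = fresh_state(params)
        with pytest.raises(ValueError, match="does not match"):
            step(state, make_env(doy=5), params, 172, 265)

    def test_daily_count_conservation(self, warm_weather):
        params = dataclasses.replace(LifeHistoryParams(), initial_population=100)
        result = run_year(warm_weather, params, seed=11)
        counters = result.daily_counters
        # active(t+1) = active(t) + births - deaths, from the initial 100
        expected = 100 + (counters["births"] - counters["deaths"]).cumsum()
        assert (counters["alive"] == expected).all()
        # census totals agree with the counters
        census_totals = result.census.groupby("doy")["count"].sum().reindex(
            counters["doy"], fill_value=0
        )
        assert (census_totals.to_numpy() == counters["alive"].to_numpy()).all()

    def test_same_seed_bit_identical(self, warm_weather):
        params = dataclasses.replace(LifeHistoryParams(), initial_population=100)
        a = run_year(warm_weather, params, seed=5)
        b = run_year(warm_weather, params, seed=5)
        pd.testing.assert_frame_equal(a.census, b.census)
        pd.testing.assert_frame_equal(a.events.to_frame(), b.events.to_frame())
        assert a.deaths == b.deaths

    def test_unreachable_photoperiod_freezes_population(self, warm_weather):
        params = no_mortality_params()
        params = dataclasses.replace(
            params,
            diapause=dataclasses.replace(params.diapause, critical_photoperiod=20.0),
            initial_population=200,
        )
        result = run_year(warm_weather, params, seed=2)
        final = result.census[result.census["doy"] == 365]
        assert final["count"].sum() == 200
        assert set(final["repro_state"]) == {"DIAPAUSE"}
        assert result.births == 0

    def test_benign_year_grows_population(self, frostfree_weather):
        params = no_mortality_params(initial_population=5)
        result = run_year(frostfree_weather, params, seed=4)
        final_total = result.census[result.census["doy"] == 365]["count"].sum()
        assert result.births > 0
        assert final_total > 5

    def test_no_mortality_and_no_frost_means_zero_deaths(self, frostfree_weather):
        params = no_mortality_params(initial_population=5)
        result = run_year(frostfree_weather, params, seed=4)
        assert result.deaths == {}

    def test_generation_ordering_in_event_log(self, warm_weather):
        params = dataclasses.replace(LifeHistoryParams(), initial_population=200)
        result = run_year(warm_weather, params, seed=9)
        ecl = result.eclosions
        ovip = result.events.to_frame().query("event == 'oviposition'")
        if (ecl["generation"] >= 1).any() and len(ovip):
            first_f1_eclosion = ecl[ecl["generation"] == 1]["doy"].min()
            f1_ovip = ovip[ovip["generation"] == 1]
            if len(f1_ovip):
                # F2 eggs cannot precede the first F1 adult
                assert f1_ovip["doy"].min() > first_f1_eclosion

    def test_diapausing_eclosions_follow_the_photoperiod_rule(self, warm_weather):
        params = dataclasses.replace(LifeHistoryParams(), initial_population=200)
        crit = params.diapause.critical_photoperiod
        result = run_year(warm_weather, params, seed=9)
        pp = warm_weather.photoperiod
        for _, row in result.eclosions.iterrows():
            daylen = pp[int(row["doy"]) - 1]
            if row["repro_state"] == "DIAPAUSE":
                assert daylen < crit
            else:
                assert daylen >= crit


class TestReplicates:
    def test_replicate_count_and_seed_derivation(self, warm_weather):
        params = dataclasses.replace(LifeHistoryParams(), initial_population=50)
        batch = run_replicates(warm_weather, params, 3, base_seed=100)
        assert len(batch) == 3
        solo = run_year(warm_weather, params, seed=102, log_events=False)
        pd.testing.assert_frame_equal(batch[2].census, solo.census)

    def test_single_replicate_equals_run_year(self, warm_weather):
        params = dataclasses.replace(LifeHistoryParams(), initial_population=50)
        batch = run_replicates(warm_weather, params, 1, base_seed=7)
        solo = run_year(warm_weather, params, seed=7, log_events=False)
        pd.testing.assert_frame_equal(batch[0].census, solo.census)

    def test_zero_replicates_rejected(self, warm_weather):
        with pytest.raises(ValueError):
            run_replicates(warm_weather, LifeHistoryParams(), 0, base_seed=0)
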