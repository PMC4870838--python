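"""Summary metrics: phenology curves, eclosion statistics, population sizes,
voltinism classification and validation-style comparisons.

Phenology is reported over three field-observable groups — young nymphs
(instars 1-3), old nymphs (instars 4-5) and adults — matching how beat-sheet
counts are recorded. "Final population" means diapausing adults alive on
Dec 31, broken out by generation; "maximum adult population" counts all
living adults regardless of reproductive state on the peak day.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import WeatherSeries, photoperiod_window
from .simulator import SimulationResult

__all__ = [
    "STAGE_GROUPS",
    "RunSummary",
    "ExperimentSummary",
    "group_census",
    "summarize_run",
    "classify_voltinism",
    "aggregate_replicates",
    "scale_relative",
    "coefficient_of_determination",
]

#: Field-observable stage groups used in validation plots.
STAGE_GROUPS = {
    "eggs": ("EGG",),
    "young_nymphs": ("N1", "N2", "N3"),
    "old_nymphs": ("N4", "N5"),
    "adults": ("ADULT",),
}

_STAGE_TO_GROUP = {s: g for g, ss in STAGE_GROUPS.items() for s in ss}


@dataclass
class DateStats:
    """Min/median/max day-of-year of a dated event set (weighted by count)."""

    min_doy: int
    median_doy: int
    max_doy: int

    @classmethod
    def from_counts(cls, doys: np.ndarray, counts: np.ndarray) -> "DateStats | None":
        if len(doys) == 0 or counts.sum() == 0:
            return None
        order = np.argsort(doys)
        doys, counts = np.asarray(doys)[order], np.asarray(counts)[order]
        cum = np.cumsum(counts)
        med = doys[np.searchsorted(cum, (cum[-1] + 1) // 2)]
        return cls(int(doys[0]), int(med), int(doys[-1]))


@dataclass
class RunSummary:
    """Scalar metrics of one replicate year."""

    site_name: str
    year: int
    seed: int
    max_adult_population: int
    max_total_population: int
    final_population_by_generation: dict[int, int]
    eclosion_dates: dict[int, DateStats]  # generation -> stats
    p_oviposition_dates: DateStats | None
    dd_total: float
    non_diapause_window: tuple[dt.date, dt.date] | None

    @property
    def final_population(self) -> int:
        return sum(self.final_population_by_generation.values())


def group_census(census: pd.DataFrame) -> pd.DataFrame:
    """Regroup a per-stage census into the field-observable stage groups."""
    out = census.copy()
    out["stage_group"] = out["stage"].map(_STAGE_TO_GROUP)
    return (
        out.groupby(["doy", "stage_group"], as_index=False)["count"].sum()
    )


def summarize_run(
    result: SimulationResult,
    weather: WeatherSeries,
    *,
    dd_base: float = 14.14,
    dd_upper: float | None = 35.76,
    critical_photoperiod: float = 13.5,
) -> RunSummary:
    """Compute the scalar run metrics from a replicate's census and events."""
    census = result.census
    adults = census[census["stage"] == "ADULT"]
    adult_daily = adults.groupby("doy")["count"].sum()
    total_daily = census.groupby("doy")["count"].sum()

    last_doy = int(census["doy"].max())
    final = adults[
        (adults["doy"] == last_doy) & (adults["repro_state"] == "DIAPAUSE")
    ]
    final_by_gen = {
        int(g): int(c)
        for g, c in final.groupby("generation")["count"].sum().items()
    }

    ecl_stats: dict[int, DateStats] = {}
    if len(result.eclosions):
        for g, sub in result.eclosions.groupby("generation"):
            stats = DateStats.from_counts(
                sub["doy"].to_numpy(), sub["count"].to_numpy()
            )
            if stats is not None:
                ecl_stats[int(g)] = stats

    p_ovip = None
    if len(result.first_ovipositions):
        sub = result.first_ovipositions[result.first_ovipositions["generation"] == 0]
        if len(sub):
            p_ovip = DateStats.from_counts(
                sub["doy"].to_numpy(), sub["count"].to_numpy()
            )

    return RunSummary(
        site_name=result.site_name,
        year=result.year,
        seed=result.seed,
        max_adult_population=int(adult_daily.max()) if len(adult_daily) else 0,
        max_total_population=int(total_daily.max()) if len(total_daily) else 0,
        final_population_by_generation=final_by_gen,
        eclosion_dates=ecl_stats,
        p_oviposition_dates=p_ovip,
        dd_total=weather.accumulate_degree_days(dd_base, dd_upper),
        non_diapause_window=photoperiod_window(
            weather.site.latitude, weather.year, critical_photoperiod,
            weather.daylength_coefficient,
        ),
    )


def classify_voltinism(
    summary: RunSummary,
) -> tuple[int, int | None, float | None]:
    """(number of filial generations with adults, dominant overwintering
    generation, F1 fraction of the final population).

    The dominant generation is the argmax of final diapausing adults (ties
    break to the lower generation); the F1 fraction is final F1 / final
    total. Both are ``None`` when no adults remain at year end.
    """
    n_gens = sum(1 for g in summary.eclosion_dates if g >= 1)
    final = summary.final_population_by_generation
    total = sum(final.values())
    if total == 0:
        return n_gens, None, None
    dominant = min(
        (g for g in final if final[g] == max(final.values())),
    )
    fraction_f1 = final.get(1, 0) / total
    return n_gens, dominant, fraction_f1


@dataclass
class ExperimentSummary:
    """Replicate-aggregated metrics for one site-year."""

    site_name: str
    year: int
    n_replicates: int
    scalars: pd.DataFrame  # one row per replicate (tidy, for external stats)
    daily_band: pd.DataFrame  # doy, stage_group, mean, lo, hi

    def scalar_means(self) -> pd.Series:
        return self.scalars.drop(columns=["site", "year", "seed"]).mean(numeric_only=True)

    def scalar_ranges(self) -> pd.DataFrame:
        num = self.scalars.drop(columns=["site", "year", "seed"])
        return num.agg(["min", "mean", "max"])


def _summary_row(s: RunSummary) -> dict:
    row = {
        "site": s.site_name,
        "year": s.year,
        "seed": s.seed,
        "max_adult_population": s.max_adult_population,
        "max_total_population": s.max_total_population,
        "final_population": s.final_population,
        "final_f1": s.final_population_by_generation.get(1, 0),
        "final_f2": s.final_population_by_generation.get(2, 0),
        "dd_total": s.dd_total,
    }
    for g in (1, 2):
        st = s.eclosion_dates.get(g)
        row[f"f{g}_eclosion_min"] = st.min_doy if st else np.nan
        row[f"f{g}_eclosion_median"] = st.median_doy if st else np.nan
        row[f"f{g}_eclosion_max"] = st.max_doy if st else np.nan
    row["p_ovip_min"] = s.p_oviposition_dates.min_doy if s.p_oviposition_dates else np.nan
    row["p_ovip_median"] = s.p_oviposition_dates.median_doy if s.p_oviposition_dates else np.nan
    row["p_ovip_max"] = s.p_oviposition_dates.max_doy if s.p_oviposition_dates else np.nan
    return row


def aggregate_replicates(
    results: list[SimulationResult],
    weather: WeatherSeries,
    *,
    percentiles: tuple[float, float] = (2.5, 97.5),
    **summary_kwargs,
) -> ExperimentSummary:
    """Aggregate replicate runs: per-day mean and percentile band of the
    grouped census, plus a tidy per-replicate scalar table."""
    if not results:
        raise ValueError("need at least one replicate")
    scalar_rows = [
        _summary_row(summarize_run(r, weather, **summary_kwargs)) for r in results
    ]
    scalars = pd.DataFrame(scalar_rows)

    grouped = []
    for k, r in enumerate(results):
        g = group_census(r.census)
        g["replicate"] = k
        grouped.append(g)
    stacked = pd.concat(grouped, ignore_index=True)
    # absent (doy, group) combinations in a replicate are zero counts
    full = (
        stacked.pivot_table(
            index=["doy", "stage_group"], columns="replicate", values="count",
            fill_value=0,
        )
        .reindex(columns=range(len(results)), fill_value=0)
    )
    lo, hi = percentiles
    band = pd.DataFrame(
        {
            "mean": full.mean(axis=1),
            "lo": np.percentile(full.to_numpy(), lo, axis=1),
            "hi": np.percentile(full.to_numpy(), hi, axis=1),
        }
    ).reset_index()
    return ExperimentSummary(
        site_name=results[0].site_name,
        year=results[0].year,
        n_replicates=len(results),
        scalars=scalars,
        daily_band=band,
    )


def scale_relative(series: np.ndarray | pd.Series, reference_max: float):
    """Scale daily counts relative to a reference maximum (validation plots
    scale both observed and predicted populations to the observed peak)."""
    if reference_max <= 0:
        raise ValueError("reference_max must be positive")
    return series / reference_max


def coefficient_of_determination(
    observed: np.ndarray | pd.Series, predicted: np.ndarray | pd.Series
) -> float | None:
    """R-squared of predictions against observations.

    ``R^2 = 1 - SS_res / SS_tot``; ``None`` when the observations have zero
    variance (the statistic is undefined there).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be aligned, length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return None
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot
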