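"""Reproducible experiment drivers: photoperiod sensitivity and multi-site
multi-year runs.

The photoperiod-sensitivity driver runs the same site-year under several
candidate critical photoperiods with identical weather and paired seeds
(common random numbers), so arm differences reflect the cue alone. The
multi-site driver sweeps a site x year grid, sourcing weather from a CSV
directory or per-site synthetic presets, and consolidates the population
metrics into one cross-site table. Every experiment writes a manifest (seeds,
parameter hash, weather checksums) sufficient to reproduce it bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .environment import (
    SiteProfile,
    SyntheticClimateSpec,
    WeatherSeries,
    photoperiod_window,
    read_weather_csv,
    synthesize_weather,
)
from .life_history import LifeHistoryParams, save_params, _params_to_dict
from .metrics import ExperimentSummary, aggregate_replicates
from .simulator import run_replicates
from .sites import DEFAULT_SITES, get_preset

__all__ = [
    "ExperimentConfig",
    "load_weather",
    "run_photoperiod_sensitivity",
    "run_multisite",
    "write_manifest",
]


@dataclass
class ExperimentConfig:
    """Configuration for experiment drivers.

    ``weather_csv_dir`` takes precedence; otherwise each site draws synthetic
    weather from ``synthetic_presets[site.name]`` (a preset name or a
    :class:`SyntheticClimateSpec`).
    """

    sites: list[SiteProfile] = field(
        default_factory=lambda: list(DEFAULT_SITES.values())
    )
    years: list[int] = field(default_factory=lambda: [2007])
    replicates: int = 100
    critical_photoperiods: list[float] = field(default_factory=lambda: [13.5])
    weather_csv_dir: str | Path | None = None
    synthetic_presets: dict[str, str | SyntheticClimateSpec] = field(default_factory=dict)
    params: LifeHistoryParams = field(default_factory=LifeHistoryParams)
    base_seed: int = 0
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("need at least one site")
        if not self.years:
            raise ValueError("need at least one year")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _site_year_seed(base_seed: int, site: SiteProfile, year: int) -> int:
    """Deterministic per-site-year seed (stable across run order)."""
    tag = zlib.crc32(f"{site.name}|{year}".encode())
    return (base_seed * 1_000_003 + tag) % (2**31)


def load_weather(
    config: ExperimentConfig, site: SiteProfile, year: int
) -> WeatherSeries:
    """Weather for one site-year, from CSV dir or synthetic preset."""
    dlc = config.params.diapause.daylength_coefficient
    if config.weather_csv_dir is not None:
        path = Path(config.weather_csv_dir) / f"{site.name.replace(' ', '_')}_{year}.csv"
        if not path.exists():
            raise FileNotFoundError(f"no weather file {path} for {site.name} {year}")
        return read_weather_csv(path, site, year, daylength_coefficient=dlc)
    preset = config.synthetic_presets.get(site.name)
    if preset is None:
        raise ValueError(
            f"no weather source for {site.name}: set weather_csv_dir or a "
            f"synthetic preset for this site"
        )
    spec = get_preset(preset) if isinstance(preset, str) else preset
    spec = dataclasses.replace(spec, seed=_site_year_seed(config.base_seed, site, year))
    return synthesize_weather(spec, site, year, daylength_coefficient=dlc)


def run_photoperiod_sensitivity(
    config: ExperimentConfig, site: SiteProfile, year: int
) -> tuple[dict[float, ExperimentSummary], pd.DataFrame]:
    """Run one site-year under each candidate critical photoperiod.

    All arms share identical weather and per-replicate seeds (paired
    comparison). Returns per-arm summaries and a table of pairwise percent
    differences in final F1/F2 adult and total populations.
    """
    weather = load_weather(config, site, year)
    seed = _site_year_seed(config.base_seed, site, year)
    summaries: dict[float, ExperimentSummary] = {}
    for cp in config.critical_photoperiods:
        params = dataclasses.replace(
            config.params,
            diapause=dataclasses.replace(config.params.diapause, critical_photoperiod=cp),
        )
        results = run_replicates(weather, params, config.replicates, seed)
        summaries[cp] = aggregate_replicates(
            weather=weather, results=results, critical_photoperiod=cp
        )

    rows = []
    metric_cols = ("final_f1", "final_f2", "final_population", "max_adult_population")
    for a, b in itertools.combinations(config.critical_photoperiods, 2):
        ma = summaries[a].scalars[list(metric_cols)].mean()
        mb = summaries[b].scalars[list(metric_cols)].mean()
        for col in metric_cols:
            denom = mb[col]
            rows.append(
                {
                    "arm_a_h": a,
                    "arm_b_h": b,
                    "metric": col,
                    "mean_a": ma[col],
                    "mean_b": mb[col],
                    "percent_diff_a_vs_b": (
                        100.0 * (ma[col] - mb[col]) / denom if denom else float("nan")
                    ),
                }
            )
    return summaries, pd.DataFrame(rows)


def run_multisite(
    config: ExperimentConfig,
) -> tuple[dict[tuple[str, int], ExperimentSummary], pd.DataFrame, list[tuple[str, int, str]]]:
    """Sweep the site x year grid.

    Returns (summaries keyed by (site name, year), a consolidated cross-site
    table of max adult / final population / DD totals plus photoperiod
    windows, and a list of (site, year, error) for site-years whose weather
    was unavailable — those are recorded and skipped, not fatal).
    """
    summaries: dict[tuple[str, int], ExperimentSummary] = {}
    errors: list[tuple[str, int, str]] = []
    rows = []
    cp = config.params.diapause.critical_photoperiod
    for site, year in itertools.product(config.sites, config.years):
        try:
            weather = load_weather(config, site, year)
        except (FileNotFoundError, ValueError) as exc:
            errors.append((site.name, year, str(exc)))
            continue
        seed = _site_year_seed(config.base_seed, site, year)
        results = run_replicates(weather, config.params, config.replicates, seed)
        summary = aggregate_replicates(
            weather=weather, results=results, critical_photoperiod=cp
        )
        summaries[(site.name, year)] = summary
        means = summary.scalar_means()
        window = photoperiod_window(
            site.latitude, year, cp, config.params.diapause.daylength_coefficient
        )
        rows.append(
            {
                "site": site.name,
                "latitude": site.latitude,
                "year": year,
                "window_first": window[0] if window else None,
                "window_last": window[1] if window else None,
                "mean_max_adult_population": means["max_adult_population"],
                "mean_final_population": means["final_population"],
                "mean_final_f1": means["final_f1"],
                "mean_final_f2": means["final_f2"],
                "dd_total": means["dd_total"],
            }
        )
    return summaries, pd.DataFrame(rows), errors


def write_manifest(
    config: ExperimentConfig,
    out_dir: str | Path,
    weather_checksums: dict[str, str] | None = None,
) -> Path:
    """Write a key-value manifest sufficient to reproduce the experiment."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params_yaml = yaml.safe_dump(_params_to_dict(config.params), sort_keys=True)
    manifest = {
        "sites": [
            {"name": s.name, "latitude": s.latitude, "longitude": s.longitude}
            for s in config.sites
        ],
        "years": list(config.years),
        "replicates": config.replicates,
        "critical_photoperiods": list(config.critical_photoperiods),
        "base_seed": config.base_seed,
        "weather_csv_dir": str(config.weather_csv_dir) if config.weather_csv_dir else None,
        "synthetic_presets": {
            k: v if isinstance(v, str) else dataclasses.asdict(v)
            for k, v in config.synthetic_presets.items()
        },
        "params_sha256": hashlib.sha256(params_yaml.encode()).hexdigest(),
        "weather_checksums": weather_checksums or {},
    }
    path = out_dir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    save_params(config.params, out_dir / "params.yaml")
    return path
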