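# Methods

## Model structure

The simulator is a stochastic individual-based model on a daily grid. State
per agent: life stage ∈ {EGG, N1…N5, ADULT}, generation (0 = overwintered P,
1 = F1, …), sex, reproductive state for adults (DIAPAUSE or VITELLOGENIC,
irreversible), a pre-oviposition degree-day accumulator, and — once drawn —
a personal reproductive schedule. A replicate year starts Jan 1 with 1000
diapausing adult females (generation P) and ends Dec 31 with no carry-over;
nothing is spatial, and no biotic mortality (predation, parasitism) or
host-plant effect is modeled.

The five processes, applied in a fixed daily order (diapause update →
mortality → development → reproduction → census):

**Day length.** CBM model (Forsythe et al. 1995):
θ = 0.2163108 + 2·atan(0.9671396·tan(0.00860·(J−186))),
φ = asin(0.39795·cos θ),
D = 24 − (24/π)·acos[(sin p′ + sin L′·sin φ)/(cos L′·cos φ)],
with latitude L and daylength coefficient p in radians (p′ = 0.8333° by
default: the sun's upper limb with standard atmospheric refraction). J is
the raw day of year; no leap correction (the formula is defined on J only).
Supported latitudes are |L| ≤ 66° so the acos argument stays in [−1, 1].
With p = 0.8333° the computed first day with D ≥ 13.5 h lands on the
published non-diapause onset dates at six of the eight registry sites
exactly and within 1–2 days at the remaining mid-Atlantic latitudes; the
source's daylength convention is not stated, so we treat p as a calibration
knob and do not force agreement below the formula's day resolution.

**Diapause.** A single critical photoperiod (default 13.5 h, the value that
maximizes population growth within the 13.5–14.75 h range reported for the
species) serves both as the spring termination cue — all P adults become
vitellogenic on the first day D ≥ CP on/before the summer solstice (Jun 21)
— and as the eclosion-day classifier for filial adults year-round: an adult
eclosing under D ≥ CP (inclusive boundary) joins the vitellogenic track,
otherwise it is in diapause for the rest of the year. Reproductive state is
not plastic in either direction.

**Development.** Expected stage durations are linear in daily mean
temperature (durations in days):

| process | slope (d/°C) | intercept (d) |
|---|---|---|
| egg → N1 | −0.9843 | 33.438 |
| N1 → N2 | −0.3728 | 14.68 |
| N2 → N3 | −0.6119 | 25.249 |
| N3 → N4 | −0.3986 | 17.602 |
| N4 → N5 | −0.4408 | 19.036 |
| N5 → adult | −0.5332 | 24.147 |

These regressions are published as "development rate" but the negative
slopes identify them as durations (days falling with temperature); the
daily Bernoulli transition probability is therefore 1/duration, with the
duration clamped at ≥ 1 day so the probability stays in [0, 1]. Development
proceeds only for Tmean in the inclusive band [14.17, 35.76] °C; outside
it the probability is 0. A consequence of daily Bernoulli transitions is a
geometric residence time per stage: the mean is the fitted duration, but
the variance is large and a small fraction of agents develops much faster
than the fitted mean. Realized eclosion distributions are correspondingly
wide.

**Reproduction.** Vitellogenic females accumulate average-method
degree-days above 12.7 °C (no upper cutoff) from the day they enter the
vitellogenic state — P females from the termination day, filial females
from eclosion. On reaching 68 DD₁₂.₇ a female draws her schedule and lays
her first clutch the same day, then every `interval` days until her event
count is exhausted or she dies. Clutches enter the population as whole egg
cohorts; hatch success (hatched/clutch, per mother) is applied as an extra
Bernoulli at the egg → N1 transition, so egg-stage censuses count whole
clutches while non-hatching eggs never become nymphs. Offspring are female
with probability 0.5. Schedule draws are truncated normals (≥ 0; intervals
≥ 1 d) rounded to integers, with hatched capped at clutch size:

| quantity | mean (published) | default SD |
|---|---|---|
| oviposition events | 9.33 (± 0.19 SEM) | 2.0 |
| clutch size | 26.08 (± 0.31 SEM) | 3.0 |
| hatched per clutch | 21.30 (± 0.48 SEM) | 4.0 |
| inter-clutch interval (d) | 4.32 (± 0.41 SEM) | 1.5 |

Only the SEMs of the means are published; per-female SDs are not. We do not
use the SEMs as individual-level SDs: an SD of 0.19 around 9.33 concentrates
nearly all rounded draws on the integer 9 and biases the population mean to
9.19, so the simulated colony would not reproduce its own source statistics.
The default SDs above are plausible individual-level spreads under which
rounding is unbiased and 10,000-draw means recover 9.33 events and
9.33 × 26.08 ≈ 243.3 total eggs per female to within Monte-Carlo error.
All four spreads are configurable in the parameter file.

**Survivorship.** Three channels. (i) Immatures: a per-stage table of
(temperature, daily survival) nodes, linearly interpolated and clamped.
(ii) Adults: vitellogenic P adults draw a daily post-termination mortality
(default 0.005); vitellogenic filial adults a separate rate (default 0);
diapausing adults draw none. (iii) Frost: after the autumnal equinox
(Sep 22, configurable), any day with Tmin strictly below 0 °C kills every
egg, nymph, and vitellogenic adult deterministically. **The immature table
and adult rates shipped as defaults are synthetic placeholders** — the
stage × temperature survivorship and overwintered-adult mortality schedules
this model calls for exist only in external laboratory studies and are not
reprinted in a reusable form. The placeholder band (0.88–0.90 per day,
dipping toward the thermal limits) was set so that season-long egg-to-adult
survival is of order 10⁻², putting year-end populations from 1000 founders
at the 10³ scale and peak adult populations near 10⁴ — the orders reported
for productive sites — while keeping 100-replicate runs tractable. Users
with access to measured schedules should supply them via the parameter
file; absolute abundances under the placeholders are indicative only.

## Synthetic weather

`synthesize_weather` draws Tmean(d) = μ − A·cos(2π(d − d_peak + 182.5)/365)
plus AR(1) noise (marginal SD σ, lag-1 autocorrelation ρ), with Tmin/Tmax
at ∓ half the diurnal range. Presets cover five archetypes (warm-humid,
cool-maritime, cold-continental, hot-arid, subtropical); the warm-humid
default (μ = 12 °C, A = 14 °C, range 10 °C, σ = 3 °C, ρ = 0.6, peak day
200) mimics a mid-Atlantic annual cycle: sub-zero winter minima (so the
frost rule engages), a ~1100–1400 DD₁₄.₁₄ year, and a photoperiod window
opening in late April at 40°N. What the generator does **not** emulate:
synoptic weather (multi-day heat waves and cold snaps beyond AR(1)
persistence), skewed diurnal cycles, precipitation-coupled cloudiness, or
inter-annual trends. Tests passing on synthetic weather therefore validate
the mechanics and qualitative climate contrasts, not site-specific
predictions — for those, feed measured station records through
`read_weather_csv` (ISO dates; °C, or tenths-of-°C via the `tenths` flag;
gaps ≤ 5 days interpolated, longer gaps rejected).

## Numerical and design choices

- **Sub-step order** (diapause → mortality → development → reproduction) is
  fixed and only affects same-day edge cases; e.g. an agent cannot die and
  transition on the same day.
- **Boundaries**: development thresholds inclusive; eclosion at exactly the
  critical photoperiod counts as long-day; frost requires Tmin strictly
  < 0 °C; the equinox day itself is frost-free (`doy > equinox`).
- **Seeds**: one `numpy` Generator per replicate, seeded `base_seed + k`;
  replicate k rerun alone is bit-identical to replicate k of a batch.
  Photoperiod-sensitivity arms share weather and replicate seeds (common
  random numbers) by default, sharpening paired contrasts.
- **Vectorization**: the population is a structure of numpy arrays; dead
  agents are compacted away periodically but persist in the event log. The
  per-agent contracts (one trial per day, at most one stage advance) are
  unchanged by this. A full site-year (1000 founders, ~10⁶ births, 100
  replicates) runs in roughly two minutes on one CPU core.
- **Metrics**: "final population" counts diapausing adults alive on Dec 31
  by generation (vitellogenic stragglers are frost-killed before then in
  every frost-prone climate); "maximum adult population" counts all living
  adults on the peak day regardless of reproductive state. Yearly DD totals
  use base 14.14 °C with ceiling 35.76 °C (the full-life-cycle base), both
  configurable. R² for validation-style comparisons is 1 − SSres/SStot and
  is reported as undefined for zero-variance observations.
- **Generations** are uncapped; warm years under mild survival produce
  F3–F5 cohorts whose late ecloses enter diapause. Census and metrics
  report per-generation columns dynamically.
- **Parameter file**: one YAML document with sections mirroring the
  parameter dataclasses; absent keys take the defaults above; save → load
  round-trips exactly.

## Photoperiod sensitivity: what orders with the cue

On a warm synthetic year, peak total population orders with the cue as
expected — 13.5 h ≥ 14.0 h ≥ 14.5 h — because a shorter critical
photoperiod opens a reproductive window up to two months longer and egg
production tracks the window. The year-end *diapausing* population responds
the other way under the placeholder survival schedules: a higher critical
photoperiod moves the induction date earlier, capturing the large
late-season eclosion wave into the frost-immune diapause class, whereas
under 13.5 h those adults remain vitellogenic and die at first frost. Which
effect dominates the year-end census depends on how sharply the survival
schedule attenuates late cohorts; with the placeholder schedules the
capture effect wins across the survival (0.80–0.90/day) and climate-shape
ranges we probed. Year-end orderings should therefore be interpreted only
jointly with a trusted survival schedule.

## Known limitations

- Absolute population sizes inherit the placeholder survival schedules.
- A single, universal critical photoperiod for termination and induction;
  no individual variation, no temperature modulation of diapause.
- The daylength convention (p = 0.8333°) is a calibration; onset dates at
  mid-Atlantic latitudes can differ from other conventions by 1–3 days.
- Geometric stage-residence variance (inherent to daily Bernoulli
  transitions) widens phenological distributions relative to
  distributed-delay formulations.
- No density dependence: populations can grow without bound in benign,
  mortality-free configurations.
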