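"""Non-diapause windows across the default site registry.

For each site the first and last calendar dates whose day length reaches the
13.5 h critical photoperiod bound the period in which overwintered adults
terminate diapause (spring side) and newly eclosed adults avoid diapause
(autumn side). Low-latitude sites never reach higher candidate thresholds.
"""

from halysim import DEFAULT_SITES, photoperiod_window

YEAR = 2007

print(f"Non-diapause windows (day length >= 13.5 h), {YEAR}:")
for site in sorted(DEFAULT_SITES.values(), key=lambda s: -s.latitude):
    w = photoperiod_window(site.latitude, YEAR, 13.5)
    print(f"  {site.name:14s} {site.latitude:6.2f}N  "
          f"{w[0]:%b %d} - {w[1]:%b %d}  ({(w[1]-w[0]).days} days)")

print("\nAt higher critical photoperiods the window shrinks or vanishes:")
for crit in (14.0, 14.5):
    w = photoperiod_window(25.47, YEAR, crit)
    status = f"{w[0]:%b %d} - {w[1]:%b %d}" if w else "never reached"
    print(f"  Homestead FL at {crit} h: {status}")
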