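"""Generate a synthetic site-year and accumulate degree-days over it.

The generator superimposes AR(1) noise on a sinusoidal annual temperature
cycle; the same seed always reproduces the same series. Degree-days here use
the daily average method above a 14.14 degC base with a 35.76 degC ceiling —
the thermal currency of the insect's full life cycle (537.63 DD required on
average).
"""

import dataclasses
import datetime as dt

from halysim import SYNTHETIC_PRESETS, SiteProfile, synthesize_weather

site = SiteProfile("Bridgeton NJ", 39.43, -75.23)
spec = dataclasses.replace(SYNTHETIC_PRESETS["warm-humid"], seed=7)
weather = synthesize_weather(spec, site, 2007)

print(f"{site.name} {weather.year}: {len(weather)} days, "
      f"checksum {weather.checksum()}")
print(f"  coldest tmin {weather.tmin.min():6.1f} degC, "
      f"warmest tmax {weather.tmax.max():5.1f} degC")

total = weather.accumulate_degree_days(14.14, 35.76)
print(f"  yearly accumulation: {total:.1f} DD (base 14.14, ceiling 35.76)")
print(f"  -> enough thermal time for ~{total/537.63:.1f} full life cycles")

june = weather.accumulate_degree_days(12.7, None,
                                      dt.date(2007, 6, 1), dt.date(2007, 6, 30))
print(f"  June alone supplies {june:.1f} DD12.7 "
      f"(pre-oviposition needs 68 DD12.7)")
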