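"""Simulate a production year for both manure-management systems.

Runs the four-growing-period calendar for the long-storage (LS) and
short-storage (SS) rooms on the same synthetic Dutch weather year, then
annualizes emissions per pig place.
"""

from pigemit.driver import annualize_outputs, run_year
from pigemit.scenario import ls_preset, ss_preset
from pigemit.validation import reduction_percent
from pigemit.weather import weather_fixture

weather = weather_fixture(seed=1, n_days=380)
ls = annualize_outputs(run_year(ls_preset(), weather))
ss = annualize_outputs(run_year(ss_preset(), weather))

print(f"{'kg / yr / pig place':>28} {'LS':>8} {'SS':>8}")
rows = [
    ("CH4 total", "ch4_total_kg_yr_place"),
    ("  from manure pit", "ch4_pit_kg_yr_place"),
    ("  enteric", "ch4_enteric_kg_yr_place"),
    ("NH3 total", "nh3_total_kg_yr_place"),
    ("  from manure pit", "nh3_pit_kg_yr_place"),
    ("  from fouled floor", "nh3_floor_kg_yr_place"),
]
for label, key in rows:
    print(f"{label:>28} {ls[key]:8.2f} {ss[key]:8.2f}")

print(
    f"\nSimulated reduction potential of short storage: "
    f"CH4 {reduction_percent(ls['ch4_total_kg_yr_place'], ss['ch4_total_kg_yr_place']):.0f}%, "
    f"NH3 {reduction_percent(ls['nh3_total_kg_yr_place'], ss['nh3_total_kg_yr_place']):.0f}%."
)
print(
    "Daily flushing removes the methane substrate before it degrades, so "
    "the SS methane total sits close to the ~1.5 kg/pig/yr enteric floor, "
    "while the sloped shallow channels plus dilution cut the ammonia term."
)
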