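"""Run the four standard scenarios and compare land, emissions, population.

The baseline (agribase) calibrates to the instance's current state; the
three circularity scenarios re-optimize the food system. The percent
changes printed at the end are the headline comparison: how much
agricultural land and per-capita greenhouse gas the circular redesigns
save, and how many more people the land could feed.
"""

import circfood as cf

inst = cf.generate_instance(seed=1)
reports = {name: cf.run_scenario(inst, preset())
           for name, preset in cf.PRESETS.items()}

print(f"{'scenario':10s} {'land (ha)':>12s} {'CO2e (kg/cap)':>14s} "
      f"{'people fed':>12s} {'violations':>10s}")
for name, rep in reports.items():
    print(f"{name:10s} {rep.total_land_ha:12,.0f} "
          f"{rep.co2e_per_capita_kg:14.1f} {rep.population_fed:12,.0f} "
          f"{len(rep.violations):10d}")

base = reports["agribase"]
print("\nchanges vs the calibrated baseline:")
print(f"  land, supply-side circularity : "
      f"{cf.percent_change(base.total_land_ha, reports['ciragri'].total_land_ha):+d}%")
print(f"  land, healthy circular diet   : "
      f"{cf.percent_change(base.total_land_ha, reports['cirhealth'].total_land_ha):+d}%")
print(f"  CO2e per capita, healthy diet : "
      f"{cf.percent_change(base.co2e_per_capita_kg, reports['cirhealth'].co2e_per_capita_kg):+d}%")
print(f"  population fed, max-population: "
      f"{cf.percent_change(base.population_fed, reports['cirpop'].population_fed):+d}%")
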