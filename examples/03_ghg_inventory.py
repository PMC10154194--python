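"""Break a solved scenario's emissions down by source category and gas.

Solves the healthy-circular-diet scenario and prints the inventory:
enteric CH4, manure management, soil and grassland N2O, compost, fertilizer
production and transport, each weighted to CO2 equivalents (100-yr GWPs:
biogenic CH4 x 28, N2O x 265). The totals show which sources dominate the
food system's footprint after the redesign.
"""

import circfood as cf

inst = cf.generate_instance(seed=1)
sol = cf.solve(cf.build_problem(inst, cf.cirhealth()))
inv = sol.ghg

print(f"{'category':22s} {'gas':4s} {'kg gas/yr':>14s} {'kg CO2e/yr':>14s}")
for (cat, gas), kg in sorted(inv.entries.items()):
    w = {"CH4": inv.gwp_ch4, "N2O": inv.gwp_n2o, "CO2": 1.0}[gas]
    print(f"{cat:22s} {gas:4s} {kg:14,.0f} {kg * w:14,.0f}")
total = inv.total_co2e()
print(f"\ntotal: {total:,.0f} kg CO2e/yr "
      f"({total / sol.population_fed:.1f} kg CO2e per capita per year)")
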