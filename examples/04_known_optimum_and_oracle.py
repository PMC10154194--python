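"""Cross-check the solver against analytically known and brute-force optima.

Two independent checks of the optimizer: (1) a constructed instance where
one crop strictly dominates the alternative, so the land minimum is known
in closed form; (2) random tiny crop-only instances whose optimum is found
by exhaustive grid search over per-capita diets (never through the LP).
Both should agree with the solver - the first to 1e-6 relative, the second
to within the grid resolution (~1%).
"""

import circfood as cf

inst, expected = cf.generate_known_optimum_instance(seed=7)
sol = cf.solve(cf.build_problem(inst, cf.cirhealth()))
rel = abs(sol.objective_value - expected.objective_ha) / expected.objective_ha
print(f"known-optimum instance: expected {expected.objective_ha:,.2f} ha, "
      f"solver {sol.objective_value:,.2f} ha (rel error {rel:.2e})")
print(f"  binding nutrient: {expected.binding_nutrient}, "
      f"diet {expected.diet_g_day:.1f} g/day of the dominant crop")

print("\nbrute-force oracle on random tiny instances:")
scen = cf.cirhealth()
for seed in (1, 2, 3, 4, 5):
    tiny = cf.generate_tiny_instance(seed)
    lp = cf.solve(cf.build_problem(tiny, scen))
    grid = cf.brute_force_optimum(tiny, scen, grid_g_day=2.0,
                                  max_g_day=1800.0)
    gap = abs(grid - lp.objective_value) / lp.objective_value
    print(f"  seed {seed}: solver {lp.objective_value:12,.1f} ha, "
          f"grid search {grid:12,.1f} ha, gap {gap:.4%}")
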