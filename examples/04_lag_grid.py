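"""A miniature fisheries-lag grid: which (group, lag) cells light up?

Generates site-year paired observations from the hurdle-gamma process
with a true biomass-removal exponent of 0.3 for emperors at lags 1-2 and
zero elsewhere, fits one hurdle-gamma model per cell, and prints the
evidence classification per cell.
"""

import numpy as np

from cotslink import TruthParams, WorldConfig, run_fisheries_lag_grid
from cotslink.simulate import simulate_paired_site_years

config = WorldConfig(n_grid_sites=25, reefs_per_site=1, years=(2000, 2011),
                     tows_per_reef_year=1, seed=4)
truth = TruthParams(biomass_slopes={("Lethrinidae", 1): 0.3, ("Lethrinidae", 2): 0.3})

cells = {}
rng = np.random.default_rng(44)
for group in ("Lethrinidae", "Labridae"):
    for lag in (1, 2, 3):
        cells[(group, lag)] = simulate_paired_site_years(config, truth, group, lag, rng=rng)

grid = run_fisheries_lag_grid(cells, warmup=1500, iterations=1500, seed=40)
cols = ["group", "lag", "median", "ci95_low", "ci95_high", "prob_above_zero", "evidence_class"]
print(grid[cols].round(3).to_string(index=False))
print("\nThe exponent is the slope of log CoTS density on log retained")
print("catch; cells with truth 0.3 (emperors, lags 1-2) should reach the")
print(">80% or >95% class, null cells should mostly read 'none'.")
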