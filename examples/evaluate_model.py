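"""Tune and evaluate a niche model: AICc grid, partial ROC, jackknife.

Runs a small feature-class x regularization-multiplier grid ranked by
small-sample-corrected AIC, then scores the selected model with the
partial-ROC AUC ratio, jackknife training gains, and per-variable
percent contributions.
"""

import numpy as np

from coastsdm import compute_bioclim, window_average
from coastsdm.evaluation import jackknife_gain, partial_roc, percent_contribution, tune
from coastsdm.grids import GridSpec
from coastsdm.maxent import sample_background
from coastsdm.synthetic import ClimateScenario, TruthModel, generate_climate, generate_occurrences
from coastsdm.workflow import occurrences_to_env

grid = GridSpec(n_rows=40, n_cols=50, west=-95.0, south=0.0, cell_size=0.6)
scenario = ClimateScenario(grid=grid, seed=3)
series = generate_climate(scenario, range(2013, 2019))
stack = compute_bioclim(window_average(series, (2013, 2018)))

variables = [6, 12]
occ = generate_occurrences(TruthModel({6: 0.45}), stack, m=300, seed=3)
_, bg_cells = sample_background(stack, n=1200, seed=3, variables=variables)
rows, cols = np.unravel_index(bg_cells, stack.spec.shape)
bg_env = np.column_stack([stack.bio[v].values[rows, cols] for v in variables])
pres_env = occurrences_to_env(occ, stack, variables)
pres_lonlat = np.column_stack([occ.lons, occ.lats])

result = tune(
    pres_env, bg_env, variables,
    presence_lonlat=pres_lonlat, spec=stack.spec,
    combos=("l", "lq", "lqh"), multipliers=(0.5, 1.0, 2.0),
)
print("candidate grid (combo, multiplier, delta-AICc, k, CV omission):")
for c in sorted(result.candidates, key=lambda c: c.aicc)[:5]:
    print(f"  {c.combo:<4} x{c.multiplier:<3} dAICc={c.delta_aicc:7.2f} "
          f"k={c.k:<3} omission={c.mean_cv_omission:.3f}")
best = result.selected
print(f"selected: {best.combo} x{best.multiplier} (delta-AICc = 0 by definition)")

model = result.selected_model
land_pred = model.cloglog(bg_env)
ratio, p = partial_roc(model.cloglog(pres_env), land_pred, n_boot=500, seed=3)
print(f"\npartial ROC: mean AUC ratio {ratio:.3f} (1 = random, 2 = perfect), p = {p:.3f}")

gains = jackknife_gain(pres_env, bg_env, variables, best.combo, best.multiplier)
print("jackknife of training gain (alone / without):")
for v, (alone, without) in gains.items():
    print(f"  BIO{v}: alone={alone:.3f} without={without:.3f}")
print("percent contribution:",
      {f"BIO{v}": round(c, 1) for v, c in percent_contribution(model).items()})
print("\nThe cold-extreme variable carries the model, matching the truth "
      "the presences were drawn from.")
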