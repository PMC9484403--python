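"""Derive the 19 bioclimatic variables from monthly climate normals.

Builds a small synthetic monthly climate series (latitudinal temperature
gradient, seasonal cycle), averages it over a 6-year window, computes
BIO1-BIO19 and prunes correlated predictors at |r| > 0.7.
"""

from coastsdm import compute_bioclim, correlation_prune, window_average
from coastsdm.grids import GridSpec
from coastsdm.synthetic import ClimateScenario, generate_climate

grid = GridSpec(n_rows=30, n_cols=40, west=-95.0, south=0.0, cell_size=0.75)
scenario = ClimateScenario(grid=grid, seed=1)

series = generate_climate(scenario, range(2013, 2019))
normals = window_average(series, (2013, 2018))
stack = compute_bioclim(normals)

# BIO6 (minimum temperature of the coldest month) falls off with latitude;
# BIO12 (annual precipitation) follows the longitudinal moisture gradient.
for i, label in [(1, "annual mean temperature (degC)"),
                 (6, "min temperature of coldest month (degC)"),
                 (12, "annual precipitation (mm)")]:
    vals = stack.bio[i].valid_values()
    print(f"BIO{i:<2} {label}: {vals.min():8.1f} .. {vals.max():8.1f}")

pruned = correlation_prune(stack)
print("\nretained predictors:", [f"BIO{v}" for v in pruned.retained])
print("examples of dropped pairs (dropped <- kept, r):")
for dropped, kept, r in pruned.dropped[:5]:
    print(f"  BIO{dropped} <- BIO{kept}  r={r:+.3f}")
print("\nA retained set free of |r| > 0.7 pairs is what the niche models train on.")
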