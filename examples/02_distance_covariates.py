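"""Compute the five spatial covariates and their correlations.

For every nest: mean daily distance to the nearest concurrently active
neighbour, distance to the closest lek active that year, and nearest-point
distances to paths, the meadow edge and the shoreline.  Edge and shore
distances are expected to correlate strongly negatively (the nesting band
lies between the two), which is why the survival model is fitted with both
but interpreted with that collinearity in mind.
"""

from ruffnest import (ScenarioConfig, nest_distance_table,
                      predictor_correlation_matrix, simulate_dataset)

nests, landscape = simulate_dataset(ScenarioConfig(rng_seed=1))
table = nest_distance_table(nests, landscape)

print("mean distances (m):")
print(table[["dist_nests", "dist_leks", "dist_paths", "dist_edge",
             "dist_shore"]].mean().round(1).to_string())

r, p = predictor_correlation_matrix(table)
print("\nPearson correlations between predictors:")
print(r.round(2).to_string())
print("\nedge vs shore: r = {:.2f}, p = {:.2g}".format(
    r.loc['dist_edge', 'dist_shore'], p.loc['dist_edge', 'dist_shore']))
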