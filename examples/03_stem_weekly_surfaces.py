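"""Fit the STEM ensemble and predict weekly occurrence surfaces.

Fits boosted-tree base models inside randomly offset space-time stixels
(reduced setting: 5 partitions, 100 trees), then predicts the occurrence
probability of every cell for three weeks under the standardised reference
conditions (complete list of length 25).  The occurrence-weighted centroid
shows the simulated species migrating north and back.
"""

import numpy as np

from stemcover import (
    EffortConfig,
    Extent,
    GbmParams,
    build_partitions,
    fit_base_models,
    fit_list_length_model,
    make_world,
    merge_lists,
    predict_occurrence,
    promote_casual_records,
    simulate_effort,
    simulate_species,
)

world = make_world(40, 40, seed=7)
occ = simulate_species(world, seed=1)
lists = simulate_effort(world, [occ], EffortConfig(), seed=5)
complete = lists[lists["type"] == "complete"]
llm = fit_list_length_model(complete, world, seed=2)
merged = merge_lists(complete, promote_casual_records(lists[lists["type"] == "casual"], llm))

partitions = build_partitions(
    Extent.from_world(world), width_km=500, depth_days=40, n_partitions=5, seed=11
)
ensemble = fit_base_models(merged, world, partitions, "SP1", gbm=GbmParams(n_trees=100), seed=3)
print(f"fitted {len(ensemble.models)} base models "
      f"({ensemble.n_skipped_stixels} stixels below the 30-list minimum)")

y = world.cells["y_km"].to_numpy()
for week in (14, 25, 38):
    pred = predict_occurrence(ensemble, week)
    p = np.nan_to_num(pred["p_occ"].to_numpy())
    centroid = (p * y).sum() / p.sum()
    print(f"week {week}: summed occurrence {p.sum():6.1f}, "
          f"occupied cells {(p > 0).sum():4d}, "
          f"occurrence centroid {centroid:5.0f} km north")
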