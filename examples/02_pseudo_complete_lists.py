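"""Promote casual records into pseudo-complete lists.

Fits the random-forest list-length model on complete lists, predicts the
expected complete-list length per (cell, month), and promotes every casual
cell-day whose record total meets it.  The promoted:complete ratio shows
how much modelling data the promotion recovers from casual records.
"""

from stemcover import (
    EffortConfig,
    fit_list_length_model,
    make_world,
    merge_lists,
    predict_expected_length,
    promote_casual_records,
    simulate_effort,
    simulate_species,
)

world = make_world(40, 40, seed=7)
occ = simulate_species(world, seed=1)
lists = simulate_effort(world, [occ], EffortConfig(), seed=5)
complete = lists[lists["type"] == "complete"]
casual = lists[lists["type"] == "casual"]

model = fit_list_length_model(complete, world, seed=2)
print(f"list-length model: n={model.n_training}, in-sample R^2={model.r2_in_sample:.2f}")
print(f"expected complete-list length, cell 100 in June: "
      f"{predict_expected_length(model, 100, 6):.1f} species")

pseudo = promote_casual_records(casual, model)
n_days = casual.groupby(["cell_id", "date"]).ngroups
print(f"promoted {len(pseudo)} of {n_days} casual cell-days "
      f"(promoted:complete ratio {len(pseudo) / len(complete):.2f})")
merged = merge_lists(complete, pseudo)
print(f"merged modelling stream: {len(merged)} lists")
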