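"""Build a synthetic study area and inspect effort biases.

Generates a 40x40 grid of 10-km cells with autocorrelated habitat, a
protected-area layer biased away from cropland, one migrating species, and
a year of checklist effort; then prints the habitat representation of that
effort (ratio 1 = effort proportional to habitat availability).
"""

from stemcover import (
    EffortConfig,
    habitat_representation,
    make_protected_layer,
    make_world,
    simulate_effort,
    simulate_species,
)

world = make_world(40, 40, cell_size_km=10, seed=7)
layer = make_protected_layer(world, total_fraction=0.201, farmland_bias=-2.0, seed=3)
occ = simulate_species(world, seed=1)
lists = simulate_effort(
    world, [occ], EffortConfig(habitat_bias={"urban": 1.0, "trees": -0.5}), seed=5
)

print(f"cells: {world.n_cells}, checklists: {len(lists)} "
      f"({(lists['type'] == 'complete').sum()} complete)")
print(f"protected share of study area: {layer['fraction_total'].mean():.3f} "
      "(area-weighted mean cell fraction)")
rep = habitat_representation(lists, world)
print("\nobserved/expected effort share per habitat (1 = unbiased):")
print(rep[["habitat", "ratio"]].round(2).to_string(index=False))
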