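"""Root-system hierarchy and plasticity behind the mixing effects.

Hierarchical distance HD = (A_focal - A_neighbour)/A_focal ranks the two
varieties of a mixture by pure-stand root area; the plasticity index P
compares a mixture's observed root area with the mean of its components'
pure stands.
"""

import rhizomix as rx

genotypes, design, params, rng = rx.arms_race_scenario(seed=1)
plants, tubes = rx.simulate_experiment(genotypes, design, params, rng)

refs, _ = rx.reference_table(
    plants, tubes, design, ("total_biomass", "root_area"))
biomass_refs = refs[refs["trait"] == "total_biomass"]
area_refs = refs[refs["trait"] == "root_area"]

table = rx.tube_genotype_table(plants, design, "total_biomass")
mixed = table[~table["is_control"] & table["is_mixture"]]
pair_values, _ = rx.mixture_pair_values(mixed, "total_biomass")
effects = rx.effects_table(pair_values, biomass_refs)

hier = rx.hierarchy_table(pair_values, biomass_refs, area_refs)
area_tab = rx.tube_root_table(tubes, design, "root_area")
mix_areas, _ = rx.mixture_tube_values(
    area_tab[~area_tab["is_control"] & area_tab["is_mixture"]], "root_area")
plast = rx.plasticity_table(mix_areas, area_refs, effects=effects)

print(rx.bivariate_stats(hier, "HD", "RY").round(3).to_string(index=False))
print()
print(rx.bivariate_stats(plast, "P", "RYT").round(3).to_string(index=False))
# Under R-, RY falls as the focal genotype rises in the root-area
# hierarchy (negative R), and mixtures whose root systems shrank the most
# relative to their pure stands (negative P) have the lowest RYT
# (positive R): competition is relaxed, not intensified, in mixtures.
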