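"""Build BLUP-adjusted pure-stand references.

The reference biomass of a variety in a treatment is the mixed-model sum
mu_hat + tau_hat_k + BLUP(variety): the treatment fixed effect at an
average block and harvest date plus the variety's predicted random
deviation.  These references are the denominators of every relative yield.
"""

import rhizomix as rx

genotypes, design, params, rng = rx.arms_race_scenario(seed=1, n_genotypes=16)
plants, tubes = rx.simulate_experiment(genotypes, design, params, rng)

table = rx.tube_genotype_table(plants, design, "total_biomass")
pure = table[~table["is_control"] & ~table["is_mixture"]]
refs, fit = rx.pure_reference_values(pure, "total_biomass", with_random_slope=True)

print("variance components:", {k: round(v, 1)
                               for k, v in fit.variance_components.items()})
print("\nadjusted pure-stand references (mg per tube), first genotypes:")
wide = refs.pivot(index="variety", columns="treatment", values="value").round(1)
print(wide.head(6).to_string())
# Each value estimates what a tube of that genotype would produce in an
# average block on an average harvest date; R- columns are lower because
# the treatment fixed effect and the genotype's random slope are added.
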