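"""Six-class hybrid-category posteriors on diagnostic loci.

With reference pools fixed for different alleles, every locus is fully
diagnostic: an all-heterozygous fish can only be an F1, a fish matching one
pool everywhere is pure.  The category posteriors recover this exactly.
"""

from hatchtrace import HybridClassModel, class_coefficients, estimate_class_posterior
from hatchtrace.mating import simulate_random_mating
from hatchtrace.genotypes import GenotypeTable
from hatchtrace.popgen import PopulationFrequencies

loci = [f"L{j + 1}" for j in range(12)]
wild_freq = PopulationFrequencies(
    ["wild"], loci, {"wild": {l: {101: 1.0} for l in loci}},
    {"wild": {l: 200 for l in loci}},
)
hatch_freq = PopulationFrequencies(
    ["hatchery"], loci, {"hatchery": {l: {103: 1.0} for l in loci}},
    {"hatchery": {l: 200 for l in loci}},
)
wild_refs = simulate_random_mating(wild_freq, wild_freq, 100, seed=1,
                                   label="w", group="wild")
hatch_refs = simulate_random_mating(hatch_freq, hatch_freq, 100, seed=2,
                                    label="h", group="hatchery")
queries = GenotypeTable.concatenate([
    simulate_random_mating(wild_freq, hatch_freq, 2, seed=3, label="f1").table,
    simulate_random_mating(wild_freq, wild_freq, 2, seed=4, label="pw").table,
])

print("Mendelian origin-pair coefficients per class:")
print(class_coefficients().to_string(), "\n")

post = estimate_class_posterior(
    queries, wild_refs, hatch_refs,
    HybridClassModel.desk(n_chains=2), seed=5,
)
print(post.categories.round(4).to_string())
print("\ncategory calls at the 0.80 probability rule:")
print(post.calls().to_string())
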