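"""Calibrate introgression thresholds from simulated F1 crosses.

Simulates wild x hatchery F1 crosses from the pooled group frequencies,
estimates p(wild) for each against the centroids, and takes the 2.5/97.5
percentiles of that null distribution as the hatchery/introgressed/wild
cutoffs.  A small set of known-truth queries is then classified.
"""

import dataclasses

import numpy as np

from hatchtrace import (AdmixtureConfig, CentroidSpec, SyntheticScenario,
                        allele_frequencies, batch_assign, build_centroids,
                        calibrate_thresholds, classify_individuals,
                        generate_scenario)

data = generate_scenario(SyntheticScenario(
    seed=11, n_wild_populations=8, n_hatchery_strains=3,
    planted_fractions={f"wild{k:02d}": {"F1": 0.08} for k in range(1, 9)},
))
table = data.table
cfg = AdmixtureConfig.desk(seed=5)

wild, hatch, _ = build_centroids(table, CentroidSpec(n_per_centroid=300, seed=4))
cal = calibrate_thresholds(
    allele_frequencies(table.for_group("wild"), "pooled"),
    allele_frequencies(table.for_group("hatchery"), "pooled"),
    n_f1=60, wild_centroid=wild, hatchery_centroid=hatch, config=cfg,
)
print(f"simulated-F1 null: t_lo={cal.t_lo:.3f}  t_hi={cal.t_hi:.3f}")
print("p(wild) in [t_lo, t_hi] classifies as introgressed, above as wild,")
print("below as hatchery.\n")

# a known mix: three planted F1s, four pure wild, three hatchery fish
rng = np.random.default_rng(1)
ids = []
for cls, k in (("F1", 3), ("wild", 4), ("hatchery", 3)):
    pool = data.truth[data.truth == cls].index.to_numpy()
    ids.extend(rng.choice(pool, size=k, replace=False))
pick = np.sort([table.individuals.index(i) for i in ids])
queries = table.subset(pick)
results = batch_assign(
    queries, wild, hatch, dataclasses.replace(cfg, seed=6)
)
frame, summary = classify_individuals(results, cal)
frame["truth"] = frame["individual"].map(data.truth)
print(frame.round(3).to_string(index=False))
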