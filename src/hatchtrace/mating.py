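"""Random-mating simulation: population centroids and simulated crosses.

A *centroid* is a simulated reference population whose allele frequencies
are the pooled frequencies of all sampled populations within a group (wild
or hatchery).  Individuals are subsampled without replacement from each
population (a fixed number per population, populations below that size being
excluded), pooled within the group, and offspring are then simulated by
drawing, at each locus independently, one allele from each parental pool's
frequency spectrum.  Passing the same pool twice gives within-group random
mating; passing the wild and hatchery pools gives simulated F1 crosses.

Offspring are drawn from pooled allele frequencies rather than by pairing
individual parents, and loci are unlinked — the standard behaviour of
frequency-conditioned hybrid simulators for microsatellite panels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotypes import GenotypeTable
from .popgen import PopulationFrequencies, allele_frequencies, pairwise_fst

__all__ = [
    "CentroidSpec",
    "SimulatedCohort",
    "simulate_random_mating",
    "build_centroids",
    "centroid_precision",
]


@dataclass
class CentroidSpec:
    """How to subsample real populations and how large to build centroids.

    Defaults follow the study design this package implements: 22 fish per
    wild population, 50 per hatchery strain, 500 simulated individuals per
    centroid; populations smaller than their subsample size must be listed
    in ``exclude`` (they contribute nothing to the pool).
    """

    wild_subsample: int = 22
    hatchery_subsample: int = 50
    n_per_centroid: int = 500
    exclude: tuple = ()
    seed: int | None = None

    def __post_init__(self):
        if self.wild_subsample < 1 or self.hatchery_subsample < 1:
            raise ValueError("subsample sizes must be >= 1")
        if self.n_per_centroid < 1:
            raise ValueError("n_per_centroid must be >= 1")


@dataclass
class SimulatedCohort:
    """A simulated set of individuals plus its provenance.

    ``cross_type`` is ``within-pool`` (both gametes from the same pool) or
    ``between-pool``; ``parents`` names the source pools.
    """

    table: GenotypeTable
    parents: tuple
    cross_type: str
    seed: int | None = None
    manifest: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.table)

    def write(self, path_prefix: str, format: str = "genepop") -> None:
        """Write the cohort plus a JSON provenance sidecar."""
        from .genotypes import write_genotypes

        ext = {"genepop": ".gen", "structure_two_row": ".str"}[format]
        write_genotypes(self.table, str(path_prefix) + ext, format)
        sidecar = {
            "parents": list(self.parents),
            "cross_type": self.cross_type,
            "seed": self.seed,
            "n": len(self),
            "manifest": self.manifest,
        }
        Path(str(path_prefix) + ".provenance.json").write_text(
            json.dumps(sidecar, indent=2)
        )


def _spectrum_arrays(freqs: PopulationFrequencies, population: str):
    """Per-locus (codes, probabilities) arrays; errors on empty loci."""
    out = []
    for locus in freqs.loci:
        f = freqs.freqs[population][locus]
        if not f:
            raise ValueError(
                f"locus {locus!r} has no allele frequencies in pool "
                f"{population!r}"
            )
        codes = np.array(sorted(f), dtype=np.int32)
        probs = np.array([f[int(c)] for c in codes])
        out.append((codes, probs / probs.sum()))
    return out


def simulate_random_mating(
    freqs_a: PopulationFrequencies,
    freqs_b: PopulationFrequencies,
    n: int,
    seed: int | None = None,
    label: str = "sim",
    group: str = "query",
) -> SimulatedCohort:
    """Simulate ``n`` offspring of random mating between two pools.

    Each offspring receives, at every locus independently, one allele drawn
    from ``freqs_a``'s spectrum and one from ``freqs_b``'s.  Each pool
    argument must contain exactly one population; pass the same object twice
    for within-pool mating.
    """
    pop_a, pop_b = freqs_a.populations[0], freqs_b.populations[0]
    if len(freqs_a.populations) != 1 or len(freqs_b.populations) != 1:
        raise ValueError("each parental pool must hold a single population")
    if freqs_a.loci != freqs_b.loci:
        raise ValueError("parental pools must share loci")
    spec_a = _spectrum_arrays(freqs_a, pop_a)
    spec_b = _spectrum_arrays(freqs_b, pop_b)
    rng = np.random.default_rng(seed)
    n_loci = len(freqs_a.loci)
    calls = np.empty((n, n_loci, 2), dtype=np.int32)
    for j in range(n_loci):
        codes_a, p_a = spec_a[j]
        codes_b, p_b = spec_b[j]
        calls[:, j, 0] = rng.choice(codes_a, size=n, p=p_a)
        calls[:, j, 1] = rng.choice(codes_b, size=n, p=p_b)
    within = pop_a == pop_b and freqs_a.freqs[pop_a] is freqs_b.freqs[pop_b]
    cross_type = "within-pool" if (pop_a == pop_b) else "between-pool"
    table = GenotypeTable(
        [f"{label}_{i + 1}" for i in range(n)],
        list(freqs_a.loci),
        calls,
        np.array([label] * n, dtype=object),
        np.array([group] * n, dtype=object),
    )
    return SimulatedCohort(table, (pop_a, pop_b), cross_type, seed)


def subsample_groups(table: GenotypeTable, spec: CentroidSpec, rng):
    """Stratified subsample without replacement; returns (wild, hatchery)
    GenotypeTables and the manifest of individual ids used."""
    manifest: dict = {"wild": {}, "hatchery": {}}
    picks = {"wild": [], "hatchery": []}
    sizes = {"wild": spec.wild_subsample, "hatchery": spec.hatchery_subsample}
    for pop in table.populations:
        mask = table.population == pop
        grp = table.group[mask][0]
        if grp not in sizes:
            continue
        if pop in spec.exclude:
            continue
        idx = np.flatnonzero(mask)
        k = sizes[grp]
        if idx.size < k:
            raise ValueError(
                f"population {pop!r} has {idx.size} individuals, fewer than "
                f"its subsample size {k}; list it in CentroidSpec.exclude"
            )
        chosen = rng.choice(idx, size=k, replace=False)
        picks[grp].extend(chosen.tolist())
        manifest[grp][pop] = [table.individuals[i] for i in chosen]
    if not picks["wild"] or not picks["hatchery"]:
        raise ValueError("need at least one wild and one hatchery population")
    return (
        table.subset(np.array(sorted(picks["wild"]))),
        table.subset(np.array(sorted(picks["hatchery"]))),
        manifest,
    )


def build_centroids(table: GenotypeTable, spec: CentroidSpec):
    """Build the wild and hatchery centroid cohorts.

    Subsamples ``spec.wild_subsample`` fish per wild population and
    ``spec.hatchery_subsample`` per hatchery strain (without replacement,
    seeded), pools each group, estimates pooled allele frequencies, and
    simulates ``spec.n_per_centroid`` individuals within each group.

    Returns ``(wild_cohort, hatchery_cohort, manifest)``; the manifest
    records exactly which individuals entered each pool.
    """
    rng = np.random.default_rng(spec.seed)
    wild_pool, hatch_pool, manifest = subsample_groups(table, spec, rng)
    freq_w = allele_frequencies(wild_pool, "pooled")
    freq_h = allele_frequencies(hatch_pool, "pooled")
    seed_w, seed_h = rng.integers(0, 2**31 - 1, size=2)
    wild = simulate_random_mating(
        freq_w, freq_w, spec.n_per_centroid, seed=int(seed_w),
        label="wild_centroid", group="wild",
    )
    hatch = simulate_random_mating(
        freq_h, freq_h, spec.n_per_centroid, seed=int(seed_h),
        label="hatchery_centroid", group="hatchery",
    )
    manifest["pool_sizes"] = {
        "wild": len(wild_pool),
        "hatchery": len(hatch_pool),
    }
    wild.manifest = manifest
    hatch.manifest = manifest
    return wild, hatch, manifest


def centroid_precision(
    table: GenotypeTable, spec: CentroidSpec, replicates: int = 10
):
    """Replicate-centroid FST summaries (precision of the centroid method).

    Builds ``replicates`` independent wild/hatchery centroid pairs, each from
    a fresh random subsample, and summarises pairwise multilocus FST among
    replicate wild centroids, among replicate hatchery centroids, and between
    wild and hatchery centroids.
    """
    if replicates < 2:
        raise ValueError("need at least two replicates")
    rng = np.random.default_rng(spec.seed)
    wilds, hatches = [], []
    for r in range(replicates):
        rep_spec = CentroidSpec(
            spec.wild_subsample,
            spec.hatchery_subsample,
            spec.n_per_centroid,
            spec.exclude,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        w, h, _ = build_centroids(table, rep_spec)
        wilds.append(w.table)
        hatches.append(h.table)

    def _relabel(tables, prefix):
        out = []
        for i, t in enumerate(tables):
            t = GenotypeTable(
                [f"{prefix}{i}_{ind}" for ind in t.individuals],
                t.loci, t.calls,
                np.array([f"{prefix}{i}"] * len(t), dtype=object),
                t.group,
            )
            out.append(t)
        return out

    combined = GenotypeTable.concatenate(
        _relabel(wilds, "W") + _relabel(hatches, "H")
    )
    mat, _ = pairwise_fst(combined)
    w_labels = [f"W{i}" for i in range(replicates)]
    h_labels = [f"H{i}" for i in range(replicates)]
    within_w = [
        mat.loc[a, b] for i, a in enumerate(w_labels) for b in w_labels[i + 1:]
    ]
    within_h = [
        mat.loc[a, b] for i, a in enumerate(h_labels) for b in h_labels[i + 1:]
    ]
    between = [mat.loc[a, b] for a in w_labels for b in h_labels]
    return {
        "within_wild_mean": float(np.mean(within_w)),
        "within_wild_var": float(np.var(within_w)),
        "within_hatchery_mean": float(np.mean(within_h)),
        "within_hatchery_var": float(np.var(within_h)),
        "between_mean": float(np.mean(between)),
        "between_var": float(np.var(between)),
        "replicates": replicates,
    }
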