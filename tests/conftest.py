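import numpy as np
import pytest

from hatchtrace.genotypes import GenotypeTable
from hatchtrace.mating import simulate_random_mating
from hatchtrace.popgen import PopulationFrequencies

LOCI12 = [f"L{j + 1}" for j in range(12)]


def make_table(rows, loci=("L1", "L2", "L3"), pops=None, groups=None):
    """Small literal genotype table; rows are per-individual call lists."""
    n = len(rows)
    return GenotypeTable(
        [f"ind{i + 1}" for i in range(n)],
        list(loci),
        np.array(rows, dtype=np.int32),
        np.array(pops if pops is not None else ["pop1"] * n, dtype=object),
        np.array(groups if groups is not None else ["wild"] * n, dtype=object),
    )


def pool_from_freqs(freq_by_locus, label="pool", n_copies=1000):
    """PopulationFrequencies for one pool from {locus: {allele: freq}}."""
    loci = list(freq_by_locus)
    return PopulationFrequencies(
        [label], loci,
        {label: {l: dict(freq_by_locus[l]) for l in loci}},
        {label: {l: n_copies for l in loci}},
    )


def diverged_pools(F=0.08, seed=3, n_loci=12, n_alleles=6, conc=0.8):
    """A wild/hatchery pool pair diverged F each from a common ancestor
    (realized pairwise theta near F for these settings)."""
    rng = np.random.default_rng(seed)
    loci = [f"L{j + 1}" for j in range(n_loci)]
    fw, fh = {}, {}
    for l in loci:
        anc = rng.dirichlet(np.full(n_alleles, conc))
        fw[l] = {
            101 + 2 * i: v for i, v in enumerate(rng.dirichlet(anc * (1 - F) / F))
        }
        fh[l] = {
            101 + 2 * i: v for i, v in enumerate(rng.dirichlet(anc * (1 - F) / F))
        }
    return pool_from_freqs(fw, "wild"), pool_from_freqs(fh, "hatchery")


def fixed_difference_pools(n_loci=12):
    loci = [f"L{j + 1}" for j in range(n_loci)]
    return (
        pool_from_freqs({l: {101: 1.0} for l in loci}, "wild"),
        pool_from_freqs({l: {103: 1.0} for l in loci}, "hatchery"),
    )


@pytest.fixture(scope="session")
def small_centroids():
    """Wild/hatchery reference cohorts (n=150 each) from pools at theta~0.07;
    small enough for per-query sampler tests."""
    pw, ph = diverged_pools()
    wild = simulate_random_mating(pw, pw, 150, seed=10, label="wc", group="wild")
    hatch = simulate_random_mating(ph, ph, 150, seed=20, label="hc", group="hatchery")
    return pw, ph, wild, hatch


@pytest.fixture(scope="session")
def fixed_centroids():
    """Reference cohorts from fixed-difference pools (every locus diagnostic)."""
    pw, ph = fixed_difference_pools()
    wild = simulate_random_mating(pw, pw, 100, seed=11, label="wc", group="wild")
    hatch = simulate_random_mating(ph, ph, 100, seed=21, label="hc", group="hatchery")
    return pw, ph, wild, hatch
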