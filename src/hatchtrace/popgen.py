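"""Population-genetic summary statistics on genotype tables.

Covers the descriptive layer of the introgression analysis: sample allele
frequencies, allelic richness and Nei's unbiased expected heterozygosity,
chi-square Hardy-Weinberg tests with Bonferroni correction, pairwise FST
(Weir & Cockerham theta by default, a Nei-style GST option), classical
principal coordinate analysis of a distance matrix, and the multilocus
probability of identity used to justify duplicate removal.

Missing calls are excluded locus-wise throughout: a frequency, He, FST or
PID computation at a locus uses only the gene copies actually typed there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .genotypes import MISSING, GenotypeTable

__all__ = [
    "PopulationFrequencies",
    "allele_frequencies",
    "summarize_diversity",
    "hwe_test",
    "pairwise_fst",
    "pcoa",
    "probability_of_identity",
]


@dataclass
class PopulationFrequencies:
    """Per-population, per-locus allele frequency spectra.

    ``freqs[pop][locus]`` maps allele code -> relative frequency among the
    non-missing gene copies; ``n_copies[pop][locus]`` is the number of gene
    copies used (2 x typed individuals, always even).  A locus with no typed
    individuals in a population has an empty map, ``n_copies == 0``, and its
    (population, locus) pair is listed in ``empty_loci``.
    """

    populations: list[str]
    loci: list[str]
    freqs: dict = field(repr=False)
    n_copies: dict = field(repr=False)
    empty_loci: list = field(default_factory=list)

    def spectrum(self, population: str, locus: str) -> dict:
        return self.freqs[population][locus]

    def allele_support(self, locus: str) -> list[int]:
        """Sorted union of allele codes observed at ``locus`` across pops."""
        codes: set[int] = set()
        for p in self.populations:
            codes.update(self.freqs[p][locus])
        return sorted(codes)

    def single(self, population: str) -> "PopulationFrequencies":
        return PopulationFrequencies(
            [population],
            list(self.loci),
            {population: self.freqs[population]},
            {population: self.n_copies[population]},
            [e for e in self.empty_loci if e[0] == population],
        )


def _locus_frequencies(calls_locus: np.ndarray):
    copies = calls_locus.reshape(-1)
    copies = copies[copies != MISSING]
    n = copies.size
    if n == 0:
        return {}, 0
    codes, counts = np.unique(copies, return_counts=True)
    return {int(c): k / n for c, k in zip(codes, counts)}, int(n)


def allele_frequencies(
    table: GenotypeTable, grouping: str = "by_population"
) -> PopulationFrequencies:
    """Sample allele frequencies from non-missing gene copies.

    ``grouping`` chooses the stratification: ``by_population`` (one spectrum
    per population label), ``by_group`` (wild / hatchery / query pools), or
    ``pooled`` (every individual in one pool labelled ``pooled``).
    """
    if len(table) == 0:
        raise ValueError("cannot compute allele frequencies of an empty table")
    if grouping == "by_population":
        labels, key = table.populations, table.population
    elif grouping == "by_group":
        seen: dict[str, None] = {}
        for g in table.group:
            seen.setdefault(g)
        labels, key = list(seen), table.group
    elif grouping == "pooled":
        labels, key = ["pooled"], np.array(["pooled"] * len(table), dtype=object)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    freqs: dict = {}
    n_copies: dict = {}
    empty = []
    for lab in labels:
        sub = table.calls[key == lab]
        freqs[lab], n_copies[lab] = {}, {}
        for j, locus in enumerate(table.loci):
            f, n = _locus_frequencies(sub[:, j, :])
            freqs[lab][locus] = f
            n_copies[lab][locus] = n
            if n == 0:
                empty.append((lab, locus))
    return PopulationFrequencies(labels, list(table.loci), freqs, n_copies, empty)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def unbiased_heterozygosity(freq: dict, n_copies: int) -> float:
    """Nei's unbiased expected heterozygosity (2n/(2n-1))(1 - sum p^2).

    ``n_copies`` is the number of gene copies (2n in the formula written in
    terms of diploid individuals n).
    """
    if n_copies < 2 or not freq:
        return np.nan
    p = np.array(list(freq.values()))
    return (n_copies / (n_copies - 1)) * (1.0 - float(p @ p))


def summarize_diversity(table: GenotypeTable) -> pd.DataFrame:
    """Per-population sample size, mean alleles/locus N_A and mean H_E.

    N_A averages the observed allele count over loci with data; H_E averages
    Nei's unbiased expected heterozygosity over the same loci.  Populations
    with no typed individuals are excluded (a warning is emitted).
    """
    import warnings

    pf = allele_frequencies(table, "by_population")
    rows = []
    for pop in pf.populations:
        n_ind = int((table.population == pop).sum())
        na, he = [], []
        for locus in pf.loci:
            f = pf.freqs[pop][locus]
            n = pf.n_copies[pop][locus]
            if n == 0:
                continue
            na.append(len(f))
            he.append(unbiased_heterozygosity(f, n))
        if not na:
            warnings.warn(f"population {pop!r} has no typed loci; excluded")
            continue
        rows.append(
            {
                "population": pop,
                "group": table.group[table.population == pop][0],
                "n": n_ind,
                "N_A": float(np.mean(na)),
                "H_E": float(np.nanmean(he)),
            }
        )
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def hwe_test(
    table: GenotypeTable,
    population: str,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Chi-square goodness-of-fit of genotype counts to Hardy-Weinberg.

    For each locus, observed genotype-class counts are compared with the
    expected counts ``n p_i^2`` (homozygotes) and ``2 n p_i p_j``
    (heterozygotes) from the sample allele frequencies, with
    ``df = G - A`` degrees of freedom (G possible genotype classes,
    A observed alleles).  No pooling of rare classes is applied.

    The Bonferroni column compares each p-value with ``alpha / n_tests``
    (``n_tests`` defaults to the number of testable loci).  Monomorphic or
    data-free loci are reported as not-applicable (NaN statistics).
    """
    sub = table.for_population(population)
    results = []
    for j, locus in enumerate(sub.loci):
        calls = sub.calls[:, j, :]
        typed = calls[(calls != MISSING).all(axis=1)]
        n = typed.shape[0]
        codes = np.unique(typed)
        if n < 2 or codes.size < 2:
            results.append((locus, n, np.nan, np.nan, np.nan))
            continue
        idx = {int(c): k for k, c in enumerate(codes)}
        a_count = codes.size
        p = np.zeros(a_count)
        for c, k in idx.items():
            p[k] = (typed == c).sum() / (2 * n)
        obs = np.zeros((a_count, a_count))
        for a, b in np.sort(typed, axis=1):
            obs[idx[int(a)], idx[int(b)]] += 1
        chi2 = 0.0
        for i in range(a_count):
            for k in range(i, a_count):
                exp = n * (p[i] ** 2 if i == k else 2 * p[i] * p[k])
                if exp > 0:
                    chi2 += (obs[i, k] - exp) ** 2 / exp
        g_classes = a_count * (a_count + 1) // 2
        df = g_classes - a_count
        pval = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
        results.append((locus, n, chi2, df, pval))
    frame = pd.DataFrame(
        results, columns=["locus", "n", "chi2", "df", "p_value"]
    ).set_index("locus")
    if n_tests is None:
        n_tests = int(frame["p_value"].notna().sum()) or 1
    threshold = alpha / n_tests
    frame["bonferroni_threshold"] = threshold
    frame["passes_bonferroni"] = frame["p_value"].isna() | (
        frame["p_value"] > threshold
    )
    return frame


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def _wc_components(calls_a: np.ndarray, calls_b: np.ndarray):
    """Weir & Cockerham (1984) variance components a, b, c summed over
    alleles for one locus and two samples.  ``calls_*`` are (n, 2) arrays."""
    samples = []
    for calls in (calls_a, calls_b):
        typed = calls[(calls != MISSING).all(axis=1)]
        if typed.shape[0] < 1:
            return 0.0, 0.0, 0.0
        samples.append(typed)
    r = 2
    ns = np.array([s.shape[0] for s in samples], dtype=float)
    nbar = ns.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
    codes = np.unique(np.concatenate([s.reshape(-1) for s in samples]))
    a_sum = b_sum = c_sum = 0.0
    for code in codes:
        p_i = np.array([(s == code).sum() / (2 * s.shape[0]) for s in samples])
        h_i = np.array(
            [((s == code).sum(axis=1) == 1).mean() for s in samples]
        )
        pbar = (ns * p_i).sum() / (r * nbar)
        s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum, b_sum, c_sum = a_sum + a, b_sum + b, c_sum + c
    return a_sum, b_sum, c_sum


def _theta_pair(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Multilocus Weir-Cockerham theta, ratio-of-sums over loci."""
    num = den = 0.0
    for j in range(calls_a.shape[1]):
        a, b, c = _wc_components(calls_a[:, j, :], calls_b[:, j, :])
        num += a
        den += a + b + c
    return num / den if den != 0 else np.nan


def _nei_pair(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Nei-style GST: (HT - HS)/HT with HT, HS summed over loci; allele
    frequencies averaged unweighted across the two samples."""
    ht_sum = hs_sum = 0.0
    for j in range(calls_a.shape[1]):
        fa, na = _locus_frequencies(calls_a[:, j, :])
        fb, nb = _locus_frequencies(calls_b[:, j, :])
        if na == 0 or nb == 0:
            continue
        codes = set(fa) | set(fb)
        pa = np.array([fa.get(c, 0.0) for c in codes])
        pb = np.array([fb.get(c, 0.0) for c in codes])
        pm = (pa + pb) / 2
        hs_sum += 1 - ((pa @ pa) + (pb @ pb)) / 2
        ht_sum += 1 - pm @ pm
    return (ht_sum - hs_sum) / ht_sum if ht_sum > 0 else np.nan


def pairwise_fst(
    table: GenotypeTable,
    estimator: str = "weir_cockerham",
    min_individuals: int = 2,
    n_permutations: int = 0,
    seed: int | None = None,
):
    """Pairwise multilocus FST among populations.

    Returns ``(matrix, p_values)`` where ``matrix`` is a symmetric
    DataFrame with zero diagonal.  ``estimator`` is ``weir_cockerham``
    (theta, ratio-of-sums over per-locus variance components; may be
    slightly negative for undifferentiated pairs) or ``nei`` (GST).
    Populations with fewer than ``min_individuals`` give NaN rows.

    With ``n_permutations > 0``, a one-sided permutation p-value is computed
    per pair by shuffling individuals between the two populations.
    """
    if estimator == "weir_cockerham":
        pair_stat = _theta_pair
    elif estimator == "nei":
        pair_stat = _nei_pair
    else:
        raise ValueError(f"unknown FST estimator {estimator!r}")
    pops = table.populations
    if len(pops) < 2:
        raise ValueError("pairwise FST needs at least two populations")
    calls_by_pop = {p: table.calls[table.population == p] for p in pops}
    k = len(pops)
    mat = np.zeros((k, k))
    pmat = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            ca, cb = calls_by_pop[pops[i]], calls_by_pop[pops[j]]
            if ca.shape[0] < min_individuals or cb.shape[0] < min_individuals:
                mat[i, j] = mat[j, i] = np.nan
                continue
            obs = pair_stat(ca, cb)
            mat[i, j] = mat[j, i] = obs
            if n_permutations > 0:
                pooled = np.concatenate([ca, cb])
                na = ca.shape[0]
                hits = 0
                for _ in range(n_permutations):
                    perm = rng.permutation(pooled.shape[0])
                    stat = pair_stat(pooled[perm[:na]], pooled[perm[na:]])
                    if stat >= obs:
                        hits += 1
                pmat[i, j] = pmat[j, i] = (hits + 1) / (n_permutations + 1)
    matrix = pd.DataFrame(mat, index=pops, columns=pops)
    pvals = (
        pd.DataFrame(pmat, index=pops, columns=pops)
        if n_permutations > 0
        else None
    )
    return matrix, pvals


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def pcoa(distance_matrix, n_axes: int | None = None):
    """Classical (Gower) principal coordinate analysis.

    ``distance_matrix`` must be square and symmetric with a zero diagonal;
    negative entries (e.g. slightly negative theta estimates) are truncated
    to zero before embedding.  Returns ``(coordinates, percent_variance,
    eigenvalues)`` where coordinates hold one column per positive eigenvalue
    (descending), and ``percent_variance`` normalises each retained
    eigenvalue by the sum of the positive eigenvalues.
    """
    labels = None
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        D = distance_matrix.to_numpy(dtype=float)
    else:
        D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    D = np.clip(D, 0.0, None)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10 * max(eigvals.max(), 1.0)
    k = int(pos.sum())
    if n_axes is not None:
        k = min(k, n_axes)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    pct = 100.0 * eigvals[:k] / eigvals[pos].sum()
    if labels is not None:
        coords = pd.DataFrame(
            coords, index=labels,
            columns=[f"axis{i + 1}" for i in range(k)],
        )
    return coords, pct, eigvals


# ---------------------------------------------------------------------------
# probability of identity
# ---------------------------------------------------------------------------

def probability_of_identity(
    freqs: PopulationFrequencies, population: str | None = None
) -> float:
    """Multilocus probability that two random individuals share a genotype.

    Per locus, ``PID = 2 (sum p_i^2)^2 - sum p_i^4`` under random mating;
    the multilocus PID is the product over loci.  All loci must have a
    non-empty frequency spectrum in the chosen population.
    """
    if population is None:
        if len(freqs.populations) != 1:
            raise ValueError("specify which population's frequencies to use")
        population = freqs.populations[0]
    pid = 1.0
    for locus in freqs.loci:
        f = freqs.freqs[population][locus]
        if not f:
            raise ValueError(f"locus {locus!r} has no allele frequencies")
        p = np.array(list(f.values()))
        s2 = float(p @ p)
        s4 = float((p**2) @ (p**2))
        pid *= 2 * s2**2 - s4
    return pid
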