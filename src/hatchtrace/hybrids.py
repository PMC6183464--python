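"""Six-class hybrid-category posterior inference.

Cross-validates the threshold classifier by assigning each query to one of
six pedigree classes — pure wild, pure hatchery, F1, F2, backcross x wild,
backcross x hatchery — from the Mendelian expectation of how a class's two
gene copies at a locus are drawn from the (wild, wild), (wild, hatchery) or
(hatchery, hatchery) origin pairs.  Inference is by Gibbs sampling with
Jeffreys priors (Dirichlet(1/2)) on the cluster allele frequencies theta
and the class mixing proportions pi, run as several chains from distinct
seeds and pooled.

Reference individuals (the simulated centroids) enter as data of known pure
class: they contribute fixed counts to theta and are excluded from the
mixture over classes.  An unsupervised mode treats them as free individuals
instead, with per-chain cluster labels anchored to the wild references
afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable
from .mating import SimulatedCohort

__all__ = [
    "CLASSES", "CATEGORIES", "HybridClassModel", "class_coefficients",
    "estimate_class_posterior", "categorize_and_compare",
]

CLASSES = ("wild", "hatchery", "F1", "F2", "BXwild", "BXhatchery")
#: aggregated reporting categories; post-F1 pools F2 and both backcrosses
CATEGORIES = ("wild", "hatchery", "F1", "postF1")

_COEFS = np.array(
    [
        [1.00, 0.00, 0.00],   # wild
        [0.00, 0.00, 1.00],   # hatchery
        [0.00, 1.00, 0.00],   # F1
        [0.25, 0.50, 0.25],   # F2 (F1 x F1)
        [0.50, 0.50, 0.00],   # backcross x wild (F1 x wild)
        [0.00, 0.50, 0.50],   # backcross x hatchery
    ]
)


def class_coefficients() -> pd.DataFrame:
    """Per-class probabilities that a locus's two gene copies originate
    from (wild,wild), (wild,hatchery), (hatchery,hatchery)."""
    return pd.DataFrame(
        _COEFS.copy(), index=list(CLASSES), columns=["ww", "wh", "hh"]
    )


@dataclass
class HybridClassModel:
    """Sampler settings for the six-class model.

    Defaults are the full-length profile (25,000 burn-in, 100,000 sweeps,
    4 chains); ``HybridClassModel.desk()`` scales down to 2,000 / 10,000
    for desk-scale runs.  ``jeffreys = 0.5`` is the Dirichlet concentration
    used for both theta and pi.
    """

    burn_in: int = 25_000
    sweeps: int = 100_000
    n_chains: int = 4
    jeffreys: float = 0.5
    supervised: bool = True
    disagreement_tolerance: float = 0.2

    @classmethod
    def desk(cls, **kw) -> "HybridClassModel":
        kw.setdefault("burn_in", 2_000)
        kw.setdefault("sweeps", 10_000)
        return cls(**kw)


@dataclass
class HybridPosterior:
    """Per-individual class probabilities plus aggregated categories."""

    probabilities: pd.DataFrame    # individuals x CLASSES
    flagged: list = field(default_factory=list)

    @property
    def categories(self) -> pd.DataFrame:
        p = self.probabilities
        out = p[["wild", "hatchery", "F1"]].copy()
        out["postF1"] = p["F2"] + p["BXwild"] + p["BXhatchery"]
        return out

    def calls(self, threshold: float = 0.80) -> pd.Series:
        """Category call: argmax category iff it reaches ``threshold``,
        else ``inconclusive``; exact ties are inconclusive."""
        cats = self.categories
        vals = cats.to_numpy()
        best = vals.argmax(axis=1)
        best_p = vals.max(axis=1)
        ties = (vals == best_p[:, None]).sum(axis=1) > 1
        labels = np.array(
            [CATEGORIES[b] for b in best], dtype=object
        )
        labels[(best_p < threshold) | ties] = "inconclusive"
        return pd.Series(labels, index=cats.index, name="category")


def _encode(loci, blocks):
    calls = np.concatenate(blocks)
    L = len(loci)
    enc = np.empty(calls.shape, dtype=np.int64)
    n_alleles = np.empty(L, dtype=np.int64)
    for l in range(L):
        col = calls[:, l, :]
        codes = np.unique(col[col != MISSING])
        n_alleles[l] = max(len(codes), 1)
        out = np.full(col.shape, -1, dtype=np.int64)
        for i, c in enumerate(codes):
            out[col == c] = i
        enc[:, l, :] = out
    return enc, n_alleles


def _ref_counts(enc, n_alleles, n_wild, n_hatch):
    L = enc.shape[1]
    amax = int(n_alleles.max())
    counts = np.zeros((2, L, amax))
    for k, sl in ((0, slice(0, n_wild)), (1, slice(n_wild, n_wild + n_hatch))):
        block = enc[sl]
        for l in range(L):
            col = block[:, l, :].reshape(-1)
            col = col[col >= 0]
            counts[k, l, :] += np.bincount(col, minlength=amax)
    return counts


def _origin_likelihoods(theta, qa, qb, typed):
    """(Q, L, 3) likelihood of each query genotype under the three origin
    pairs, given cluster frequencies ``theta`` (2, L, A)."""
    Q, L = qa.shape
    tw = theta[0]
    th = theta[1]
    l_idx = np.arange(L)[None, :]
    a = np.where(typed, qa, 0)
    b = np.where(typed, qb, 0)
    tw_a, tw_b = tw[l_idx, a], tw[l_idx, b]
    th_a, th_b = th[l_idx, a], th[l_idx, b]
    het = (qa != qb) & typed
    ww = np.where(het, 2.0 * tw_a * tw_b, tw_a * tw_b)
    hh = np.where(het, 2.0 * th_a * th_b, th_a * th_b)
    wh = np.where(het, tw_a * th_b + tw_b * th_a, tw_a * th_a)
    out = np.stack([ww, wh, hh], axis=2)
    out[~typed] = 1.0  # missing locus contributes nothing
    return out


def _run_chain(enc_q, typed, n_alleles, fixed_counts, jeffreys,
               burn, sweeps, rng):
    """One Gibbs chain over the queries; returns mean class indicators."""
    Q, L = enc_q.shape[0], enc_q.shape[1]
    amax = int(n_alleles.max())
    qa, qb = enc_q[:, :, 0], enc_q[:, :, 1]

    theta = np.zeros((2, L, amax))
    for k in range(2):
        for l in range(L):
            A = n_alleles[l]
            theta[k, l, :A] = rng.dirichlet(
                jeffreys + fixed_counts[k, l, :A]
            )
    pi = rng.dirichlet(np.full(6, jeffreys))
    class_sum = np.zeros((Q, 6))
    l_idx = np.arange(L)[None, :]

    for sweep in range(burn + sweeps):
        lik3 = _origin_likelihoods(theta, qa, qb, typed)     # (Q, L, 3)
        per_class = lik3 @ _COEFS.T                          # (Q, L, 6)
        logp = np.log(np.clip(per_class, 1e-300, None)).sum(axis=1)
        logp += np.log(np.clip(pi, 1e-300, None))
        # Gumbel-max categorical draw per query
        g = rng.gumbel(size=(Q, 6))
        cls = (logp + g).argmax(axis=1)

        # per-locus origin pair given the class
        w3 = _COEFS[cls][:, None, :] * lik3                  # (Q, L, 3)
        w3 = np.clip(w3, 0.0, None)
        tot = w3.sum(axis=2, keepdims=True)
        tot[tot == 0] = 1.0
        u = rng.random((qa.shape[0], L, 1)) * tot
        origin = (u > np.cumsum(w3, axis=2)).sum(axis=2)     # 0=ww,1=wh,2=hh

        # orientation of the wh pair at heterozygous loci
        tw = theta[0]
        th = theta[1]
        a = np.where(typed, qa, 0)
        b = np.where(typed, qb, 0)
        p_ab = tw[l_idx, a] * th[l_idx, b]
        p_ba = tw[l_idx, b] * th[l_idx, a]
        swap = rng.random(qa.shape) * (p_ab + p_ba) < p_ba

        # tally query gene copies per cluster
        qcounts = np.zeros((2, L, amax))
        ww_m = (origin == 0) & typed
        wh_m = (origin == 1) & typed
        hh_m = (origin == 2) & typed
        for mask, k_a, k_b, swapped in (
            (ww_m, 0, 0, False),
            (hh_m, 1, 1, False),
            (wh_m, 0, 1, True),
        ):
            ii, ll = np.nonzero(mask)
            if ii.size == 0:
                continue
            ka = np.full(ii.shape, k_a)
            kb = np.full(ii.shape, k_b)
            if swapped:
                s = swap[ii, ll]
                ka = np.where(s, 1, 0)
                kb = np.where(s, 0, 1)
            np.add.at(qcounts, (ka, ll, qa[ii, ll]), 1.0)
            np.add.at(qcounts, (kb, ll, qb[ii, ll]), 1.0)

        for k in range(2):
            for l in range(L):
                A = n_alleles[l]
                theta[k, l, :A] = rng.dirichlet(
                    jeffreys + fixed_counts[k, l, :A] + qcounts[k, l, :A]
                )
        pi = rng.dirichlet(jeffreys + np.bincount(cls, minlength=6))

        if sweep >= burn:
            class_sum[np.arange(Q), cls] += 1.0
    return class_sum / sweeps


def estimate_class_posterior(
    queries: GenotypeTable,
    wild_refs: SimulatedCohort,
    hatchery_refs: SimulatedCohort,
    model: HybridClassModel | None = None,
    seed: int | None = None,
) -> HybridPosterior:
    """Posterior class probabilities for each query individual.

    Runs ``model.n_chains`` chains from seeds spawned off ``seed`` and pools
    their posterior class frequencies.  An individual whose per-category
    probability differs across chains by more than
    ``model.disagreement_tolerance`` is flagged.
    """
    if model is None:
        model = HybridClassModel()
    if wild_refs.table.loci != queries.loci or hatchery_refs.table.loci != queries.loci:
        raise ValueError("reference cohorts must share the query loci")
    n_w, n_h = len(wild_refs), len(hatchery_refs)
    enc, n_alleles = _encode(
        queries.loci,
        [wild_refs.table.calls, hatchery_refs.table.calls, queries.calls],
    )
    if model.supervised:
        # references contribute fixed counts to theta and are excluded from
        # the class mixture
        enc_q = enc[n_w + n_h:]
        fixed = _ref_counts(enc, n_alleles, n_w, n_h)
    else:
        # references sampled as free individuals alongside the queries
        enc_q = enc
        fixed = np.zeros((2, enc.shape[1], int(n_alleles.max())))
    typed = (enc_q >= 0).all(axis=2)

    wild_col = CLASSES.index("wild")
    hatch_col = CLASSES.index("hatchery")
    swap_cols = {
        wild_col: hatch_col, hatch_col: wild_col,
        CLASSES.index("BXwild"): CLASSES.index("BXhatchery"),
        CLASSES.index("BXhatchery"): CLASSES.index("BXwild"),
    }
    seeds = np.random.SeedSequence(seed).spawn(model.n_chains)
    chains = []
    for s in seeds:
        rng = np.random.default_rng(s)
        out = _run_chain(
            enc_q, typed, n_alleles, fixed, model.jeffreys,
            model.burn_in, model.sweeps, rng,
        )
        if not model.supervised:
            # anchor cluster labels to the wild references, then drop refs
            if out[:n_w, wild_col].mean() < out[:n_w, hatch_col].mean():
                order = [swap_cols.get(c, c) for c in range(6)]
                out = out[:, order]
            out = out[n_w + n_h:]
        chains.append(out)
    pooled = np.mean(chains, axis=0)
    probs = pd.DataFrame(pooled, index=queries.individuals, columns=list(CLASSES))

    flagged = []
    cat_map = {
        "wild": ["wild"], "hatchery": ["hatchery"], "F1": ["F1"],
        "postF1": ["F2", "BXwild", "BXhatchery"],
    }
    for cat, members in cat_map.items():
        per_chain = np.stack(
            [c[:, [CLASSES.index(m) for m in members]].sum(axis=1) for c in chains]
        )
        spread = per_chain.max(axis=0) - per_chain.min(axis=0)
        for idx in np.nonzero(spread > model.disagreement_tolerance)[0]:
            flagged.append(queries.individuals[idx])
    return HybridPosterior(probs, sorted(set(flagged)))


def categorize_and_compare(
    posterior: HybridPosterior,
    structure_results,
    threshold: float = 0.80,
) -> dict:
    """Consensus between the category calls and the threshold classifier.

    ``structure_results`` is a list of labelled ``AssignmentResult`` (labels
    ``wild`` / ``introgressed`` / ``hatchery``).  A category call of F1 or
    post-F1 agrees with ``introgressed``; ``inconclusive`` never agrees.
    Returns the cross-tabulation, the per-individual comparison frame and
    the consensus fraction.
    """
    calls = posterior.calls(threshold)
    ids = [r.individual for r in structure_results]
    if sorted(ids) != sorted(calls.index):
        raise ValueError("posterior and threshold results cover different individuals")
    thr = pd.Series(
        [r.label for r in structure_results], index=ids, name="threshold"
    ).reindex(calls.index)
    mapped = calls.map(
        {"wild": "wild", "hatchery": "hatchery", "F1": "introgressed",
         "postF1": "introgressed", "inconclusive": "inconclusive"}
    )
    agree = mapped == thr
    table = pd.crosstab(calls.rename("category"), thr)
    return {
        "consensus_fraction": float(agree.mean()),
        "n_agree": int(agree.sum()),
        "n_total": int(agree.size),
        "crosstab": table,
        "comparison": pd.DataFrame(
            {"category": calls, "threshold": thr, "agree": agree}
        ),
    }
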