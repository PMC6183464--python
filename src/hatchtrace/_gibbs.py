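"""Numba kernel for the two-cluster admixture Gibbs sampler.

One chain handles a panel of N diploid individuals at L unlinked loci with
alleles recoded to ``0..A_l-1`` (``-1`` = missing copy).  The model is the
standard admixture model without prior population information:

* per-copy origin indicators z ~ Categorical(q_i * P[k, l, a]),
* cluster allele frequencies P[k, l] ~ Dirichlet(lambda + counts),
* per-individual ancestry q_i ~ Dirichlet(alpha + n_i),
* the symmetric Dirichlet concentration alpha updated by Gaussian
  random-walk Metropolis under a uniform prior on (0, alpha_max]
  (step size adapted toward ~40% acceptance during burn-in only).

The kernel is random-number bound (~25k categorical draws per sweep on a
1,001-individual panel), so the per-copy uniform draws come from a
hand-inlined xorshift64* stream (seeded by splitmix64 from the chain seed);
gamma, normal and the remaining uniforms use numba's MT19937 ``np.random``
seeded from the same chain seed.  The (individual, locus, copy) grid is
flattened to the typed gene copies only; allele counts index a flat
``L * A_max`` slot table whose per-locus block is
``[l * A_max, l * A_max + A_l)``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_MULT = np.uint64(0x2545F4914F6CDD1D)
_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_M2 = np.uint64(0x94D049BB133111EB)
_U53 = 1.0 / 9007199254740992.0  # 2^-53
_S12 = np.uint64(12)
_S25 = np.uint64(25)
_S27 = np.uint64(27)
_S11 = np.uint64(11)


@njit(cache=True, fastmath=True)
def _core(
    copy_slot,      # (M,) int32: l * amax + a of each typed gene copy
    owner_start,    # (N+1,) int32: copies of individual i are a contiguous
                    # block copy_slot[owner_start[i]:owner_start[i+1]]
    locus_lo,       # (L,) int32: first slot of locus l
    locus_hi,       # (L,) int32: one past the last used slot of locus l
    n_slots,
    lam,
    alpha_init,
    alpha_max,
    alpha_sd,       # <= 0 disables the alpha update (fixed alpha)
    adapt,          # nonzero: tune alpha_sd toward ~40% acceptance in burn-in
    burn,
    sweeps,
    thin,
    seed,
    track_idx,
):
    np.random.seed(seed)
    # splitmix64 expansion of the seed into the xorshift64* state
    state = (np.uint64(seed) + _SM_GAMMA) * _MULT
    state = (state ^ (state >> np.uint64(30))) * _SM_M1
    state = (state ^ (state >> _S27)) * _SM_M2
    state = state ^ (state >> np.uint64(31))
    if state == np.uint64(0):
        state = _SM_GAMMA

    N = owner_start.shape[0] - 1
    L = locus_lo.shape[0]

    P = np.zeros((2, n_slots))
    for l in range(L):
        w = 1.0 / (locus_hi[l] - locus_lo[l])
        for sl in range(locus_lo[l], locus_hi[l]):
            P[0, sl] = w
            P[1, sl] = w
    q = np.full((N, 2), 0.5)
    counts = np.zeros((2, n_slots))
    alpha = alpha_init
    sd = alpha_sd

    q_sum = np.zeros((N, 2))
    p_sum = np.zeros((2, n_slots))
    n_track = 0 if thin <= 0 else (sweeps + thin - 1) // thin
    trace = np.empty(n_track)
    kept = 0
    accepted = 0
    proposed = 0
    adapt_acc = 0
    adapt_n = 0

    max_copies = 0
    for i in range(N):
        c = owner_start[i + 1] - owner_start[i]
        if c > max_copies:
            max_copies = c
    zbuf = np.empty(max(max_copies, 1), dtype=np.int64)

    total = burn + sweeps
    for sweep in range(total):
        for sl in range(n_slots):
            counts[0, sl] = 0.0
            counts[1, sl] = 0.0
        slogq = 0.0
        # z update per gene copy, then the owner's ancestry q, then a
        # joint mode-swap proposal (flip all of i's origins and mirror q_i;
        # the ancestry prior and P(z|q) terms cancel, so the acceptance
        # ratio is the allele-emission likelihood ratio).  The swap lets a
        # weakly informative individual's bimodal posterior mix across its
        # two modes even when alpha is small and chains are short.
        for i in range(N):
            q0 = q[i, 0]
            q1 = q[i, 1]
            n0 = 0.0
            n1 = 0.0
            lo_i = owner_start[i]
            hi_i = owner_start[i + 1]
            lr = 1.0
            for c in range(lo_i, hi_i):
                sl = copy_slot[c]
                p0 = P[0, sl]
                p1 = P[1, sl]
                w0 = q0 * p0
                tot = w0 + q1 * p1
                state ^= state >> _S12
                state ^= state << _S25
                state ^= state >> _S27
                u = float((state * _MULT) >> _S11) * _U53
                if u * tot < w0:
                    counts[0, sl] += 1.0
                    n0 += 1.0
                    zbuf[c - lo_i] = 0
                    lr *= p1 / p0
                else:
                    counts[1, sl] += 1.0
                    n1 += 1.0
                    zbuf[c - lo_i] = 1
                    lr *= p0 / p1
            g0 = np.random.gamma(alpha + n0, 1.0)
            g1 = np.random.gamma(alpha + n1, 1.0)
            tot = g0 + g1
            q0 = g0 / tot
            q1 = g1 / tot
            if q0 < 1e-300:
                q0 = 1e-300
            if q1 < 1e-300:
                q1 = 1e-300
            # mode-swap Metropolis
            take = lr >= 1.0
            if not take:
                state ^= state >> _S12
                state ^= state << _S25
                state ^= state >> _S27
                u = float((state * _MULT) >> _S11) * _U53
                take = u < lr
            if take:
                for c in range(lo_i, hi_i):
                    sl = copy_slot[c]
                    k = zbuf[c - lo_i]
                    counts[k, sl] -= 1.0
                    counts[1 - k, sl] += 1.0
                q0, q1 = q1, q0
            q[i, 0] = q0
            q[i, 1] = q1
            slogq += math.log(q0) + math.log(q1)

        # cluster allele frequencies
        for k in range(2):
            for l in range(L):
                tot = 0.0
                for sl in range(locus_lo[l], locus_hi[l]):
                    g = np.random.gamma(lam + counts[k, sl], 1.0)
                    P[k, sl] = g
                    tot += g
                for sl in range(locus_lo[l], locus_hi[l]):
                    P[k, sl] /= tot

        # alpha Metropolis
        if alpha_sd > 0.0:
            prop = alpha + np.random.normal() * sd
            proposed += 1
            adapt_n += 1
            if 0.0 < prop <= alpha_max:
                delta = (
                    N * (math.lgamma(2 * prop) - 2 * math.lgamma(prop)
                         - math.lgamma(2 * alpha) + 2 * math.lgamma(alpha))
                    + (prop - alpha) * slogq
                )
                if delta >= 0.0 or np.random.random() < math.exp(delta):
                    alpha = prop
                    accepted += 1
                    adapt_acc += 1
            if adapt != 0 and sweep < burn and adapt_n >= 100:
                rate = adapt_acc / adapt_n
                if rate < 0.25:
                    sd *= 0.7
                elif rate > 0.55:
                    sd *= 1.4
                adapt_acc = 0
                adapt_n = 0

        if sweep >= burn:
            for i in range(N):
                q_sum[i, 0] += q[i, 0]
                q_sum[i, 1] += q[i, 1]
            for sl in range(n_slots):
                p_sum[0, sl] += P[0, sl]
                p_sum[1, sl] += P[1, sl]
            if thin > 0 and (sweep - burn) % thin == 0:
                trace[kept] = q[track_idx, 0]
                kept += 1

    q_mean = q_sum / sweeps
    p_mean = p_sum / sweeps
    acc_rate = accepted / proposed if proposed > 0 else np.nan
    return q_mean, trace[:kept], p_mean, acc_rate, alpha


def admixture_chain(
    alleles, n_alleles, lam, alpha_init, alpha_max, alpha_sd,
    burn, sweeps, thin, seed, track_idx, adapt=False,
):
    """Flatten an (N, L, 2) recoded panel and run one Gibbs chain.

    Returns ``(q_mean, trace, p_mean, acceptance_rate, alpha_final)`` with
    ``p_mean`` reshaped to (2, L, A_max); unused trailing allele slots of a
    locus stay at zero.
    """
    alleles = np.ascontiguousarray(alleles, dtype=np.int64)
    N, L = alleles.shape[0], alleles.shape[1]
    amax = int(np.max(n_alleles))
    typed = alleles >= 0
    per_ind = typed.sum(axis=(1, 2)).astype(np.int32)
    owner_start = np.zeros(N + 1, dtype=np.int32)
    np.cumsum(per_ind, out=owner_start[1:])
    locus_idx = np.broadcast_to(np.arange(L)[None, :, None], alleles.shape)
    # row-major flattening keeps each individual's copies contiguous
    copy_slot = (locus_idx * amax + alleles)[typed].astype(np.int32)
    locus_lo = (np.arange(L) * amax).astype(np.int32)
    locus_hi = (locus_lo + np.asarray(n_alleles)).astype(np.int32)

    q_mean, trace, p_flat, acc, alpha_final = _core(
        copy_slot, owner_start, locus_lo, locus_hi, L * amax,
        lam, alpha_init, alpha_max, alpha_sd, 1 if adapt else 0,
        burn, sweeps, thin, int(seed), track_idx,
    )
    return q_mean, trace, p_flat.reshape(2, L, amax), acc, alpha_final
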