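"""Low-level coalescent walker (numba).

A single kernel simulates backward-time genealogies of sampled genes under a
multi-deme demography with splits, admixture pulses and size changes, and
accumulates one of three things per replicate locus:

  mode 0  branch length per multidimensional descendant configuration
          (the Rao-Blackwellised expected-SFS accumulator),
  mode 1  Poisson-mutated segregating sites per configuration (an observed
          MSFS draw under infinite sites),
  mode 2  per-site leaf membership bitsets (for genotype/sequence emission).

Configurations index the count of subtended sampled genes per sampled deme in
mixed radix (first deme most significant), so numeric order on the flat index
equals lexicographic order on the count vector.

Randomness is a counter-based splitmix64 stream: each locus derives its state
from (seed, locus index), so enlarging n_loci never reshuffles earlier loci.
"""

import numpy as np
from numba import njit

_GOLD = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)


@njit(inline="always")
def _mix64(z):
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return z ^ (z >> np.uint64(31))


@njit(inline="always")
def _next_u64(state):
    # splitmix64: state is a 1-element uint64 array (mutated in place)
    state[0] = state[0] + _GOLD
    return _mix64(state[0])


@njit(inline="always")
def _u01(state):
    # uniform on (0, 1], never exactly 0 so log() is safe
    return (np.float64(_next_u64(state) >> np.uint64(11)) + 1.0) * (1.0 / 9007199254740992.0)


@njit(inline="always")
def _poisson(state, lam):
    # Knuth; branch-wise lambda is mu*L*dt, small in all intended regimes
    limit = np.exp(-lam)
    k = 0
    p = 1.0
    while True:
        p *= _u01(state)
        if p <= limit:
            return k
        k += 1


@njit(cache=False)
def walk(
    seed,
    rep0,
    n_reps,
    mode,
    sizes0,      # f8[D]   2N in gene-copy units
    init,        # i8[D]   sampled genes per deme
    samp_dim,    # i8[ns]  deme index of each sampled (config) dimension
    stride,      # i8[ns]  mixed-radix strides, first deme most significant
    ev_time,     # f8[E]
    ev_type,     # i8[E]   0 split(child a -> parent b), 1 pulse(dest a, src b, frac x), 2 size(deme a, 2N x)
    ev_a,
    ev_b,
    ev_x,
    mu_bp_l,     # f8      mutation rate per locus per generation (mu * L)
    out_len,     # f8[nconfig]   mode 0
    out_cnt,     # i8[nconfig]   mode 1
    site_words,  # u8 matrix: u64[cap, nwords]  mode 2
    site_rep,    # i8[cap]                       mode 2
    tmrca,       # f8[n_reps]
    totlen,      # f8[n_reps]
):
    """Run n_reps independent locus genealogies; returns number of sites
    written in mode 2 (or 0 otherwise), -1 on site-buffer overflow."""
    D = sizes0.shape[0]
    ns = samp_dim.shape[0]
    E = ev_time.shape[0]
    maxlin = 0
    for d in range(D):
        maxlin += init[d]
    nwords = site_words.shape[1]
    cap = site_rep.shape[0]

    sz = np.empty(D, np.float64)
    k = np.empty(D, np.int64)
    mem = np.empty((D, maxlin), np.int64)
    lin_deme = np.empty(maxlin, np.int64)
    lin_pos = np.empty(maxlin, np.int64)
    birth = np.empty(maxlin, np.float64)
    cfg = np.empty((maxlin, ns), np.int64)
    words = np.empty((maxlin, nwords), np.uint64)
    state = np.empty(1, np.uint64)

    nsite = 0
    for rep in range(n_reps):
        state[0] = _mix64((np.uint64(seed) + _GOLD) ^ (np.uint64(rep0 + rep) * _MIX1))
        # init lineages: one per sampled gene
        for d in range(D):
            sz[d] = sizes0[d]
            k[d] = 0
        lid = 0
        for s in range(ns):
            d = samp_dim[s]
            for _ in range(init[d]):
                mem[d, k[d]] = lid
                lin_pos[lid] = k[d]
                lin_deme[lid] = d
                k[d] += 1
                birth[lid] = 0.0
                for s2 in range(ns):
                    cfg[lid, s2] = 0
                cfg[lid, s] = 1
                if mode == 2:
                    for w in range(nwords):
                        words[lid, w] = np.uint64(0)
                    words[lid, lid >> 6] = np.uint64(1) << np.uint64(lid & 63)
                lid += 1
        nl = lid
        t = 0.0
        ep = 0
        tl = 0.0

        while nl > 1:
            rate = 0.0
            for d in range(D):
                if k[d] > 1:
                    rate += k[d] * (k[d] - 1) * 0.5 / sz[d]
            if rate > 0.0:
                tnext = t - np.log(_u01(state)) / rate
            else:
                if ep >= E:
                    break  # unreachable on a validated model
                tnext = np.inf
            if ep < E and ev_time[ep] <= tnext:
                # apply demographic event
                t = ev_time[ep]
                a = ev_a[ep]
                b = ev_b[ep]
                if ev_type[ep] == 0:
                    # split: move every lineage from child a to parent b
                    for i in range(k[a]):
                        l = mem[a, i]
                        mem[b, k[b]] = l
                        lin_pos[l] = k[b]
                        lin_deme[l] = b
                        k[b] += 1
                    k[a] = 0
                elif ev_type[ep] == 1:
                    # pulse: each lineage in dest a jumps to source b w.p. x
                    i = k[a] - 1
                    while i >= 0:
                        if _u01(state) <= ev_x[ep]:
                            l = mem[a, i]
                            last = mem[a, k[a] - 1]
                            mem[a, i] = last
                            lin_pos[last] = i
                            k[a] -= 1
                            mem[b, k[b]] = l
                            lin_pos[l] = k[b]
                            lin_deme[l] = b
                            k[b] += 1
                        i -= 1
                else:
                    sz[a] = ev_x[ep]
                ep += 1
                continue
            t = tnext
            # pick deme proportional to its pair rate
            r = _u01(state) * rate
            acc = 0.0
            d = -1
            for dd in range(D):
                if k[dd] > 1:
                    d = dd  # fallback: last eligible deme absorbs rounding slack
                    acc += k[dd] * (k[dd] - 1) * 0.5 / sz[dd]
                    if r <= acc:
                        break
            # pick an unordered pair
            ai = int(_u01(state) * k[d])
            if ai == k[d]:
                ai -= 1
            bi = int(_u01(state) * (k[d] - 1))
            if bi == k[d] - 1:
                bi -= 1
            if bi >= ai:
                bi += 1
            li = mem[d, ai]
            lj = mem[d, bi]
            # record both child branches
            for child in range(2):
                l = li if child == 0 else lj
                dt = t - birth[l]
                tl += dt
                if mode == 0:
                    idx = 0
                    for s in range(ns):
                        idx += cfg[l, s] * stride[s]
                    out_len[idx] += dt
                elif mode == 1:
                    m = _poisson(state, mu_bp_l * dt)
                    if m > 0:
                        idx = 0
                        for s in range(ns):
                            idx += cfg[l, s] * stride[s]
                        out_cnt[idx] += m
                else:
                    m = _poisson(state, mu_bp_l * dt)
                    for _ in range(m):
                        if nsite >= cap:
                            return -1
                        for w in range(nwords):
                            site_words[nsite, w] = words[l, w]
                        site_rep[nsite] = rep0 + rep
                        nsite += 1
            # merge: li becomes the parent, lj retires
            last = mem[d, k[d] - 1]
            mem[d, lin_pos[lj]] = last
            lin_pos[last] = lin_pos[lj]
            k[d] -= 1
            birth[li] = t
            for s in range(ns):
                cfg[li, s] += cfg[lj, s]
            if mode == 2:
                for w in range(nwords):
                    words[li, w] |= words[lj, w]
            nl -= 1

        tmrca[rep] = t
        totlen[rep] = tl
    return nsite
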