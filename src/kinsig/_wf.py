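"""Numba kernel for the haploid Wright-Fisher forward simulation.

One gene = one independent replicate (free recombination between genes,
full linkage within).  The population is a dense genotype matrix over the
currently segregating sites; fixed and lost columns are recycled each
generation, which keeps the working set at mutation-selection-drift
equilibrium size.  Fitness is multiplicative across deleterious sites,
w = (1 - s_eff)^k.  Infinite sites within the gene: a position currently
segregating cannot receive a second mutation (the draw is rejected and
redrawn); positions freed by loss or fixation become available again.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def wf_simulate(
    N: int,
    L: int,
    mu_site: float,
    s_eff: float,
    f_nonsyn: float,
    can_syn: np.ndarray,
    can_nonsyn: np.ndarray,
    generations: int,
    seed: int,
    cap: int,
):
    """Run one gene for `generations` and return the final population.

    Returns (genotypes (N, n_active) uint8, positions, is_deleterious,
    status); status < 0 signals capacity overflow (caller raises).
    """
    np.random.seed(seed)
    genoA = np.zeros((N, cap), dtype=np.uint8)
    genoB = np.zeros((N, cap), dtype=np.uint8)
    pos = np.zeros(cap, dtype=np.int32)
    is_del = np.zeros(cap, dtype=np.uint8)
    in_use = np.zeros(L, dtype=np.uint8)
    k_del = np.zeros(N, dtype=np.int32)
    nk = np.zeros(N, dtype=np.int32)
    colsum = np.zeros(cap, dtype=np.int32)
    cw = np.zeros(N, dtype=np.float64)
    maxk = 512
    wlut = np.empty(maxk, dtype=np.float64)
    for k in range(maxk):
        wlut[k] = (1.0 - s_eff) ** k
    lam = mu_site * L * N
    active = 0
    cur, nxt = genoA, genoB
    for _gen in range(generations):
        # cumulative fitness over individuals
        tot = 0.0
        for i in range(N):
            kk = k_del[i]
            if kk >= maxk:
                kk = maxk - 1
            tot += wlut[kk]
            cw[i] = tot
        for j in range(active):
            colsum[j] = 0
        # multinomial resampling proportional to fitness
        for i in range(N):
            rpick = np.random.random() * tot
            lo = 0
            hi = N - 1
            while lo < hi:
                mid = (lo + hi) >> 1
                if cw[mid] < rpick:
                    lo = mid + 1
                else:
                    hi = mid
            p = lo
            nk[i] = k_del[p]
            for j in range(active):
                v = cur[p, j]
                nxt[i, j] = v
                colsum[j] += v
        tmp = cur
        cur = nxt
        nxt = tmp
        tmpk = k_del
        k_del = nk
        nk = tmpk
        # recycle fixed / lost columns (order of columns is irrelevant)
        j = 0
        while j < active:
            cs = colsum[j]
            if cs == 0 or cs == N:
                in_use[pos[j]] = 0
                if cs == N and is_del[j] == 1:
                    for i in range(N):
                        k_del[i] -= 1
                last = active - 1
                if j != last:
                    for i in range(N):
                        cur[i, j] = cur[i, last]
                    pos[j] = pos[last]
                    is_del[j] = is_del[last]
                    colsum[j] = colsum[last]
                active = last
            else:
                j += 1
        # new mutations
        nm = np.random.poisson(lam)
        for _m in range(nm):
            if active >= cap:
                return cur[:, :active].copy(), pos[:active].copy(), is_del[:active].copy(), -1
            ddel = np.random.random() < f_nonsyn
            pp = -1
            for _try in range(10000):
                cand = np.random.randint(0, L)
                if in_use[cand] == 1:
                    continue
                if ddel:
                    if can_nonsyn[cand] == 1:
                        pp = cand
                        break
                else:
                    if can_syn[cand] == 1:
                        pp = cand
                        break
            if pp < 0:
                continue
            ind = np.random.randint(0, N)
            for i in range(N):
                cur[i, active] = 0
            cur[ind, active] = 1
            pos[active] = pp
            is_del[active] = 1 if ddel else 0
            in_use[pp] = 1
            if ddel:
                k_del[ind] += 1
            active += 1
    return cur[:, :active].copy(), pos[:active].copy(), is_del[:active].copy(), active
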