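"""Numba kernels for the per-iteration cell updates (hot loops).

Cells are processed in a uniformly shuffled order to avoid positional bias;
the occupancy grid enforces one cell per site.  Each kernel seeds numba's own
MT19937 stream from a seed drawn off the per-run Generator, so runs remain
bit-reproducible for a fixed root seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: the 26 Moore-neighbourhood offsets
MOORE = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)],
    dtype=np.int64,
)


@njit(cache=True)
def division_kernel(
    occ,  # bool (n, n, n), updated in place
    pos,  # int64 (N, 3)
    phenotype,  # uint8: 0 stem, 1 progenitor
    div_used,  # int64
    migratory,  # uint8: 0 low, 1 high
    senescent,  # bool, updated in place
    hypoxic,  # bool
    p_div: float,
    stem_div_prob: float,
    stem_sym_prob: float,
    p_high_daughter: float,
    hyp_factor: float,
    div_lim: int,
    offsets,  # (26, 3) int64
    seed: int,
):
    """One division sweep; returns daughter arrays and the division count.

    A non-senescent cell divides with its phenotype's probability (scaled by
    hyp_factor when hypoxic) iff an empty Moore neighbour exists; the daughter
    goes to a uniformly chosen empty neighbour.  Progenitor division consumes
    one of the lineage's remaining divisions: both resulting progenitors carry
    the incremented count and senesce at div_lim.  Stem cells divide
    symmetrically (two stems) with probability stem_sym_prob, else produce a
    fresh progenitor (count 0).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    nx, ny, nz = occ.shape
    order = np.random.permutation(n)
    d_pos = np.empty((n, 3), np.int64)
    d_phen = np.empty(n, np.uint8)
    d_used = np.empty(n, np.int64)
    d_mig = np.empty(n, np.uint8)
    d_hyp = np.empty(n, np.bool_)
    nd = 0
    cand = np.empty(26, np.int64)
    for oi in range(n):
        i = order[oi]
        if senescent[i]:
            continue
        prob = stem_div_prob if phenotype[i] == 0 else p_div
        if hypoxic[i]:
            prob *= hyp_factor
        if prob <= 0.0 or np.random.random() >= prob:
            continue
        x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
        cnt = 0
        for k in range(26):
            xx = x + offsets[k, 0]
            yy = y + offsets[k, 1]
            zz = z + offsets[k, 2]
            if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz and not occ[xx, yy, zz]:
                cand[cnt] = k
                cnt += 1
        if cnt == 0:
            continue  # spatial inhibition: fully surrounded cells cannot divide
        k = cand[np.random.randint(cnt)]
        xx = x + offsets[k, 0]
        yy = y + offsets[k, 1]
        zz = z + offsets[k, 2]
        occ[xx, yy, zz] = True
        d_pos[nd, 0] = xx
        d_pos[nd, 1] = yy
        d_pos[nd, 2] = zz
        d_mig[nd] = 1 if np.random.random() < p_high_daughter else 0
        d_hyp[nd] = hypoxic[i]
        if phenotype[i] == 0:
            if np.random.random() < stem_sym_prob:
                d_phen[nd] = 0
            else:
                d_phen[nd] = 1
            d_used[nd] = 0
        else:
            div_used[i] += 1
            if div_used[i] >= div_lim:
                senescent[i] = True
            d_phen[nd] = 1
            d_used[nd] = div_used[i]
        nd += 1
    return d_pos[:nd], d_phen[:nd], d_used[:nd], d_mig[:nd], d_hyp[:nd], nd


@njit(cache=True)
def migration_kernel(
    occ,  # bool (n, n, n), updated in place
    pos,  # int64 (N, 3), updated in place
    migratory,
    hypoxic,
    exp_low: float,  # expected lattice steps per iteration, low-migratory
    exp_high: float,
    offsets,
    seed: int,
):
    """One migration sweep; returns the number of realized single-site moves.

    Each cell takes k unit steps, k = floor(E) + Bernoulli(frac(E)) with E the
    class's expected steps per iteration (hypoxic cells use the high rate).
    Each step picks one of the 26 directions uniformly; steps that would exit
    the domain or enter an occupied site are rejected.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    nx, ny, nz = occ.shape
    order = np.random.permutation(n)
    moves = 0
    for oi in range(n):
        i = order[oi]
        e = exp_high if (migratory[i] == 1 or hypoxic[i]) else exp_low
        k = int(e)
        if np.random.random() < e - k:
            k += 1
        for _ in range(k):
            d = np.random.randint(26)
            xx = pos[i, 0] + offsets[d, 0]
            yy = pos[i, 1] + offsets[d, 1]
            zz = pos[i, 2] + offsets[d, 2]
            if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz and not occ[xx, yy, zz]:
                occ[pos[i, 0], pos[i, 1], pos[i, 2]] = False
                occ[xx, yy, zz] = True
                pos[i, 0] = xx
                pos[i, 1] = yy
                pos[i, 2] = zz
                moves += 1
    return moves
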