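"""Numba kernels for the hexagonal cellular Potts engine.

All kernels operate on an "odd-r" offset grid (see :mod:`utrisim.hexgrid`).
The medium / elastic boundary (EB) is cell id 0 and carries no volume or
surface constraint.  Energy conventions:

* contact term: ``c * JC`` per unordered heterotypic cell-cell link
  (``c = 2`` reproduces the ordered-pair double sum),
* boundary term: ``c * E * S**2`` where ``S`` is the number of unordered
  cell-EB links (the tissue perimeter).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# (parity, k, 0|1) -> (drow, dcol)
_OFFS = np.array(
    [
        [(0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0)],
        [(0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1)],
    ],
    dtype=np.int64,
)

SQRT3_2 = np.sqrt(3.0) / 2.0


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's internal RNG (separate state from numpy's)."""
    np.random.seed(seed)


@njit(cache=True)
def recount(owner, max_id, VT, lam_vol, ST, lam_surf, JC, E, c):
    """Brute-force bookkeeping and energy decomposition.

    Returns ``(volumes, surfaces, sumx, sumy, S, H_contact, H_vol, H_surf,
    H_boundary)`` where arrays are indexed by cell id (0 = EB, unconstrained).
    """
    h, w = owner.shape
    volumes = np.zeros(max_id + 1, dtype=np.int64)
    surfaces = np.zeros(max_id + 1, dtype=np.int64)
    sumx = np.zeros(max_id + 1, dtype=np.float64)
    sumy = np.zeros(max_id + 1, dtype=np.float64)
    S_ordered_cell_eb = 0
    cc_ordered = 0
    for r in range(h):
        par = r % 2
        y = r * SQRT3_2
        for cidx in range(w):
            a = owner[r, cidx]
            if a != 0:
                volumes[a] += 1
                sumx[a] += cidx + 0.5 * par
                sumy[a] += y
            for k in range(6):
                rr = r + _OFFS[par, k, 0]
                cc = cidx + _OFFS[par, k, 1]
                if rr < 0 or rr >= h or cc < 0 or cc >= w:
                    continue
                b = owner[rr, cc]
                if b == a:
                    continue
                if a != 0:
                    surfaces[a] += 1
                    if b == 0:
                        S_ordered_cell_eb += 1
                    else:
                        cc_ordered += 1
    S = S_ordered_cell_eb  # each cell-EB link seen once from the cell side
    H_contact = c * JC * (cc_ordered / 2.0)
    H_boundary = c * E * S * S
    H_vol = 0.0
    H_surf = 0.0
    for sig in range(1, max_id + 1):
        if volumes[sig] > 0:
            H_vol += lam_vol * (volumes[sig] - VT) ** 2
            H_surf += lam_surf * (surfaces[sig] - ST) ** 2
    return volumes, surfaces, sumx, sumy, S, H_contact, H_vol, H_surf, H_boundary


@njit(cache=True, inline="always")
def _local_counts(owner, tr, tc, A, B):
    """In-bounds neighbour count k and owner tallies (n0, nA, nB) at target."""
    h, w = owner.shape
    par = tr % 2
    k = 0
    n0 = 0
    nA = 0
    nB = 0
    for j in range(6):
        rr = tr + _OFFS[par, j, 0]
        cc = tc + _OFFS[par, j, 1]
        if rr < 0 or rr >= h or cc < 0 or cc >= w:
            continue
        k += 1
        o = owner[rr, cc]
        if o == 0:
            n0 += 1
        if o == A:
            nA += 1
        if o == B:
            nB += 1
    return k, n0, nA, nB


@njit(cache=True)
def proposal_delta(
    owner, volumes, surfaces, S, tr, tc, B, VT, lam_vol, ST, lam_surf, JC, E, c
):
    """Energy change for copying owner ``B`` onto the target site.

    Returns ``(dH, dS, dsA, dsB)``.  ``A`` (the current owner) is read from
    the grid; a same-owner proposal returns all zeros.
    """
    A = owner[tr, tc]
    if A == B:
        return 0.0, 0, 0, 0
    k, n0, nA, nB = _local_counts(owner, tr, tc, A, B)

    # tissue-perimeter (cell-EB unordered link) change
    s_old = (k - n0) if A == 0 else n0
    s_new = (k - n0) if B == 0 else n0
    dS = s_new - s_old

    # heterotypic cell-cell unordered link change
    cc_old = (k - n0 - nA) if A != 0 else 0
    cc_new = (k - n0 - nB) if B != 0 else 0

    dH = c * JC * (cc_new - cc_old) + c * E * (2.0 * S * dS + dS * dS)

    dsA = 0
    dsB = 0
    if A != 0:
        vA = volumes[A]
        sA = surfaces[A]
        dsA = 2 * nA - k
        if vA == 1:  # cell annihilated: its penalty terms vanish entirely
            dH -= lam_vol * (vA - VT) ** 2 + lam_surf * (sA - ST) ** 2
        else:
            dH += lam_vol * ((vA - 1 - VT) ** 2 - (vA - VT) ** 2)
            dH += lam_surf * ((sA + dsA - ST) ** 2 - (sA - ST) ** 2)
    if B != 0:
        vB = volumes[B]
        sB = surfaces[B]
        dsB = k - 2 * nB
        dH += lam_vol * ((vB + 1 - VT) ** 2 - (vB - VT) ** 2)
        dH += lam_surf * ((sB + dsB - ST) ** 2 - (sB - ST) ** 2)
    return dH, dS, dsA, dsB


@njit(cache=True)
def apply_copy(owner, volumes, surfaces, sumx, sumy, tr, tc, B, dS, dsA, dsB):
    """Commit an accepted copy; returns the perimeter change ``dS`` passthrough."""
    A = owner[tr, tc]
    x = tc + 0.5 * (tr % 2)
    y = tr * SQRT3_2
    owner[tr, tc] = B
    if A != 0:
        volumes[A] -= 1
        surfaces[A] += dsA
        sumx[A] -= x
        sumy[A] -= y
        if volumes[A] == 0:
            surfaces[A] = 0
            sumx[A] = 0.0
            sumy[A] = 0.0
    if B != 0:
        volumes[B] += 1
        surfaces[B] += dsB
        sumx[B] += x
        sumy[B] += y


@njit(cache=True, fastmath=True)
def run_mcs(
    owner,
    volumes,
    surfaces,
    sumx,
    sumy,
    S_box,
    Tm,
    VT,
    lam_vol,
    ST,
    lam_surf,
    JC,
    E,
    c,
):
    """One Monte Carlo step: ``height*width`` index-copy attempts.

    Picks a random target site and a random neighbour as copy source.
    Returns ``(n_accepted, edge_touch)``; ``edge_touch`` is 1 if a cell
    pixel was written on the lattice border (the caller should abort).
    The energy bookkeeping is the same as :func:`proposal_delta`, inlined
    for speed (equality is asserted by the oracle tests).
    """
    h, w = owner.shape
    n_attempts = h * w
    accepted = 0
    edge = 0
    S = S_box[0]
    for _ in range(n_attempts):
        u = np.random.randint(0, n_attempts * 6)  # one draw: site and direction
        j = u % 6
        u //= 6
        tr = u // w
        tc = u % w
        par = tr % 2
        sr = tr + _OFFS[par, j, 0]
        sc = tc + _OFFS[par, j, 1]
        if sr < 0 or sr >= h or sc < 0 or sc >= w:
            continue
        B = owner[sr, sc]
        A = owner[tr, tc]
        if A == B:
            continue
        k = 0
        n0 = 0
        nA = 0
        nB = 0
        for jj in range(6):
            rr = tr + _OFFS[par, jj, 0]
            cc = tc + _OFFS[par, jj, 1]
            if rr < 0 or rr >= h or cc < 0 or cc >= w:
                continue
            k += 1
            o = owner[rr, cc]
            if o == 0:
                n0 += 1
            if o == A:
                nA += 1
            if o == B:
                nB += 1
        s_old = (k - n0) if A == 0 else n0
        s_new = (k - n0) if B == 0 else n0
        dS = s_new - s_old
        cc_old = (k - n0 - nA) if A != 0 else 0
        cc_new = (k - n0 - nB) if B != 0 else 0
        dH = c * JC * (cc_new - cc_old) + c * E * (2.0 * S * dS + dS * dS)
        dsA = 0
        dsB = 0
        if A != 0:
            vA = volumes[A]
            sA = surfaces[A]
            dsA = 2 * nA - k
            if vA == 1:
                dH -= lam_vol * (vA - VT) ** 2 + lam_surf * (sA - ST) ** 2
            else:
                dH += lam_vol * ((vA - 1 - VT) ** 2 - (vA - VT) ** 2)
                dH += lam_surf * ((sA + dsA - ST) ** 2 - (sA - ST) ** 2)
        if B != 0:
            vB = volumes[B]
            sB = surfaces[B]
            dsB = k - 2 * nB
            dH += lam_vol * ((vB + 1 - VT) ** 2 - (vB - VT) ** 2)
            dH += lam_surf * ((sB + dsB - ST) ** 2 - (sB - ST) ** 2)
        if dH <= 0.0 or np.random.random() < np.exp(-dH / Tm):
            x = tc + 0.5 * par
            y = tr * SQRT3_2
            owner[tr, tc] = B
            if A != 0:
                volumes[A] -= 1
                surfaces[A] += dsA
                sumx[A] -= x
                sumy[A] -= y
                if volumes[A] == 0:
                    surfaces[A] = 0
                    sumx[A] = 0.0
                    sumy[A] = 0.0
            if B != 0:
                volumes[B] += 1
                surfaces[B] += dsB
                sumx[B] += x
                sumy[B] += y
                if tr == 0 or tr == h - 1 or tc == 0 or tc == w - 1:
                    edge = 1
            S += dS
            accepted += 1
    S_box[0] = S
    return accepted, edge


@njit(cache=True)
def surface_of_pixels(owner, rows, cols, cid):
    """Heterotypic-link count (surface) of the cell ``cid`` given its pixels."""
    h, w = owner.shape
    s = 0
    for i in range(rows.shape[0]):
        r = rows[i]
        cidx = cols[i]
        par = r % 2
        for k in range(6):
            rr = r + _OFFS[par, k, 0]
            cc = cidx + _OFFS[par, k, 1]
            if rr < 0 or rr >= h or cc < 0 or cc >= w:
                continue
            if owner[rr, cc] != cid:
                s += 1
    return s


@njit(cache=True)
def diffuse_secrete(M, alpha, nsub, src_rows, src_cols, amount_per_sub):
    """``nsub`` forward-Euler substeps of hex diffusion plus point secretion.

    ``alpha = D * dt_sub / h**2`` (dimensionless); the 6-neighbour hexagonal
    Laplacian is ``(2/3) * sum(M_j - M_i)`` at unit spacing.  No-flux
    boundaries arise naturally from the symmetric pairwise-difference form,
    which conserves total mass exactly.  Each source deposits
    ``amount_per_sub`` into its site per substep.
    """
    h, w = M.shape
    coef = 2.0 * alpha / 3.0
    lap = np.empty_like(M)
    for _ in range(nsub):
        for r in range(h):
            par = r % 2
            for cidx in range(w):
                m = M[r, cidx]
                acc = 0.0
                for k in range(6):
                    rr = r + _OFFS[par, k, 0]
                    cc = cidx + _OFFS[par, k, 1]
                    if rr < 0 or rr >= h or cc < 0 or cc >= w:
                        continue
                    acc += M[rr, cc] - m
                lap[r, cidx] = acc
        for r in range(h):
            for cidx in range(w):
                M[r, cidx] += coef * lap[r, cidx]
        for i in range(src_rows.shape[0]):
            M[src_rows[i], src_cols[i]] += amount_per_sub
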