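"""Numba hot loops for the lattice dynamics.

Everything here operates on flat arrays so the compiled code never touches
Python objects: ``owner`` is the flattened label lattice, ``nbr_*`` are
precomputed periodic neighbour-index tables, and the per-cell bookkeeping
arrays are indexed by cell identifier (0 is always Medium).

The random stream is a splitmix64 generator held in a one-element uint64
array, so a run is reproducible bit-for-bit from its integer seed and is
independent of NumPy's global state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _rng_next(state):
    state[0] = state[0] + _GOLDEN
    z = state[0]
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _rng_double(state):
    return (_rng_next(state) >> np.uint64(11)) * _INV53


@njit(cache=True, inline="always")
def _rng_below(state, n):
    # bias is O(n / 2**53): irrelevant for lattice-sized n
    return int((_rng_next(state) >> np.uint64(11)) * _INV53 * n)


@njit(cache=True)
def delta_h(
    owner,
    nbr_bdry,
    j_matrix,
    cell_type,
    partner,
    area,
    perim,
    target_area,
    target_perim,
    lam_area,
    lam_perim,
    t,
    src,
    touched,
    d_perim,
):
    """Energy change of copying cell ``src`` onto site ``t``.

    Fills ``touched``/``d_perim`` (scratch, length >= n_neighbours + 2) with
    the cells whose perimeter changes and by how much; returns
    ``(dH_total, d_boundary, n_touched)``.  The lattice is not modified.
    """
    tgt = owner[t]
    nb = nbr_bdry.shape[1]
    touched[0] = tgt
    touched[1] = src
    d_perim[0] = 0
    d_perim[1] = 0
    n_touched = 2
    d_boundary = 0.0
    for i in range(nb):
        q = nbr_bdry[t, i]
        oq = owner[q]
        if oq != tgt:
            if partner[tgt] != oq:
                d_boundary -= j_matrix[cell_type[tgt], cell_type[oq]]
            d_perim[0] -= 1
        if oq != src:
            if partner[src] != oq:
                d_boundary += j_matrix[cell_type[src], cell_type[oq]]
            d_perim[1] += 1
        # perimeter change seen from the neighbour's side of the link
        d = 0
        if oq != src:
            d += 1
        if oq != tgt:
            d -= 1
        if d != 0:
            slot = -1
            for m in range(n_touched):
                if touched[m] == oq:
                    slot = m
                    break
            if slot < 0:
                touched[n_touched] = oq
                d_perim[n_touched] = 0
                slot = n_touched
                n_touched += 1
            d_perim[slot] += d

    d_total = d_boundary

    a = float(area[src])
    ta = target_area[src]
    d_total += lam_area[src] * ((a + 1.0 - ta) ** 2 - (a - ta) ** 2)
    a = float(area[tgt])
    ta = target_area[tgt]
    d_total += lam_area[tgt] * ((a - 1.0 - ta) ** 2 - (a - ta) ** 2)

    for m in range(n_touched):
        c = touched[m]
        dp = d_perim[m]
        if dp != 0 and lam_perim[c] != 0.0:
            p = float(perim[c])
            tp = target_perim[c]
            d_total += lam_perim[c] * ((p + dp - tp) ** 2 - (p - tp) ** 2)

    return d_total, d_boundary, n_touched


@njit(cache=True)
def run_attempts(
    owner,
    nbr_copy,
    nbr_bdry,
    j_matrix,
    cell_type,
    partner,
    area,
    perim,
    target_area,
    target_perim,
    lam_area,
    lam_perim,
    alive,
    temperature,
    n_attempts,
    rng_state,
):
    """One batch of Metropolis copy attempts (a full MCS when
    n_attempts == lattice size).  Mutates owner / area / perim / alive in
    place.  Returns (n_accepted, accumulated boundary-energy change)."""
    n_sites = owner.shape[0]
    n_copy = nbr_copy.shape[1]
    touched = np.empty(nbr_bdry.shape[1] + 2, np.int64)
    d_perim = np.empty(nbr_bdry.shape[1] + 2, np.int64)
    accepted = 0
    d_boundary_total = 0.0
    for _ in range(n_attempts):
        t = _rng_below(rng_state, n_sites)
        s = nbr_copy[t, _rng_below(rng_state, n_copy)]
        src = owner[s]
        tgt = owner[t]
        if src == tgt:
            continue
        d_total, d_boundary, n_touched = delta_h(
            owner, nbr_bdry, j_matrix, cell_type, partner,
            area, perim, target_area, target_perim, lam_area, lam_perim,
            t, src, touched, d_perim,
        )
        if d_total > 0.0:
            if _rng_double(rng_state) >= np.exp(-d_total / temperature):
                continue
        owner[t] = src
        area[src] += 1
        area[tgt] -= 1
        for m in range(n_touched):
            perim[touched[m]] += d_perim[m]
        if area[tgt] == 0:
            alive[tgt] = False
        accepted += 1
        d_boundary_total += d_boundary
    return accepted, d_boundary_total


@njit(cache=True)
def type_contact_per_cell(owner, nbr_bdry, cell_type, n_ids, wanted_type):
    """Per-cell count of boundary links to sites owned by another cell of
    ``wanted_type``.  out[c] is the aggregate contact length CS of cell c."""
    out = np.zeros(n_ids, np.int64)
    nb = nbr_bdry.shape[1]
    for p in range(owner.shape[0]):
        c = owner[p]
        for i in range(nb):
            oq = owner[nbr_bdry[p, i]]
            if oq != c and cell_type[oq] == wanted_type:
                out[c] += 1
    return out
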