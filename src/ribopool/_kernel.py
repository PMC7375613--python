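"""Compiled tick loop of the translation engine.

Everything here operates on the flat numpy arrays packed by
:mod:`ribopool.engine`.  The per-lattice step functions are exposed so the
Python-level ``step_initiation`` / ``step_elongation`` wrappers and the
multi-tick driver share a single implementation.

State encodings
---------------
initiation machine: 0 = IDLE, 1 = AWAIT_RIBOSOME (timer running)
ribosome machine:   0 = AWAIT_TRNA, 1 = ELONGATING (translocation timer),
                    2 = BLOCKED (downstream footprint too close)

Ribosomes of a lattice are stored front-to-back: slot 0 is the one
closest to the 3' end.  A-site positions are 1-based codon indices.
"""

import numpy as np
from numba import njit

INIT_IDLE = 0
INIT_WAIT = 1
RIB_WAIT_TRNA = 0
RIB_ELONG = 1
RIB_BLOCKED = 2

_U30 = np.uint64(30)
_U27 = np.uint64(27)
_U31 = np.uint64(31)
_U11 = np.uint64(11)
_C1 = np.uint64(0x9E3779B97F4A7C15)
_C2 = np.uint64(0xBF58476D1CE4E5B9)
_C3 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53
_MAX_TICKS = 2**31


@njit(cache=True, inline="always")
def _rand_u64(rng):
    # splitmix64; rng is a 1-element uint64 array
    rng[0] = rng[0] + _C1
    z = rng[0]
    z = (z ^ (z >> _U30)) * _C2
    z = (z ^ (z >> _U27)) * _C3
    return z ^ (z >> _U31)


@njit(cache=True, inline="always")
def _rand_float(rng):
    return float(_rand_u64(rng) >> _U11) * _INV53


@njit(cache=True)
def _shuffle(rng, perm):
    n = perm.shape[0]
    for i in range(n):
        perm[i] = i
    for i in range(n - 1, 0, -1):
        j = int(_rand_u64(rng) % np.uint64(i + 1))
        tmp = perm[i]
        perm[i] = perm[j]
        perm[j] = tmp


@njit(cache=True, inline="always")
def _to_ticks(seconds, dt, cap):
    # waits are capped so a machine whose ratio was sampled in a starved
    # moment re-evaluates instead of sleeping through the whole run
    t = int(np.floor(seconds / dt + 0.5))
    if t < 1:
        return 1
    if t > cap:
        return cap
    return t


@njit(cache=True, inline="always")
def _esdr_one(cid, H_free, D, c2t_off, c2t_j, c2t_a, exp_c):
    total = 0.0
    ex = exp_c[cid]
    for t in range(c2t_off[cid], c2t_off[cid + 1]):
        d = D[c2t_j[t]]
        if d < 1.0:
            d = 1.0
        total += c2t_a[t] * H_free[c2t_j[t]] / d**ex
    return total


@njit(cache=True, inline="always")
def _add_demand(cid, delta, codon_demand, D, c2t_off, c2t_j, c2t_a):
    codon_demand[cid] += delta
    for t in range(c2t_off[cid], c2t_off[cid + 1]):
        D[c2t_j[t]] += c2t_a[t] * delta


@njit(cache=True)
def _alloc_trna(cid, H_free, bound, rng, c2t_off, c2t_j, c2t_a):
    """Weighted pick (alpha * H_free) among non-exhausted decoders.

    Returns the chosen species index and mutates the pools, or -1 if every
    decoder is exhausted (no mutation)."""
    total = 0.0
    for t in range(c2t_off[cid], c2t_off[cid + 1]):
        if H_free[c2t_j[t]] > 0:
            total += c2t_a[t] * H_free[c2t_j[t]]
    if total <= 0.0:
        return -1
    u = _rand_float(rng) * total
    acc = 0.0
    pick = -1
    for t in range(c2t_off[cid], c2t_off[cid + 1]):
        if H_free[c2t_j[t]] > 0:
            pick = c2t_j[t]
            acc += c2t_a[t] * H_free[c2t_j[t]]
            if u < acc:
                break
    H_free[pick] -= 1
    bound[pick] += 1
    return pick


@njit(cache=True)
def _enter_await_trna(
    i, k, pos,
    lat_codons, lat_off,
    rib_state, rib_timer,
    H_free, D, codon_demand,
    c2t_off, c2t_j, c2t_a, exp_c,
    scale_elong, eps, dt, max_wait,
):
    cid = lat_codons[lat_off[i] + pos - 1]
    _add_demand(cid, 1, codon_demand, D, c2t_off, c2t_j, c2t_a)
    sdr = _esdr_one(cid, H_free, D, c2t_off, c2t_j, c2t_a, exp_c)
    if sdr < eps:
        sdr = eps
    rib_state[i, k] = RIB_WAIT_TRNA
    rib_timer[i, k] = _to_ticks(scale_elong / sdr, dt, max_wait)


@njit(cache=True)
def step_init_lattice(
    i,
    lat_codons, lat_off, lat_init_sec,
    init_state, init_timer,
    rib_pos, rib_state, rib_timer, rib_ta, rib_te, rib_n,
    scal, H_free, bound, codon_demand, D,
    c2t_off, c2t_j, c2t_a, exp_c,
    dt, s, rsdr_ref, scale_elong, eps, max_wait,
):
    """One tick of the initiation machine of lattice ``i``.

    Returns 1 if a ribosome was placed this tick, else 0.
    """
    if init_state[i] == INIT_IDLE:
        init_state[i] = INIT_WAIT
        scal[1] += 1  # init_demand
        dem = scal[1]
        if dem < 1:
            dem = 1
        ratio = scal[0] / dem
        if ratio < eps:
            ratio = eps
        init_timer[i] = _to_ticks(
            lat_init_sec[i] * rsdr_ref / ratio, dt, max_wait
        )
        return 0
    if init_timer[i] > 0:
        init_timer[i] -= 1
    if init_timer[i] > 0:
        return 0
    # timer expired: place if a ribosome is free and the 5' end is clear
    n = rib_n[i]
    if scal[0] <= 0:
        return 0  # delayed, re-checked next tick
    if n > 0 and rib_pos[i, n - 1] <= s:
        return 0
    rib_pos[i, n] = 1
    rib_ta[i, n] = -1
    rib_te[i, n] = -1
    rib_n[i] = n + 1
    _enter_await_trna(
        i, n, 1, lat_codons, lat_off, rib_state, rib_timer,
        H_free, D, codon_demand, c2t_off, c2t_j, c2t_a, exp_c,
        scale_elong, eps, dt, max_wait,
    )
    scal[0] -= 1
    scal[1] -= 1
    init_state[i] = INIT_IDLE
    return 1


@njit(cache=True)
def step_elong_lattice(
    i,
    lat_codons, lat_off,
    rib_pos, rib_state, rib_timer, rib_ta, rib_te, rib_n,
    scal, H_free, bound, codon_demand, D,
    c2t_off, c2t_j, c2t_a, exp_c,
    rng,
    dt, s, scale_elong, eps, transloc_ticks, max_wait,
):
    """One tick of every ribosome machine on lattice ``i``, front to back.

    Returns the number of termination events.
    """
    L = lat_off[i + 1] - lat_off[i]
    terms = 0
    k = 0
    while k < rib_n[i]:
        st = rib_state[i, k]
        if rib_timer[i, k] > 0:
            rib_timer[i, k] -= 1
        if st == RIB_WAIT_TRNA:
            if rib_timer[i, k] == 0:
                cid = lat_codons[lat_off[i] + rib_pos[i, k] - 1]
                j = _alloc_trna(
                    cid, H_free, bound, rng, c2t_off, c2t_j, c2t_a
                )
                if j >= 0:
                    _add_demand(
                        cid, -1, codon_demand, D, c2t_off, c2t_j, c2t_a
                    )
                    rib_ta[i, k] = j
                    rib_state[i, k] = RIB_ELONG
                    rib_timer[i, k] = transloc_ticks
                # on failure the timer stays at 0: retried next tick
            k += 1
            continue
        # ELONGATING with expired timer, or BLOCKED: try to translocate
        if st == RIB_ELONG and rib_timer[i, k] > 0:
            k += 1
            continue
        p = rib_pos[i, k]
        if k > 0 and rib_pos[i, k - 1] - p < s + 1:
            rib_state[i, k] = RIB_BLOCKED  # re-checked every tick
            k += 1
            continue
        # move: release the old E-site tRNA, shift A->E
        old_e = rib_te[i, k]
        if old_e >= 0:
            bound[old_e] -= 1
            H_free[old_e] += 1
        carried = rib_ta[i, k]
        rib_ta[i, k] = -1
        if p + 1 > L:
            # termination: release the last tRNA, free the ribosome
            if carried >= 0:
                bound[carried] -= 1
                H_free[carried] += 1
            scal[0] += 1
            for m in range(k, rib_n[i] - 1):
                rib_pos[i, m] = rib_pos[i, m + 1]
                rib_state[i, m] = rib_state[i, m + 1]
                rib_timer[i, m] = rib_timer[i, m + 1]
                rib_ta[i, m] = rib_ta[i, m + 1]
                rib_te[i, m] = rib_te[i, m + 1]
            rib_n[i] -= 1
            terms += 1
            # do not advance k: the shifted-in ribosome is processed next
            continue
        rib_te[i, k] = carried
        rib_pos[i, k] = p + 1
        _enter_await_trna(
            i, k, p + 1, lat_codons, lat_off, rib_state, rib_timer,
            H_free, D, codon_demand, c2t_off, c2t_j, c2t_a, exp_c,
            scale_elong, eps, dt, max_wait,
        )
        k += 1
    return terms


@njit(cache=True)
def run_ticks(
    n_ticks, tick0,
    lat_codons, lat_off, lat_gene, lat_init_sec,
    init_state, init_timer,
    rib_pos, rib_state, rib_timer, rib_ta, rib_te, rib_n,
    scal, H_free, bound, codon_demand, D,
    c2t_off, c2t_j, c2t_a, exp_c,
    rng, perm,
    dt, s, rsdr_ref, scale_elong, eps, transloc_ticks, max_wait,
    # outputs (preallocated by the caller, length n_ticks unless noted)
    traj_gfree, traj_bound_rib, traj_hfree_sum, traj_bound_trna,
    tick_inits, tick_terms,
    esdr_traj,            # (n_ticks, 61)
    occupancy,            # flat, aligned with lat_codons
    gene_term,            # cumulative per-gene termination counts
    term_snap, hfree_snap, snap_every,   # (n_snaps, n_genes)/(n_snaps, n_trna)
):
    n_lat = rib_n.shape[0]
    n_trna = H_free.shape[0]
    for tick in range(n_ticks):
        _shuffle(rng, perm)
        inits = 0
        terms = 0
        for x in range(n_lat):
            i = perm[x]
            inits += step_init_lattice(
                i, lat_codons, lat_off, lat_init_sec, init_state,
                init_timer, rib_pos, rib_state, rib_timer, rib_ta, rib_te,
                rib_n, scal, H_free, bound, codon_demand, D,
                c2t_off, c2t_j, c2t_a, exp_c,
                dt, s, rsdr_ref, scale_elong, eps, max_wait,
            )
            t = step_elong_lattice(
                i, lat_codons, lat_off, rib_pos, rib_state, rib_timer,
                rib_ta, rib_te, rib_n, scal, H_free, bound, codon_demand,
                D, c2t_off, c2t_j, c2t_a, exp_c, rng,
                dt, s, scale_elong, eps, transloc_ticks, max_wait,
            )
            terms += t
            if t > 0:
                gene_term[lat_gene[i]] += t
        # per-tick accounting, counted from the lattices (not the ledger)
        nb_rib = 0
        nb_trna = 0
        for i in range(n_lat):
            n = rib_n[i]
            nb_rib += n
            base = lat_off[i]
            for k in range(n):
                occupancy[base + rib_pos[i, k] - 1] += 1
                if rib_ta[i, k] >= 0:
                    nb_trna += 1
                if rib_te[i, k] >= 0:
                    nb_trna += 1
        hsum = np.int64(0)
        for j in range(n_trna):
            hsum += H_free[j]
        traj_gfree[tick] = scal[0]
        traj_bound_rib[tick] = nb_rib
        traj_hfree_sum[tick] = hsum
        traj_bound_trna[tick] = nb_trna
        tick_inits[tick] = inits
        tick_terms[tick] = terms
        for c in range(esdr_traj.shape[1]):
            esdr_traj[tick, c] = _esdr_one(
                c, H_free, D, c2t_off, c2t_j, c2t_a, exp_c
            )
        g = tick0 + tick
        if snap_every > 0 and (g + 1) % snap_every == 0:
            row = (g + 1) // snap_every - 1
            if 0 <= row < term_snap.shape[0]:
                for gi in range(gene_term.shape[0]):
                    term_snap[row, gi] = gene_term[gi]
                for j in range(n_trna):
                    hfree_snap[row, j] = H_free[j]
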