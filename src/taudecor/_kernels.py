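"""Numba kernels for the kinetic Monte Carlo lattice simulation.

The lattice is ``h x p`` (rows = dimers along a protofilament, columns =
protofilaments).  A p-mode molecule anchored at (i, j) occupies rows
i..i+sigma_p of column j; an h-mode molecule occupies columns
j..j+sigma_h of row i.  Boundaries are open along the protofilament
axis and non-wrapping across it (the seam forbids lateral molecules
crossing from the last protofilament back to the first).

State arrays:
  occ_mode  int8[h, p]   -1 empty, 0 p-molecule, 1 h-molecule
  anc_i/j   int32[h, p]  anchor coordinates written on every covered site
  valid_p/h uint8[h, p]  anchor admissibility maps

The admissible anchors of each mode are additionally kept in a dense
index list (with a reverse position map) so that a uniformly random
anchor is drawn in O(1) even near saturation, where the admissible set
is a vanishing fraction of the lattice.
"""

import numpy as np
from numba import njit

__all__ = ["run_kmc", "census_parallel", "census_perp"]


@njit(cache=True, inline="always")
def _valid_p_at(occ_mode, i, j, sigma_p, h):
    if i + sigma_p >= h:
        return False
    for t in range(sigma_p + 1):
        if occ_mode[i + t, j] >= 0:
            return False
    return True


@njit(cache=True, inline="always")
def _valid_h_at(occ_mode, i, j, sigma_h, p):
    if j + sigma_h >= p:
        return False
    for t in range(sigma_h + 1):
        if occ_mode[i, j + t] >= 0:
            return False
    return True


@njit(cache=True, inline="always")
def _list_add(site, anchor_list, anchor_pos, count):
    anchor_list[count] = site
    anchor_pos[site] = count
    return count + 1


@njit(cache=True, inline="always")
def _list_remove(site, anchor_list, anchor_pos, count):
    idx = anchor_pos[site]
    last = anchor_list[count - 1]
    anchor_list[idx] = last
    anchor_pos[last] = idx
    anchor_pos[site] = -1
    return count - 1


@njit(cache=True)
def _refresh(
    occ_mode,
    valid_p,
    valid_h,
    list_p,
    pos_p,
    list_h,
    pos_h,
    m_p,
    m_h,
    fi0,
    fi1,
    fj0,
    fj1,
    sigma_p,
    sigma_h,
    h,
    p,
):
    """Recompute anchor validity around footprint rows fi0..fi1, cols fj0..fj1.

    Flipped anchors are pushed to / removed from the per-mode anchor
    lists; returns the updated (m_p, m_h) list sizes.
    """
    i_lo = max(0, fi0 - sigma_p)
    for i in range(i_lo, min(fi1, h - 1) + 1):
        for j in range(fj0, fj1 + 1):
            new = 1 if _valid_p_at(occ_mode, i, j, sigma_p, h) else 0
            if new != valid_p[i, j]:
                valid_p[i, j] = new
                site = i * p + j
                if new == 1:
                    m_p = _list_add(site, list_p, pos_p, m_p)
                else:
                    m_p = _list_remove(site, list_p, pos_p, m_p)
    j_lo = max(0, fj0 - sigma_h)
    for i in range(fi0, min(fi1, h - 1) + 1):
        for j in range(j_lo, min(fj1, p - 1) + 1):
            new = 1 if _valid_h_at(occ_mode, i, j, sigma_h, p) else 0
            if new != valid_h[i, j]:
                valid_h[i, j] = new
                site = i * p + j
                if new == 1:
                    m_h = _list_add(site, list_h, pos_h, m_h)
                else:
                    m_h = _list_remove(site, list_h, pos_h, m_h)
    return m_p, m_h


@njit(cache=True)
def census_parallel(occ_mode, anc_i, sigma_p, hist, pair_hist, rmax_half):
    """Accumulate nearest-neighbor center distances along every protofilament.

    Distances are recorded in half-site units (a p-molecule's center sits
    at i + sigma_p/2, an h-molecule crosses each protofilament at a single
    site).  ``pair_hist`` resolves the (mode_left, mode_right) identity.
    """
    h, p = occ_mode.shape
    for j in range(p):
        prev_c = -1
        prev_m = -1
        for i in range(h):
            m = occ_mode[i, j]
            if m < 0:
                continue
            if m == 0:
                if anc_i[i, j] != i:
                    continue
                c = 2 * i + sigma_p
            else:
                c = 2 * i
            if prev_c >= 0:
                d = c - prev_c
                if d <= rmax_half:
                    hist[d] += 1.0
                    pair_hist[prev_m, m, d] += 1.0
            prev_c = c
            prev_m = m


@njit(cache=True)
def census_perp(occ_mode, anc_j, sigma_h, hist, pair_hist, rmax_half):
    """Accumulate nearest-neighbor center distances along every helix row."""
    h, p = occ_mode.shape
    for i in range(h):
        prev_c = -1
        prev_m = -1
        for j in range(p):
            m = occ_mode[i, j]
            if m < 0:
                continue
            if m == 1:
                if anc_j[i, j] != j:
                    continue
                c = 2 * j + sigma_h
            else:
                c = 2 * j
            if prev_c >= 0:
                d = c - prev_c
                if d <= rmax_half:
                    hist[d] += 1.0
                    pair_hist[prev_m, m, d] += 1.0
            prev_c = c
            prev_m = m


@njit(cache=True)
def _attach(
    occ_mode, anc_i, anc_j, valid_p, valid_h,
    list_p, pos_p, list_h, pos_h, m_p, m_h,
    mode, i, j, sigma_p, sigma_h, h, p,
):
    if mode == 0:
        for t in range(sigma_p + 1):
            occ_mode[i + t, j] = 0
            anc_i[i + t, j] = i
            anc_j[i + t, j] = j
        return _refresh(
            occ_mode, valid_p, valid_h, list_p, pos_p, list_h, pos_h, m_p, m_h,
            i, i + sigma_p, j, j, sigma_p, sigma_h, h, p,
        )
    for t in range(sigma_h + 1):
        occ_mode[i, j + t] = 1
        anc_i[i, j + t] = i
        anc_j[i, j + t] = j
    return _refresh(
        occ_mode, valid_p, valid_h, list_p, pos_p, list_h, pos_h, m_p, m_h,
        i, i, j, j + sigma_h, sigma_p, sigma_h, h, p,
    )


@njit(cache=True)
def _detach(
    occ_mode, anc_i, anc_j, valid_p, valid_h,
    list_p, pos_p, list_h, pos_h, m_p, m_h,
    mode, i, j, sigma_p, sigma_h, h, p,
):
    if mode == 0:
        for t in range(sigma_p + 1):
            occ_mode[i + t, j] = -1
        return _refresh(
            occ_mode, valid_p, valid_h, list_p, pos_p, list_h, pos_h, m_p, m_h,
            i, i + sigma_p, j, j, sigma_p, sigma_h, h, p,
        )
    for t in range(sigma_h + 1):
        occ_mode[i, j + t] = -1
    return _refresh(
        occ_mode, valid_p, valid_h, list_p, pos_p, list_h, pos_h, m_p, m_h,
        i, i, j, j + sigma_h, sigma_p, sigma_h, h, p,
    )


@njit(cache=True)
def run_kmc(
    h,
    p,
    sigma_p,
    sigma_h,
    kp,
    kh,
    n_tau_total,
    grand_canonical,
    x,
    burnin_time,
    n_samples,
    sample_interval,
    seed,
    rmax_half,
    collect_hist,
    n_batches,
    n_trace,
):
    """Gillespie simulation of reversible two-mode adsorption.

    Per-anchor attach propensity in mode i is k_eq_i * c_free (with
    c_free = n_free/N canonically or the fixed ratio x grand-canonically)
    and per-molecule detach propensity is 1 (time is measured in mean
    bound lifetimes), so the stationary state satisfies detailed balance
    with the equilibrium isotherms.

    Configurations are recorded on a uniform grid of simulated time
    (never per event: the embedded jump chain weights states by their
    total exit rate and is a biased sample of the stationary law).

    Returns the sampled mode counts, batch-resolved spacing histograms in
    half-site units, the aggregate pair-type histograms, a burn-in
    coverage trace, the final lattice grids and the total simulated time.
    """
    np.random.seed(seed)
    N = h * p
    occ_mode = np.full((h, p), -1, np.int8)
    anc_i = np.full((h, p), -1, np.int32)
    anc_j = np.full((h, p), -1, np.int32)
    valid_p = np.zeros((h, p), np.uint8)
    valid_h = np.zeros((h, p), np.uint8)
    list_p = np.zeros(N, np.int64)
    list_h = np.zeros(N, np.int64)
    pos_p = np.full(N, -1, np.int64)
    pos_h = np.full(N, -1, np.int64)
    m_p = 0
    m_h = 0
    for i in range(h):
        for j in range(p):
            if _valid_p_at(occ_mode, i, j, sigma_p, h):
                valid_p[i, j] = 1
                m_p = _list_add(i * p + j, list_p, pos_p, m_p)
            if _valid_h_at(occ_mode, i, j, sigma_h, p):
                valid_h[i, j] = 1
                m_h = _list_add(i * p + j, list_h, pos_h, m_h)

    # grand-canonical runs are capped by lattice capacity, not the reservoir
    cap = N if grand_canonical else max(n_tau_total, 1)
    bound_p_i = np.zeros(cap, np.int32)
    bound_p_j = np.zeros(cap, np.int32)
    bound_h_i = np.zeros(cap, np.int32)
    bound_h_j = np.zeros(cap, np.int32)
    n_p = 0
    n_h = 0

    samp_p = np.zeros(n_samples, np.int64)
    samp_h = np.zeros(n_samples, np.int64)
    nbins = rmax_half + 1
    hist_par = np.zeros((n_batches, nbins))
    hist_perp = np.zeros((n_batches, nbins))
    pair_par = np.zeros((2, 2, nbins))
    pair_perp = np.zeros((2, 2, nbins))
    trace_p = np.zeros(n_trace, np.int64)
    trace_h = np.zeros(n_trace, np.int64)
    trace_dt = burnin_time / max(n_trace, 1)

    t_sim = 0.0
    s_idx = 0
    tr_idx = 0
    while s_idx < n_samples:
        if grand_canonical:
            c_free = x
        else:
            c_free = (n_tau_total - n_p - n_h) / N
        r_pa = kp * c_free * m_p
        r_ha = kh * c_free * m_h
        r_pd = 1.0 * n_p
        r_hd = 1.0 * n_h
        r_tot = r_pa + r_ha + r_pd + r_hd
        if r_tot <= 0.0:
            # absorbing: no Tau in the system at all; the state is frozen,
            # so every remaining grid point records the current counts
            while tr_idx < n_trace:
                trace_p[tr_idx] = n_p
                trace_h[tr_idx] = n_h
                tr_idx += 1
            while s_idx < n_samples:
                samp_p[s_idx] = n_p
                samp_h[s_idx] = n_h
                s_idx += 1
            break
        dt = -np.log(np.random.random()) / r_tot
        # the state is constant on [t_sim, t_sim + dt): record every grid
        # point that falls inside the interval before executing the event
        while tr_idx < n_trace and tr_idx * trace_dt < t_sim + dt:
            trace_p[tr_idx] = n_p
            trace_h[tr_idx] = n_h
            tr_idx += 1
        while (
            s_idx < n_samples
            and burnin_time + (s_idx + 1) * sample_interval <= t_sim + dt
        ):
            samp_p[s_idx] = n_p
            samp_h[s_idx] = n_h
            if collect_hist:
                b = s_idx * n_batches // n_samples
                census_parallel(
                    occ_mode, anc_i, sigma_p, hist_par[b], pair_par, rmax_half
                )
                census_perp(occ_mode, anc_j, sigma_h, hist_perp[b], pair_perp, rmax_half)
            s_idx += 1
        if s_idx >= n_samples:
            t_sim += dt
            break
        t_sim += dt
        u = np.random.random() * r_tot
        if u < r_pa:
            site = list_p[np.random.randint(0, m_p)]
            i = site // p
            j = site % p
            m_p, m_h = _attach(
                occ_mode, anc_i, anc_j, valid_p, valid_h,
                list_p, pos_p, list_h, pos_h, m_p, m_h,
                0, i, j, sigma_p, sigma_h, h, p,
            )
            bound_p_i[n_p] = i
            bound_p_j[n_p] = j
            n_p += 1
        elif u < r_pa + r_ha:
            site = list_h[np.random.randint(0, m_h)]
            i = site // p
            j = site % p
            m_p, m_h = _attach(
                occ_mode, anc_i, anc_j, valid_p, valid_h,
                list_p, pos_p, list_h, pos_h, m_p, m_h,
                1, i, j, sigma_p, sigma_h, h, p,
            )
            bound_h_i[n_h] = i
            bound_h_j[n_h] = j
            n_h += 1
        elif u < r_pa + r_ha + r_pd:
            idx = np.random.randint(0, n_p)
            i = bound_p_i[idx]
            j = bound_p_j[idx]
            m_p, m_h = _detach(
                occ_mode, anc_i, anc_j, valid_p, valid_h,
                list_p, pos_p, list_h, pos_h, m_p, m_h,
                0, i, j, sigma_p, sigma_h, h, p,
            )
            n_p -= 1
            bound_p_i[idx] = bound_p_i[n_p]
            bound_p_j[idx] = bound_p_j[n_p]
        else:
            idx = np.random.randint(0, n_h)
            i = bound_h_i[idx]
            j = bound_h_j[idx]
            m_p, m_h = _detach(
                occ_mode, anc_i, anc_j, valid_p, valid_h,
                list_p, pos_p, list_h, pos_h, m_p, m_h,
                1, i, j, sigma_p, sigma_h, h, p,
            )
            n_h -= 1
            bound_h_i[idx] = bound_h_i[n_h]
            bound_h_j[idx] = bound_h_j[n_h]

    return (
        samp_p,
        samp_h,
        hist_par,
        hist_perp,
        pair_par,
        pair_perp,
        trace_p,
        trace_h,
        occ_mode,
        anc_i,
        anc_j,
        t_sim,
    )
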