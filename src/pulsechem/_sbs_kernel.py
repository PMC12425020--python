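"""Compiled inner loop of the step-by-step engine.

Mirrors the reference implementation in :mod:`pulsechem.particle_engine`
(Gaussian jumps, periodic wrapping, minimum-image cell-list reaction sweep,
nearest-first greedy pair resolution) but runs the whole time loop inside a
single numba kernel.  The pure-Python path remains the behavioural oracle;
unit tests check the two agree statistically.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _wrap(x, L):  # pragma: no cover - jitted
    x = (x + 0.5 * L) % L - 0.5 * L
    if x >= 0.5 * L:
        x -= L
    return x


@njit(cache=True, inline="always")
def _min_image(dx, L):  # pragma: no cover - jitted
    return dx - L * np.floor(dx / L + 0.5)


@njit(cache=True)
def _sweep(pos, sp, n_live, L, rlookup, radius, prods, sqrt_d, counts,
           event_counts, jitter, r_max):  # pragma: no cover - jitted
    """One reaction sweep; returns the new number of live particles."""
    if n_live < 2 or r_max <= 0.0:
        return n_live
    # linked-cell grid: cells no smaller than the largest reaction radius,
    # no more than ~4 cells per particle so the head array stays O(n)
    ncell_max = int(L / r_max)
    ncell_tgt = int((4.0 * n_live) ** (1.0 / 3.0))
    ncell = ncell_tgt if ncell_tgt < ncell_max else ncell_max
    cand_cap = 64 + 4 * n_live
    ci = np.empty(cand_cap, np.int64)
    cj = np.empty(cand_cap, np.int64)
    cm = np.empty(cand_cap, np.int64)
    cd = np.empty(cand_cap, np.float64)
    k = 0
    if ncell < 3:
        for i in range(n_live):
            for j in range(i + 1, n_live):
                m = rlookup[sp[i], sp[j]]
                if m < 0:
                    continue
                dx = _min_image(pos[j, 0] - pos[i, 0], L)
                dy = _min_image(pos[j, 1] - pos[i, 1], L)
                dz = _min_image(pos[j, 2] - pos[i, 2], L)
                d2 = dx * dx + dy * dy + dz * dz
                r = radius[m]
                if d2 <= r * r and k < cand_cap:
                    ci[k] = i
                    cj[k] = j
                    cm[k] = m
                    cd[k] = np.sqrt(d2)
                    k += 1
    else:
        inv = ncell / L
        head = np.full(ncell * ncell * ncell, -1, np.int64)
        nxt = np.empty(n_live, np.int64)
        cellx = np.empty(n_live, np.int64)
        celly = np.empty(n_live, np.int64)
        cellz = np.empty(n_live, np.int64)
        for i in range(n_live):
            cx = int((pos[i, 0] + 0.5 * L) * inv)
            cy = int((pos[i, 1] + 0.5 * L) * inv)
            cz = int((pos[i, 2] + 0.5 * L) * inv)
            if cx >= ncell:
                cx = ncell - 1
            if cy >= ncell:
                cy = ncell - 1
            if cz >= ncell:
                cz = ncell - 1
            cellx[i] = cx
            celly[i] = cy
            cellz[i] = cz
            c = (cx * ncell + cy) * ncell + cz
            nxt[i] = head[c]
            head[c] = i
        for i in range(n_live):
            for ox in range(-1, 2):
                ax = (cellx[i] + ox) % ncell
                for oy in range(-1, 2):
                    ay = (celly[i] + oy) % ncell
                    for oz in range(-1, 2):
                        az = (cellz[i] + oz) % ncell
                        j = head[(ax * ncell + ay) * ncell + az]
                        while j >= 0:
                            if j > i:
                                m = rlookup[sp[i], sp[j]]
                                if m >= 0:
                                    dx = _min_image(pos[j, 0] - pos[i, 0], L)
                                    dy = _min_image(pos[j, 1] - pos[i, 1], L)
                                    dz = _min_image(pos[j, 2] - pos[i, 2], L)
                                    d2 = dx * dx + dy * dy + dz * dz
                                    r = radius[m]
                                    if d2 <= r * r and k < cand_cap:
                                        ci[k] = i
                                        cj[k] = j
                                        cm[k] = m
                                        cd[k] = np.sqrt(d2)
                                        k += 1
                            j = nxt[j]
    if k == 0:
        return n_live
    # nearest-first greedy, random tie-break via tiny jitter on the key
    key = np.empty(k, np.float64)
    for q in range(k):
        key[q] = cd[q] + r_max * 1e-9 * np.random.random()
    corder = np.argsort(key)
    consumed = np.zeros(n_live, np.uint8)
    cap = pos.shape[0]
    n_new = n_live
    fired = False
    for qq in range(k):
        q = corder[qq]
        i = ci[q]
        j = cj[q]
        if consumed[i] == 1 or consumed[j] == 1:
            continue
        m = cm[q]
        if n_new + 3 > cap:
            break
        consumed[i] = 1
        consumed[j] = 1
        fired = True
        event_counts[m] += 1
        counts[sp[i]] -= 1
        counts[sp[j]] -= 1
        wi = sqrt_d[sp[i]]
        wj = sqrt_d[sp[j]]
        tot = wi + wj
        frac = wi / tot if tot > 0.0 else 0.5
        dx = _min_image(pos[j, 0] - pos[i, 0], L)
        dy = _min_image(pos[j, 1] - pos[i, 1], L)
        dz = _min_image(pos[j, 2] - pos[i, 2], L)
        mx = _wrap(pos[i, 0] + frac * dx, L)
        my = _wrap(pos[i, 1] + frac * dy, L)
        mz = _wrap(pos[i, 2] + frac * dz, L)
        n_prod = 0
        for p in range(3):
            if prods[m, p] >= 0:
                n_prod += 1
        for p in range(n_prod):
            px, py, pz = mx, my, mz
            if n_prod > 1:
                px = _wrap(mx + np.random.normal() * jitter, L)
                py = _wrap(my + np.random.normal() * jitter, L)
                pz = _wrap(mz + np.random.normal() * jitter, L)
            pos[n_new, 0] = px
            pos[n_new, 1] = py
            pos[n_new, 2] = pz
            sp[n_new] = prods[m, p]
            counts[prods[m, p]] += 1
            n_new += 1
    if not fired:
        return n_live
    # compact: drop consumed reactants, keep appended products
    w = 0
    for i in range(n_live):
        if consumed[i] == 0:
            if w != i:
                pos[w, 0] = pos[i, 0]
                pos[w, 1] = pos[i, 1]
                pos[w, 2] = pos[i, 2]
                sp[w] = sp[i]
            w += 1
    for i in range(n_live, n_new):
        pos[w, 0] = pos[i, 0]
        pos[w, 1] = pos[i, 1]
        pos[w, 2] = pos[i, 2]
        sp[w] = sp[i]
        w += 1
    return w


@njit(cache=True)
def sbs_core(pos, sp, n_live, t0, t_end, phase_until, phase_dt, L,
             diffusion, rlookup, radius, prods, counts, sample_t,
             inj_time, inj_ptr, inj_pos, inj_sp, seed, jitter,
             ):  # pragma: no cover - jitted
    """Full SBS time loop; fills and returns the sampled count series."""
    np.random.seed(seed)
    n_species = counts.shape[0]
    n_samp = sample_t.shape[0]
    out = np.zeros((n_samp, n_species), np.int64)
    event_counts = np.zeros(radius.shape[0], np.int64)
    sqrt_d = np.sqrt(diffusion)
    r_max = 0.0
    for m in range(radius.shape[0]):
        if radius[m] > r_max:
            r_max = radius[m]
    t = t0
    isamp = 0
    inj_i = 0
    n_inj = inj_time.shape[0]
    n_phase = phase_until.shape[0]
    while t < t_end - 1e-30:
        # merge any due injections, then sweep
        while inj_i < n_inj and inj_time[inj_i] <= t:
            a = inj_ptr[inj_i]
            b = inj_ptr[inj_i + 1]
            for q in range(a, b):
                pos[n_live, 0] = inj_pos[q, 0]
                pos[n_live, 1] = inj_pos[q, 1]
                pos[n_live, 2] = inj_pos[q, 2]
                sp[n_live] = inj_sp[q]
                counts[inj_sp[q]] += 1
                n_live += 1
            inj_i += 1
            n_live = _sweep(pos, sp, n_live, L, rlookup, radius, prods,
                            sqrt_d, counts, event_counts, jitter, r_max)
        dt = phase_dt[n_phase - 1]
        for ph in range(n_phase):
            if t < phase_until[ph]:
                dt = phase_dt[ph]
                break
        if t + dt > t_end:
            dt = t_end - t
        if inj_i < n_inj and t + dt > inj_time[inj_i] and inj_time[inj_i] > t:
            dt = inj_time[inj_i] - t
        # Gaussian jumps + wrap
        for i in range(n_live):
            sig = np.sqrt(2.0 * diffusion[sp[i]] * dt)
            if sig > 0.0:
                pos[i, 0] = _wrap(pos[i, 0] + np.random.normal() * sig, L)
                pos[i, 1] = _wrap(pos[i, 1] + np.random.normal() * sig, L)
                pos[i, 2] = _wrap(pos[i, 2] + np.random.normal() * sig, L)
        t += dt
        n_live = _sweep(pos, sp, n_live, L, rlookup, radius, prods,
                        sqrt_d, counts, event_counts, jitter, r_max)
        while isamp < n_samp and sample_t[isamp] <= t:
            for s in range(n_species):
                out[isamp, s] = counts[s]
            isamp += 1
    while isamp < n_samp:
        for s in range(n_species):
            out[isamp, s] = counts[s]
        isamp += 1
    return out, n_live, event_counts
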