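"""Numba kernels for the event-driven hard-sphere engine.

Implementation notes
--------------------
* Asynchronous particle updates: each particle carries the local time of
  its last update (``tloc``); positions are extrapolated ballistically on
  demand.
* Cell lists with linked-list membership; a particle's pending events are
  invalidated lazily through a per-particle event counter stamped into
  every heap entry.
* For boxes too small for a 3x3x3 cell neighbourhood (``nc < 3``) the
  kernel falls back to all-pairs predictions over the 27 periodic images,
  with per-particle "refresh" events bounding the prediction horizon.
* Diameter growth (compression) is multiplicative and global:
  ``d_i(t) = dbase_i * (1 + g * (t - t_start))`` until ``t_growth_end``,
  which preserves species diameter ratios exactly.  Collisions during
  growth add the contact-growth speed to the exchanged impulse so pairs
  always separate faster than their contact grows.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = np.inf

# driver status codes
OK = 0
JAMMED = 1
TIME_REVERSED = 2
HEAP_OVERFLOW = 3
REC_OVERFLOW = 4


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _min_image(d, L):
    if d > 0.5 * L:
        return d - L
    elif d < -0.5 * L:
        return d + L
    return d


@njit(cache=True, inline="always")
def _wrap(x, L):
    if x >= L:
        x -= L
        if x >= L:
            x = x % L
    elif x < 0.0:
        x += L
        if x < 0.0:
            x = x % L
    return x


@njit(cache=True, inline="always")
def _quad_contact_time(rx, ry, rz, vx, vy, vz, rn, rdot):
    """Earliest tau > 0 with |dr + dv*tau| = rn + rdot*tau, or inf.

    ``rn`` is the contact distance now, ``rdot`` its growth rate.
    The gap function is f(tau) = a*tau^2 + 2*b*tau + c with f(0) = c >= 0.
    """
    a = vx * vx + vy * vy + vz * vz - rdot * rdot
    b = rx * vx + ry * vy + rz * vz - rn * rdot
    c = rx * rx + ry * ry + rz * rz - rn * rn
    if c < 0.0:
        c = 0.0  # at-contact round-off
    if a == 0.0:
        if b < 0.0:
            return -c / (2.0 * b)
        return INF
    disc = b * b - a * c
    if a > 0.0:
        if b >= 0.0 or disc < 0.0:
            return INF
        return c / (-b + np.sqrt(disc))
    # a < 0: growth outruns relative motion; a positive root always exists
    sq = np.sqrt(disc)
    t1 = (-b - sq) / a
    t2 = (-b + sq) / a
    tmin = INF
    if t1 > 0.0 and t1 < tmin:
        tmin = t1
    if t2 > 0.0 and t2 < tmin:
        tmin = t2
    return tmin


@njit(cache=True)
def pair_collision_time(r1, v1, d1, r2, v2, d2, box_edge):
    """Earliest contact time for one pair over the 27 periodic images (inf if none)."""
    rn = 0.5 * (d1 + d2)
    best = INF
    for ox in range(-1, 2):
        for oy in range(-1, 2):
            for oz in range(-1, 2):
                rx = r2[0] - r1[0] + ox * box_edge
                ry = r2[1] - r1[1] + oy * box_edge
                rz = r2[2] - r1[2] + oz * box_edge
                tau = _quad_contact_time(
                    rx, ry, rz,
                    v2[0] - v1[0], v2[1] - v1[1], v2[2] - v1[2],
                    rn, 0.0,
                )
                if tau < best:
                    best = tau
    return best


# ---------------------------------------------------------------------------
# binary heap over parallel arrays (time, i, j, stamp_i, stamp_j)
# j >= 0  : pair collision
# j == -1 : cell crossing / refresh; stamp_j stores axis*2 + direction code
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _hswap(ht, hi, hj, hci, hcj, a, b):
    ht[a], ht[b] = ht[b], ht[a]
    hi[a], hi[b] = hi[b], hi[a]
    hj[a], hj[b] = hj[b], hj[a]
    hci[a], hci[b] = hci[b], hci[a]
    hcj[a], hcj[b] = hcj[b], hcj[a]


@njit(cache=True)
def _hpush(ht, hi, hj, hci, hcj, hn, t, i, j, ci, cj):
    k = hn
    ht[k] = t
    hi[k] = i
    hj[k] = j
    hci[k] = ci
    hcj[k] = cj
    while k > 0:
        p = (k - 1) >> 1
        if ht[p] <= ht[k]:
            break
        _hswap(ht, hi, hj, hci, hcj, p, k)
        k = p
    return hn + 1


@njit(cache=True)
def _hpop(ht, hi, hj, hci, hcj, hn):
    last = hn - 1
    _hswap(ht, hi, hj, hci, hcj, 0, last)
    k = 0
    while True:
        l = 2 * k + 1
        if l >= last:
            break
        r = l + 1
        c = l
        if r < last and ht[r] < ht[l]:
            c = r
        if ht[k] <= ht[c]:
            break
        _hswap(ht, hi, hj, hci, hcj, k, c)
        k = c
    return last


@njit(cache=True)
def _hgc(ht, hi, hj, hci, hcj, hn, cnt):
    """Drop stale entries and re-heapify; returns new size."""
    m = 0
    for k in range(hn):
        i = hi[k]
        j = hj[k]
        ok = hci[k] == cnt[i]
        if ok and j >= 0 and hcj[k] != cnt[j]:
            ok = False
        if ok:
            ht[m] = ht[k]
            hi[m] = i
            hj[m] = j
            hci[m] = hci[k]
            hcj[m] = hcj[k]
            m += 1
    # sift-down heapify
    for s in range(m // 2 - 1, -1, -1):
        k = s
        while True:
            l = 2 * k + 1
            if l >= m:
                break
            c = l
            r = l + 1
            if r < m and ht[r] < ht[l]:
                c = r
            if ht[k] <= ht[c]:
                break
            _hswap(ht, hi, hj, hci, hcj, k, c)
            k = c
    return m


# ---------------------------------------------------------------------------
# cell list helpers
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _cell_id(ix, iy, iz, nc):
    return (ix * nc + iy) * nc + iz


@njit(cache=True)
def _cell_link(i, cid, chead, cnext, cprev):
    h = chead[cid]
    cnext[i] = h
    cprev[i] = -1 - cid  # encode cell id for head entries
    if h >= 0:
        cprev[h] = i
    chead[cid] = i


@njit(cache=True)
def _cell_unlink(i, chead, cnext, cprev):
    p = cprev[i]
    nx = cnext[i]
    if p >= 0:
        cnext[p] = nx
    else:
        chead[-1 - p] = nx
    if nx >= 0:
        cprev[nx] = p


# ---------------------------------------------------------------------------
# event scheduling
# ---------------------------------------------------------------------------

@njit(cache=True)
def _crossing_event(i, t, pos, vel, tloc, L, nc, cs, cidx, cellmode):
    """(absolute time, axis*2+dir code) of particle i's next cell exit/refresh."""
    if not cellmode:
        vx = vel[i, 0]
        vy = vel[i, 1]
        vz = vel[i, 2]
        sp = np.sqrt(vx * vx + vy * vy + vz * vz)
        if sp == 0.0:
            return INF, 0
        return tloc[i] + 0.25 * L / sp, 0
    best = INF
    code = 0
    for ax in range(3):
        v = vel[i, ax]
        x = pos[i, ax]
        if v > 0.0:
            thit = ((cidx[i, ax] + 1) * cs - x) / v
            d = 1
        elif v < 0.0:
            thit = (cidx[i, ax] * cs - x) / v
            d = 0
        else:
            continue
        if thit < 0.0:
            thit = 0.0
        ta = tloc[i] + thit
        if ta < best:
            best = ta
            code = ax * 2 + d
    return best, code


@njit(cache=True)
def _schedule(i, t, pos, vel, tloc, dbase, L, nc, cs, cidx,
              chead, cnext, cnt, cellmode, growth, t_start,
              ht, hi, hj, hci, hcj, hn):
    """Push particle i's next crossing and candidate pair collisions.

    Pair events beyond i's next crossing are skipped: they are re-found
    when the crossing is processed.
    Returns the new heap size.
    """
    tcross, code = _crossing_event(i, t, pos, vel, tloc, L, nc, cs, cidx, cellmode)
    if tcross < INF:
        hn = _hpush(ht, hi, hj, hci, hcj, hn, tcross, i, -1, cnt[i], code)
    horizon = tcross + 1e-12

    scale = 1.0 + growth * (t - t_start)
    xi = pos[i, 0] + vel[i, 0] * (t - tloc[i])
    yi = pos[i, 1] + vel[i, 1] * (t - tloc[i])
    zi = pos[i, 2] + vel[i, 2] * (t - tloc[i])

    if cellmode:
        cx = cidx[i, 0]
        cy = cidx[i, 1]
        cz = cidx[i, 2]
        for ox in range(-1, 2):
            jx = (cx + ox) % nc
            for oy in range(-1, 2):
                jy = (cy + oy) % nc
                for oz in range(-1, 2):
                    jz = (cz + oz) % nc
                    j = chead[_cell_id(jx, jy, jz, nc)]
                    while j >= 0:
                        if j != i:
                            dt_j = t - tloc[j]
                            rx = _min_image(pos[j, 0] + vel[j, 0] * dt_j - xi, L)
                            ry = _min_image(pos[j, 1] + vel[j, 1] * dt_j - yi, L)
                            rz = _min_image(pos[j, 2] + vel[j, 2] * dt_j - zi, L)
                            rn = 0.5 * (dbase[i] + dbase[j]) * scale
                            rdot = 0.5 * (dbase[i] + dbase[j]) * growth
                            tau = _quad_contact_time(
                                rx, ry, rz,
                                vel[j, 0] - vel[i, 0],
                                vel[j, 1] - vel[i, 1],
                                vel[j, 2] - vel[i, 2],
                                rn, rdot,
                            )
                            tc = t + tau
                            if tc <= horizon:
                                hn = _hpush(ht, hi, hj, hci, hcj, hn,
                                            tc, i, j, cnt[i], cnt[j])
                        j = cnext[j]
    else:
        n = pos.shape[0]
        for j in range(n):
            if j == i:
                continue
            dt_j = t - tloc[j]
            rn = 0.5 * (dbase[i] + dbase[j]) * scale
            rdot = 0.5 * (dbase[i] + dbase[j]) * growth
            best = INF
            for ox in range(-1, 2):
                for oy in range(-1, 2):
                    for oz in range(-1, 2):
                        rx = pos[j, 0] + vel[j, 0] * dt_j - xi + ox * L
                        ry = pos[j, 1] + vel[j, 1] * dt_j - yi + oy * L
                        rz = pos[j, 2] + vel[j, 2] * dt_j - zi + oz * L
                        tau = _quad_contact_time(
                            rx, ry, rz,
                            vel[j, 0] - vel[i, 0],
                            vel[j, 1] - vel[i, 1],
                            vel[j, 2] - vel[i, 2],
                            rn, rdot,
                        )
                        if tau < best:
                            best = tau
            tc = t + best
            if tc <= horizon:
                hn = _hpush(ht, hi, hj, hci, hcj, hn, tc, i, j, cnt[i], cnt[j])
    return hn


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

@njit(cache=True)
def evolve(pos, vel, tloc, dbase, mass, L,
           t_start, growth, t_growth_end,
           restitution, nu, temperature,
           max_collisions, t_max,
           sample_times, frames_pos, frames_vel, frames_scale,
           rec_t, rec_i, rec_j, rec_cap,
           seed):
    """Advance the system; mutates pos/vel/tloc/dbase in place.

    Returns (t_final, n_collisions, virial_sum, n_sampled, n_recorded, status).
    ``virial_sum`` accumulates impulse * contact-distance over all pair
    collisions (for the collisional pressure).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    t = t_start

    # --- cells ---------------------------------------------------------
    if growth > 0.0 and t_growth_end < INF:
        final_scale = 1.0 + growth * (t_growth_end - t_start)
    else:
        final_scale = 1.0
    dmax = dbase.max() * final_scale
    nc = int(L / (dmax * (1.0 + 1e-9)))
    cellmode = nc >= 3
    if not cellmode:
        nc = 1
    cs = L / nc

    cidx = np.empty((n, 3), dtype=np.int64)
    chead = np.full(nc * nc * nc, -1, dtype=np.int64)
    cnext = np.empty(n, dtype=np.int64)
    cprev = np.empty(n, dtype=np.int64)
    for i in range(n):
        for ax in range(3):
            c = int(pos[i, ax] / cs)
            if c >= nc:
                c = nc - 1
            elif c < 0:
                c = 0
            cidx[i, ax] = c
        _cell_link(i, _cell_id(cidx[i, 0], cidx[i, 1], cidx[i, 2], nc),
                   chead, cnext, cprev)

    # --- heap ----------------------------------------------------------
    cap = 96 * n + 4096
    if not cellmode:
        cap += 4 * n * n  # all-pairs fallback can push O(n) entries per schedule
    ht = np.empty(cap, dtype=np.float64)
    hi = np.empty(cap, dtype=np.int64)
    hj = np.empty(cap, dtype=np.int64)
    hci = np.empty(cap, dtype=np.int64)
    hcj = np.empty(cap, dtype=np.int64)
    hn = 0
    cnt = np.zeros(n, dtype=np.int64)

    for i in range(n):
        hn = _schedule(i, t, pos, vel, tloc, dbase, L, nc, cs, cidx,
                       chead, cnext, cnt, cellmode, growth, t_start,
                       ht, hi, hj, hci, hcj, hn)

    if nu > 0.0:
        next_thermo = t + np.random.exponential(1.0 / (nu * n))
    else:
        next_thermo = INF

    n_samples = sample_times.shape[0]
    s_idx = 0
    ncoll = 0
    nrec = 0
    virial = 0.0
    status = OK
    grow_pending = growth > 0.0
    stall = 0  # consecutive near-zero-dt collisions (jam heuristic)
    t_prev_coll = t

    while True:
        t_heap = ht[0] if hn > 0 else INF
        tnext = t_heap
        kind = 0  # heap
        if next_thermo < tnext:
            tnext = next_thermo
            kind = 1
        if grow_pending and t_growth_end < tnext:
            tnext = t_growth_end
            kind = 2
        if s_idx < n_samples and sample_times[s_idx] <= tnext:
            tnext = sample_times[s_idx]
            kind = 3
        if t_max < tnext:
            kind = 4

        if kind == 4:
            t = t_max
            break
        if tnext < t - 1e-9:
            status = TIME_REVERSED
            break

        if kind == 3:  # sample frame
            ts = tnext
            for i in range(n):
                dt_i = ts - tloc[i]
                for ax in range(3):
                    frames_pos[s_idx, i, ax] = _wrap(pos[i, ax] + vel[i, ax] * dt_i, L)
                    frames_vel[s_idx, i, ax] = vel[i, ax]
            if grow_pending:
                frames_scale[s_idx] = 1.0 + growth * (ts - t_start)
            else:
                frames_scale[s_idx] = 1.0
            s_idx += 1
            t = ts
            if s_idx == n_samples and t_max == INF and max_collisions <= 0:
                break
            continue

        if kind == 1:  # thermostat ghost collision
            t = next_thermo
            i = int(np.random.random() * n)
            if i == n:
                i = n - 1
            dt_i = t - tloc[i]
            for ax in range(3):
                pos[i, ax] = pos[i, ax] + vel[i, ax] * dt_i
            tloc[i] = t
            sd = np.sqrt(temperature / mass[i])
            vel[i, 0] = sd * np.random.normal()
            vel[i, 1] = sd * np.random.normal()
            vel[i, 2] = sd * np.random.normal()
            cnt[i] += 1
            if hn > cap - 2 * n - 64:
                hn = _hgc(ht, hi, hj, hci, hcj, hn, cnt)
                if hn > cap - 2 * n - 64:
                    status = HEAP_OVERFLOW
                    break
            hn = _schedule(i, t, pos, vel, tloc, dbase, L, nc, cs, cidx,
                           chead, cnext, cnt, cellmode, growth, t_start,
                           ht, hi, hj, hci, hcj, hn)
            next_thermo = t + np.random.exponential(1.0 / (nu * n))
            continue

        if kind == 2:  # end of diameter growth: freeze and rebuild queue
            t = t_growth_end
            scale = 1.0 + growth * (t - t_start)
            for i in range(n):
                dbase[i] = dbase[i] * scale
            growth = 0.0
            grow_pending = False
            t_start = t  # scale reference is now identity
            for i in range(n):
                cnt[i] += 1
            hn = 0
            for i in range(n):
                hn = _schedule(i, t, pos, vel, tloc, dbase, L, nc, cs, cidx,
                               chead, cnext, cnt, cellmode, growth, t_start,
                               ht, hi, hj, hci, hcj, hn)
            continue

        # heap event
        tev = ht[0]
        i = hi[0]
        j = hj[0]
        ci = hci[0]
        cj = hcj[0]
        hn = _hpop(ht, hi, hj, hci, hcj, hn)
        if ci != cnt[i]:
            continue
        if j >= 0 and cj != cnt[j]:
            continue
        t = tev

        if hn > cap - 4 * n - 128:
            hn = _hgc(ht, hi, hj, hci, hcj, hn, cnt)
            if hn > cap - 4 * n - 128:
                status = HEAP_OVERFLOW
                break

        if j == -1:  # cell crossing / refresh
            dt_i = t - tloc[i]
            for ax in range(3):
                pos[i, ax] = pos[i, ax] + vel[i, ax] * dt_i
            tloc[i] = t
            if cellmode:
                ax = cj >> 1
                d = cj & 1
                old = _cell_id(cidx[i, 0], cidx[i, 1], cidx[i, 2], nc)
                if d == 1:
                    cidx[i, ax] += 1
                    if cidx[i, ax] == nc:
                        cidx[i, ax] = 0
                        pos[i, ax] -= L
                else:
                    cidx[i, ax] -= 1
                    if cidx[i, ax] < 0:
                        cidx[i, ax] = nc - 1
                        pos[i, ax] += L
                new = _cell_id(cidx[i, 0], cidx[i, 1], cidx[i, 2], nc)
                if new != old:
                    _cell_unlink(i, chead, cnext, cprev)
                    _cell_link(i, new, chead, cnext, cprev)
            else:
                for ax in range(3):
                    pos[i, ax] = _wrap(pos[i, ax], L)
            cnt[i] += 1
            hn = _schedule(i, t, pos, vel, tloc, dbase, L, nc, cs, cidx,
                           chead, cnext, cnt, cellmode, growth, t_start,
                           ht, hi, hj, hci, hcj, hn)
            continue

        # pair collision
        dt_i = t - tloc[i]
        dt_j = t - tloc[j]
        for ax in range(3):
            pos[i, ax] = pos[i, ax] + vel[i, ax] * dt_i
            pos[j, ax] = pos[j, ax] + vel[j, ax] * dt_j
        tloc[i] = t
        tloc[j] = t

        scale = 1.0 + growth * (t - t_start)
        rn = 0.5 * (dbase[i] + dbase[j]) * scale
        rdot = 0.5 * (dbase[i] + dbase[j]) * growth

        if cellmode:
            rx = _min_image(pos[j, 0] - pos[i, 0], L)
            ry = _min_image(pos[j, 1] - pos[i, 1], L)
            rz = _min_image(pos[j, 2] - pos[i, 2], L)
        else:
            # pick the periodic image realizing the contact
            bestd = INF
            rx = 0.0
            ry = 0.0
            rz = 0.0
            for ox in range(-1, 2):
                for oy in range(-1, 2):
                    for oz in range(-1, 2):
                        qx = pos[j, 0] - pos[i, 0] + ox * L
                        qy = pos[j, 1] - pos[i, 1] + oy * L
                        qz = pos[j, 2] - pos[i, 2] + oz * L
                        dd = abs(np.sqrt(qx * qx + qy * qy + qz * qz) - rn)
                        if dd < bestd:
                            bestd = dd
                            rx = qx
                            ry = qy
                            rz = qz
        dist = np.sqrt(rx * rx + ry * ry + rz * rz)
        if dist == 0.0:
            status = TIME_REVERSED
            break
        nx = rx / dist
        ny = ry / dist
        nz = rz / dist
        w = ((vel[j, 0] - vel[i, 0]) * nx
             + (vel[j, 1] - vel[i, 1]) * ny
             + (vel[j, 2] - vel[i, 2]) * nz)
        mi = mass[i]
        mj = mass[j]
        mu = mi * mj / (mi + mj)
        p = mu * (1.0 + restitution) * (w - rdot)
        if p < 0.0:  # genuinely approaching (relative to growing contact)
            vel[i, 0] += p / mi * nx
            vel[i, 1] += p / mi * ny
            vel[i, 2] += p / mi * nz
            vel[j, 0] -= p / mj * nx
            vel[j, 1] -= p / mj * ny
            vel[j, 2] -= p / mj * nz
            virial += (-p) * dist
            if nrec < rec_cap:
                rec_t[nrec] = t
                a = i
                b = j
                if a > b:
                    a, b = b, a
                rec_i[nrec] = a
                rec_j[nrec] = b
                nrec += 1
            ncoll += 1
            if t - t_prev_coll < 1e-12:
                stall += 1
                if stall > 50 * n:
                    status = JAMMED
                    break
            else:
                stall = 0
            t_prev_coll = t
        cnt[i] += 1
        cnt[j] += 1
        hn = _schedule(i, t, pos, vel, tloc, dbase, L, nc, cs, cidx,
                       chead, cnext, cnt, cellmode, growth, t_start,
                       ht, hi, hj, hci, hcj, hn)
        hn = _schedule(j, t, pos, vel, tloc, dbase, L, nc, cs, cidx,
                       chead, cnext, cnt, cellmode, growth, t_start,
                       ht, hi, hj, hci, hcj, hn)
        if max_collisions > 0 and ncoll >= max_collisions:
            break

    # synchronize every particle to the final time
    for i in range(n):
        dt_i = t - tloc[i]
        for ax in range(3):
            pos[i, ax] = _wrap(pos[i, ax] + vel[i, ax] * dt_i, L)
        tloc[i] = t
    if growth > 0.0:
        fs = 1.0 + growth * (t - t_start)
        for i in range(n):
            dbase[i] = dbase[i] * fs

    return t, ncoll, virial, s_idx, nrec, status


# ---------------------------------------------------------------------------
# random sequential insertion for initial configurations
# ---------------------------------------------------------------------------

@njit(cache=True)
def rsi_place(diams, L, seed, max_attempts):
    """Place non-overlapping spheres uniformly at random (largest placed first
    by the caller's ordering).  Returns (positions, number placed)."""
    np.random.seed(seed)
    n = diams.shape[0]
    pos = np.empty((n, 3), dtype=np.float64)
    dmax = diams.max()
    nc = int(L / dmax)
    if nc < 3:
        nc = 1
    cs = L / nc
    chead = np.full(nc * nc * nc, -1, dtype=np.int64)
    cnext = np.full(n, -1, dtype=np.int64)
    cidx = np.empty((n, 3), dtype=np.int64)

    for i in range(n):
        placed = False
        for _ in range(max_attempts):
            x = np.random.random() * L
            y = np.random.random() * L
            z = np.random.random() * L
            cx = min(int(x / cs), nc - 1)
            cy = min(int(y / cs), nc - 1)
            cz = min(int(z / cs), nc - 1)
            ok = True
            if nc >= 3:
                for ox in range(-1, 2):
                    jx = (cx + ox) % nc
                    for oy in range(-1, 2):
                        jy = (cy + oy) % nc
                        for oz in range(-1, 2):
                            jz = (cz + oz) % nc
                            j = chead[_cell_id(jx, jy, jz, nc)]
                            while j >= 0:
                                rx = _min_image(pos[j, 0] - x, L)
                                ry = _min_image(pos[j, 1] - y, L)
                                rz = _min_image(pos[j, 2] - z, L)
                                rc = 0.5 * (diams[i] + diams[j])
                                if rx * rx + ry * ry + rz * rz < rc * rc:
                                    ok = False
                                    break
                                j = cnext[j]
                            if not ok:
                                break
                        if not ok:
                            break
                    if not ok:
                        break
            else:
                for j in range(i):
                    rx = _min_image(pos[j, 0] - x, L)
                    ry = _min_image(pos[j, 1] - y, L)
                    rz = _min_image(pos[j, 2] - z, L)
                    rc = 0.5 * (diams[i] + diams[j])
                    if rx * rx + ry * ry + rz * rz < rc * rc:
                        ok = False
                        break
            if ok:
                pos[i, 0] = x
                pos[i, 1] = y
                pos[i, 2] = z
                cidx[i, 0] = cx
                cidx[i, 1] = cy
                cidx[i, 2] = cz
                cid = _cell_id(cx, cy, cz, nc)
                cnext[i] = chead[cid]
                chead[cid] = i
                placed = True
                break
        if not placed:
            return pos, i
    return pos, n


@njit(cache=True)
def max_overlap(pos, diams, L):
    """Largest pair overlap depth (positive = overlapping) over all pairs."""
    n = pos.shape[0]
    worst = -INF
    for i in range(n):
        for j in range(i + 1, n):
            rx = _min_image(pos[j, 0] - pos[i, 0], L)
            ry = _min_image(pos[j, 1] - pos[i, 1], L)
            rz = _min_image(pos[j, 2] - pos[i, 2], L)
            d = np.sqrt(rx * rx + ry * ry + rz * rz)
            ov = 0.5 * (diams[i] + diams[j]) - d
            if ov > worst:
                worst = ov
    return worst
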