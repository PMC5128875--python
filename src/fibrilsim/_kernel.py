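"""Compiled core of the event-driven dynamics.

Implements exact hard-sphere / square-well kinematics under periodic minimum
image: pair event prediction (smallest positive root of |Δr + Δv t| = R),
impulsive event resolution with exact momentum/energy bookkeeping, an
Andersen-style ghost-kick thermostat, a binary-heap event calendar with lazy
invalidation through per-bead event counters, and a Verlet neighbour list
with a conservative rebuild horizon (v_max · elapsed < skin/2).

Each interacting pair carries an explicit *shell* index (which region
between discontinuity radii it occupies).  Predictions consider only the
two boundaries of the current shell and executions update the shell, so a
pair sitting numerically on a boundary — the state every executed event
leaves behind — is never misclassified, and near-simultaneous events cannot
tunnel a pair through a wall.

All beads have unit mass; velocities are in Å per reduced time unit and
energies in ε_HB.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# event bookkeeping slots
EV_CORE, EV_WELL_IN, EV_WELL_OUT, EV_BOND_WALL, EV_HB_FORM, EV_HB_BREAK, \
    EV_PASS, EV_GHOST, EV_BOUNCE = range(9)
N_EV_KINDS = 9

_BIG = 1.0e300


@njit(cache=True, inline="always", fastmath=True)
def _minimg(d, L):
    return d - L * np.floor(d / L + 0.5)


@njit(cache=True)
def _heap_push(ht, hi, hj, hr, hci, hcj, size, t, i, j, r, ci, cj):
    k = size
    ht[k] = t
    hi[k] = i
    hj[k] = j
    hr[k] = r
    hci[k] = ci
    hcj[k] = cj
    while k > 0:
        p = (k - 1) // 2
        if ht[p] <= ht[k]:
            break
        ht[p], ht[k] = ht[k], ht[p]
        hi[p], hi[k] = hi[k], hi[p]
        hj[p], hj[k] = hj[k], hj[p]
        hr[p], hr[k] = hr[k], hr[p]
        hci[p], hci[k] = hci[k], hci[p]
        hcj[p], hcj[k] = hcj[k], hcj[p]
        k = p
    return size + 1


@njit(cache=True)
def _heap_pop(ht, hi, hj, hr, hci, hcj, size):
    last = size - 1
    ht[0], ht[last] = ht[last], ht[0]
    hi[0], hi[last] = hi[last], hi[0]
    hj[0], hj[last] = hj[last], hj[0]
    hr[0], hr[last] = hr[last], hr[0]
    hci[0], hci[last] = hci[last], hci[0]
    hcj[0], hcj[last] = hcj[last], hcj[0]
    k = 0
    while True:
        l = 2 * k + 1
        if l >= last:
            break
        c = l
        if l + 1 < last and ht[l + 1] < ht[l]:
            c = l + 1
        if ht[k] <= ht[c]:
            break
        ht[k], ht[c] = ht[c], ht[k]
        hi[k], hi[c] = hi[c], hi[k]
        hj[k], hj[c] = hj[c], hj[k]
        hr[k], hr[c] = hr[c], hr[k]
        hci[k], hci[c] = hci[c], hci[k]
        hcj[k], hcj[c] = hcj[c], hcj[k]
        k = c
    return last


@njit(cache=True, fastmath=True)
def _predict_pair(pos, vel, tb, L, t_now, i, j,
                  tt, type_nd, type_r2, shell):
    """Earliest boundary crossing for pair (i, j) after t_now.

    Only the inner and outer boundary of the pair's current shell are
    candidates.  Tiny negative roots (round-off past a boundary) are
    clamped to "now".  Returns (t_abs, boundary_index) or (_BIG, -1).
    """
    nd = type_nd[tt]
    if nd == 0:
        return _BIG, -1
    dx = (pos[i, 0] + vel[i, 0] * (t_now - tb[i])) - \
         (pos[j, 0] + vel[j, 0] * (t_now - tb[j]))
    dy = (pos[i, 1] + vel[i, 1] * (t_now - tb[i])) - \
         (pos[j, 1] + vel[j, 1] * (t_now - tb[j]))
    dz = (pos[i, 2] + vel[i, 2] * (t_now - tb[i])) - \
         (pos[j, 2] + vel[j, 2] * (t_now - tb[j]))
    dx = _minimg(dx, L)
    dy = _minimg(dy, L)
    dz = _minimg(dz, L)
    dvx = vel[i, 0] - vel[j, 0]
    dvy = vel[i, 1] - vel[j, 1]
    dvz = vel[i, 2] - vel[j, 2]
    r2 = dx * dx + dy * dy + dz * dz
    b = dx * dvx + dy * dvy + dz * dvz
    v2 = dvx * dvx + dvy * dvy + dvz * dvz
    if v2 <= 0.0:
        return _BIG, -1
    s = shell
    best_t = _BIG
    best_m = -1
    # inner boundary: reachable only while approaching
    if s > 0 and b < 0.0:
        R2 = type_r2[tt, s - 1]
        disc = b * b - v2 * (r2 - R2)
        if disc > 0.0:
            tc = (-b - np.sqrt(disc)) / v2
            if tc >= -1.0e-9:
                if tc < 0.0:
                    tc = 0.0
                best_t = tc
                best_m = s - 1
    # outer boundary: always crossed eventually
    if s < nd:
        R2 = type_r2[tt, s]
        disc = b * b - v2 * (r2 - R2)
        if disc > 0.0:
            tc = (-b + np.sqrt(disc)) / v2
        else:
            tc = -1.0        # perigee above the outer radius cannot happen
        if tc < 0.0 and r2 > R2:
            tc = 0.0         # round-off past the boundary: resolve now
        if 0.0 <= tc < best_t:
            best_t = tc
            best_m = s
    if best_m < 0:
        return _BIG, -1
    return t_now + best_t, best_m


@njit(cache=True, fastmath=True)
def _schedule_bead(bead, t_now,
                   pos, vel, tb, L,
                   ptype, type_nd, type_r2, shell_mat,
                   nb_indptr, nb_list, ctr,
                   ht, hi, hj, hr, hci, hcj, heap_size):
    best_t = _BIG
    best_j = -1
    best_m = -1
    for k in range(nb_indptr[bead], nb_indptr[bead + 1]):
        other = nb_list[k]
        tt = ptype[bead, other]
        t_ev, m = _predict_pair(pos, vel, tb, L, t_now, bead, other,
                                tt, type_nd, type_r2,
                                shell_mat[bead, other])
        if t_ev < best_t:
            best_t = t_ev
            best_j = other
            best_m = m
    if best_j >= 0 and best_t < _BIG:
        a, b = bead, best_j
        if a > b:
            a, b = b, a
        heap_size = _heap_push(ht, hi, hj, hr, hci, hcj, heap_size,
                               best_t, a, b, best_m, ctr[a], ctr[b])
    return heap_size


@njit(cache=True, fastmath=True)
def _build_neighbors(pos, L, ptype, type_maxr, skin,
                     nb_indptr, nb_list):
    n = pos.shape[0]
    total = 0
    for i in range(n):
        nb_indptr[i] = total
        for j in range(n):
            if j == i:
                continue
            tt = ptype[i, j]
            if tt == 0:
                continue
            cut = type_maxr[tt] + skin
            dx = _minimg(pos[i, 0] - pos[j, 0], L)
            dy = _minimg(pos[i, 1] - pos[j, 1], L)
            dz = _minimg(pos[i, 2] - pos[j, 2], L)
            if dx * dx + dy * dy + dz * dz < cut * cut:
                nb_list[total] = j
                total += 1
    nb_indptr[n] = total
    return total


@njit(cache=True)
def _hb_gate(i_nh, j_co, pos, vel, tb, t_now, L,
             ca_self, ca_prev, ca_next,
             aux_min, aux_max, cos_thresh, parallel_on):
    """Formation gate: auxiliary CA distances and strand alignment."""
    for trial in range(2):
        if trial == 0:
            a = i_nh
            c = ca_self[j_co]
        else:
            a = j_co
            c = ca_self[i_nh]
        dx = (pos[a, 0] + vel[a, 0] * (t_now - tb[a])) - \
             (pos[c, 0] + vel[c, 0] * (t_now - tb[c]))
        dy = (pos[a, 1] + vel[a, 1] * (t_now - tb[a])) - \
             (pos[c, 1] + vel[c, 1] * (t_now - tb[c]))
        dz = (pos[a, 2] + vel[a, 2] * (t_now - tb[a])) - \
             (pos[c, 2] + vel[c, 2] * (t_now - tb[c]))
        dx = _minimg(dx, L)
        dy = _minimg(dy, L)
        dz = _minimg(dz, L)
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < aux_min or d > aux_max:
            return False
    if not parallel_on:
        return True
    sx = sy = sz = 0.0
    ox = oy = oz = 0.0
    for trial in range(2):
        bead = i_nh if trial == 0 else j_co
        p = ca_prev[bead]
        q = ca_next[bead]
        if p == q:
            return True  # chain too short for a direction; no gate
        vx = (pos[q, 0] + vel[q, 0] * (t_now - tb[q])) - \
             (pos[p, 0] + vel[p, 0] * (t_now - tb[p]))
        vy = (pos[q, 1] + vel[q, 1] * (t_now - tb[q])) - \
             (pos[p, 1] + vel[p, 1] * (t_now - tb[p]))
        vz = (pos[q, 2] + vel[q, 2] * (t_now - tb[q])) - \
             (pos[p, 2] + vel[p, 2] * (t_now - tb[p]))
        vx = _minimg(vx, L)
        vy = _minimg(vy, L)
        vz = _minimg(vz, L)
        if trial == 0:
            sx, sy, sz = vx, vy, vz
        else:
            ox, oy, oz = vx, vy, vz
    dot = sx * ox + sy * oy + sz * oz
    na = np.sqrt(sx * sx + sy * sy + sz * sz)
    nb = np.sqrt(ox * ox + oy * oy + oz * oz)
    if na == 0.0 or nb == 0.0:
        return True
    return dot >= cos_thresh * na * nb


@njit(cache=True)
def run_kernel(pos, vel, tb, hb_partner, ctr, shell_mat,
               ptype, type_nd, type_r2, type_level, type_is_hb, type_maxr,
               kind, chain_of, ca_self, ca_prev, ca_next, L, skin,
               aux_min, aux_max, cos_thresh, parallel_on, eps_hb,
               ghost_rate, seg_end, seg_T,
               n_target, snap_every,
               snap_pos, snap_t, snap_pe, snap_ke, snap_ncoll, snap_nhb,
               snap_nhb_inter, t0, t_end, pe0, seed):
    """Advance the system by ``n_target`` pair events (or until ``t_end``).

    Returns (t, ncoll, pe, ke, n_snap, event_counts)."""
    np.random.seed(seed)
    n = pos.shape[0]
    counts = np.zeros(N_EV_KINDS, dtype=np.int64)

    ke = 0.0
    for b in range(n):
        ke += 0.5 * (vel[b, 0] ** 2 + vel[b, 1] ** 2 + vel[b, 2] ** 2)
    pe = pe0
    nhb = 0
    for b in range(n):
        if hb_partner[b] >= 0:
            nhb += 1
    nhb //= 2

    cap = 64 * n + 4096
    ht = np.empty(cap)
    hi = np.empty(cap, dtype=np.int32)
    hj = np.empty(cap, dtype=np.int32)
    hr = np.empty(cap, dtype=np.int8)
    hci = np.empty(cap, dtype=np.int64)
    hcj = np.empty(cap, dtype=np.int64)
    heap_size = 0

    nb_indptr = np.zeros(n + 1, dtype=np.int64)
    nb_list = np.empty(n * n, dtype=np.int32)

    t = t0
    half_skin = 0.5 * skin

    for b in range(n):
        for d in range(3):
            pos[b, d] -= L * np.floor(pos[b, d] / L)
    _build_neighbors(pos, L, ptype, type_maxr, skin, nb_indptr, nb_list)
    t_built = t
    v_max = 1.0e-12
    for b in range(n):
        s = np.sqrt(vel[b, 0] ** 2 + vel[b, 1] ** 2 + vel[b, 2] ** 2)
        if s > v_max:
            v_max = s
    for b in range(n):
        heap_size = _schedule_bead(b, t, pos, vel, tb, L, ptype, type_nd,
                                   type_r2, shell_mat, nb_indptr, nb_list,
                                   ctr, ht, hi, hj, hr, hci, hcj, heap_size)

    seg_ptr = 0
    n_seg = seg_end.shape[0]
    temp = seg_T[0] if n_seg > 0 else 0.0
    if ghost_rate > 0.0 and temp > 0.0:
        t_ghost = t + np.random.exponential(1.0 / (ghost_rate * n))
    else:
        t_ghost = _BIG

    ncoll = 0
    n_snap = 0
    next_snap = snap_every if snap_every > 0 else np.int64(2 ** 62)
    zero_dt_run = 0
    t_prev_event = t - 1.0

    while ncoll < n_target:
        if heap_size == 0:
            te_pair = _BIG
        else:
            te_pair = ht[0]
        te = te_pair if te_pair < t_ghost else t_ghost
        if te > t_end:
            t = t_end
            break
        if te >= _BIG:
            raise RuntimeError("event calendar empty: no future events")

        # neighbour-list horizon
        if v_max * (te - t_built) >= half_skin:
            t_adv = t_built + 0.90 * half_skin / v_max
            if t_adv > te:
                t_adv = te
            if t_adv < t:
                t_adv = t
            for b in range(n):
                dt = t_adv - tb[b]
                for d in range(3):
                    pos[b, d] += vel[b, d] * dt
                    pos[b, d] -= L * np.floor(pos[b, d] / L)
                tb[b] = t_adv
            t = t_adv
            _build_neighbors(pos, L, ptype, type_maxr, skin,
                             nb_indptr, nb_list)
            t_built = t
            v_max = 1.0e-12
            for b in range(n):
                s = np.sqrt(vel[b, 0] ** 2 + vel[b, 1] ** 2 +
                            vel[b, 2] ** 2)
                if s > v_max:
                    v_max = s
            heap_size = 0
            for b in range(n):
                heap_size = _schedule_bead(b, t, pos, vel, tb, L, ptype,
                                           type_nd, type_r2, shell_mat,
                                           nb_indptr, nb_list, ctr,
                                           ht, hi, hj, hr, hci, hcj,
                                           heap_size)
            continue

        if t_ghost < te_pair:
            # ghost kick
            t = t_ghost
            b = np.random.randint(0, n)
            dtb = t - tb[b]
            for d in range(3):
                pos[b, d] += vel[b, d] * dtb
            tb[b] = t
            old = 0.5 * (vel[b, 0] ** 2 + vel[b, 1] ** 2 + vel[b, 2] ** 2)
            sd = np.sqrt(temp)
            vel[b, 0] = sd * np.random.normal(0.0, 1.0)
            vel[b, 1] = sd * np.random.normal(0.0, 1.0)
            vel[b, 2] = sd * np.random.normal(0.0, 1.0)
            ke += 0.5 * (vel[b, 0] ** 2 + vel[b, 1] ** 2 +
                         vel[b, 2] ** 2) - old
            s = np.sqrt(vel[b, 0] ** 2 + vel[b, 1] ** 2 + vel[b, 2] ** 2)
            if s > v_max:
                v_max = s
            ctr[b] += 1
            counts[EV_GHOST] += 1
            heap_size = _schedule_bead(b, t, pos, vel, tb, L, ptype,
                                       type_nd, type_r2, shell_mat,
                                       nb_indptr, nb_list, ctr,
                                       ht, hi, hj, hr, hci, hcj, heap_size)
            t_ghost = t + np.random.exponential(1.0 / (ghost_rate * n))
            continue

        # pair event
        heap_size = _heap_pop(ht, hi, hj, hr, hci, hcj, heap_size)
        ev_t = ht[heap_size]
        i = hi[heap_size]
        j = hj[heap_size]
        m = hr[heap_size]
        ci = hci[heap_size]
        cj = hcj[heap_size]
        if ci != ctr[i] or cj != ctr[j]:
            # stale entry: a bead whose counter still matches lost its only
            # scheduled event and needs a fresh minimum; a bead whose
            # counter changed was already rescheduled at its own event
            if heap_size + 2 >= cap:
                heap_size = 0
                for b in range(n):
                    heap_size = _schedule_bead(b, t, pos, vel, tb, L, ptype,
                                               type_nd, type_r2, shell_mat,
                                               nb_indptr, nb_list, ctr,
                                               ht, hi, hj, hr, hci, hcj,
                                               heap_size)
                continue
            if ci == ctr[i]:
                heap_size = _schedule_bead(i, t, pos, vel, tb, L, ptype,
                                           type_nd, type_r2, shell_mat,
                                           nb_indptr, nb_list, ctr,
                                           ht, hi, hj, hr, hci, hcj,
                                           heap_size)
            if cj == ctr[j]:
                heap_size = _schedule_bead(j, t, pos, vel, tb, L, ptype,
                                           type_nd, type_r2, shell_mat,
                                           nb_indptr, nb_list, ctr,
                                           ht, hi, hj, hr, hci, hcj,
                                           heap_size)
            continue

        if ev_t - t_prev_event < 1.0e-14:
            zero_dt_run += 1
            if zero_dt_run > 2_000_000:
                raise RuntimeError("unresolvable zero-time event cascade")
        else:
            zero_dt_run = 0
        t_prev_event = ev_t
        t = ev_t

        for b in (i, j):
            dtb = t - tb[b]
            for d in range(3):
                pos[b, d] += vel[b, d] * dtb
            tb[b] = t

        dx = _minimg(pos[i, 0] - pos[j, 0], L)
        dy = _minimg(pos[i, 1] - pos[j, 1], L)
        dz = _minimg(pos[i, 2] - pos[j, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        tt = ptype[i, j]
        R2 = type_r2[tt, m]
        if abs(r2 - R2) > 1.0e-5 * (1.0 + R2):
            raise RuntimeError("pair not at its discontinuity at event time")
        dvx = vel[i, 0] - vel[j, 0]
        dvy = vel[i, 1] - vel[j, 1]
        dvz = vel[i, 2] - vel[j, 2]
        b_dot = dx * dvx + dy * dvy + dz * dvz
        s_cur = shell_mat[i, j]
        inward = b_dot < 0.0
        if inward:
            if m != s_cur - 1:
                raise RuntimeError("event boundary inconsistent with shell")
            s_new = s_cur - 1
        else:
            if m != s_cur:
                raise RuntimeError("event boundary inconsistent with shell")
            s_new = s_cur + 1

        is_hb_pair = type_is_hb[tt]
        nd = type_nd[tt]
        outer = (m == nd - 1)

        du = 0.0
        hard = False
        act_form = False
        act_break = False
        ev_kind = EV_CORE
        if is_hb_pair and outer:
            bonded = hb_partner[i] == j
            if inward:
                if (not bonded) and hb_partner[i] < 0 and hb_partner[j] < 0:
                    i_nh = i if kind[i] == 0 else j
                    j_co = j if kind[j] == 2 else i
                    if _hb_gate(i_nh, j_co, pos, vel, tb, t, L,
                                ca_self, ca_prev, ca_next,
                                aux_min, aux_max, cos_thresh, parallel_on):
                        du = -eps_hb
                        act_form = True
                        ev_kind = EV_HB_FORM
                    else:
                        du = 0.0
                        ev_kind = EV_PASS
                else:
                    du = 0.0
                    ev_kind = EV_PASS
            else:
                if bonded:
                    du = eps_hb
                    act_break = True
                    ev_kind = EV_HB_BREAK
                else:
                    du = 0.0
                    ev_kind = EV_PASS
        else:
            lv_new = type_level[tt, s_new]
            lv_cur = type_level[tt, s_cur]
            if lv_new == np.inf:
                hard = True
                ev_kind = EV_BOND_WALL if type_level[tt, nd] == np.inf \
                    else EV_CORE
            else:
                du = lv_new - lv_cur
                if du < 0.0:
                    ev_kind = EV_WELL_IN
                elif du > 0.0:
                    ev_kind = EV_WELL_OUT
                else:
                    ev_kind = EV_PASS

        crossed = True
        if hard:
            fac = b_dot / r2
            vel[i, 0] -= fac * dx
            vel[i, 1] -= fac * dy
            vel[i, 2] -= fac * dz
            vel[j, 0] += fac * dx
            vel[j, 1] += fac * dy
            vel[j, 2] += fac * dz
            crossed = False
        elif du != 0.0:
            r = np.sqrt(r2)
            u = b_dot / r
            crit = u * u - 4.0 * du
            if du > 0.0 and crit <= 0.0:
                # insufficient radial energy: bounce, no level change
                fac = b_dot / r2
                vel[i, 0] -= fac * dx
                vel[i, 1] -= fac * dy
                vel[i, 2] -= fac * dz
                vel[j, 0] += fac * dx
                vel[j, 1] += fac * dy
                vel[j, 2] += fac * dz
                ev_kind = EV_BOUNCE
                act_form = False
                act_break = False
                crossed = False
            else:
                u_new = np.sqrt(crit)
                if inward:
                    u_new = -u_new
                half = 0.5 * (u_new - u) / r
                vel[i, 0] += half * dx
                vel[i, 1] += half * dy
                vel[i, 2] += half * dz
                vel[j, 0] -= half * dx
                vel[j, 1] -= half * dy
                vel[j, 2] -= half * dz
                pe += du
                ke -= du
                if act_form:
                    hb_partner[i] = j
                    hb_partner[j] = i
                    nhb += 1
                if act_break:
                    hb_partner[i] = -1
                    hb_partner[j] = -1
                    nhb -= 1
        if crossed:
            shell_mat[i, j] = s_new
            shell_mat[j, i] = s_new

        counts[ev_kind] += 1
        ncoll += 1
        ctr[i] += 1
        ctr[j] += 1
        for b in (i, j):
            s = np.sqrt(vel[b, 0] ** 2 + vel[b, 1] ** 2 + vel[b, 2] ** 2)
            if s > v_max:
                v_max = s
        if heap_size + 2 >= cap:
            heap_size = 0
            for b in range(n):
                heap_size = _schedule_bead(b, t, pos, vel, tb, L, ptype,
                                           type_nd, type_r2, shell_mat,
                                           nb_indptr, nb_list, ctr,
                                           ht, hi, hj, hr, hci, hcj,
                                           heap_size)
        else:
            heap_size = _schedule_bead(i, t, pos, vel, tb, L, ptype,
                                       type_nd, type_r2, shell_mat,
                                       nb_indptr, nb_list, ctr,
                                       ht, hi, hj, hr, hci, hcj, heap_size)
            heap_size = _schedule_bead(j, t, pos, vel, tb, L, ptype,
                                       type_nd, type_r2, shell_mat,
                                       nb_indptr, nb_list, ctr,
                                       ht, hi, hj, hr, hci, hcj, heap_size)

        if seg_ptr < n_seg - 1 and ncoll >= seg_end[seg_ptr]:
            seg_ptr += 1
            temp = seg_T[seg_ptr]

        if ncoll >= next_snap and n_snap < snap_pos.shape[0]:
            for b in range(n):
                dtb = t - tb[b]
                for d in range(3):
                    snap_pos[n_snap, b, d] = pos[b, d] + vel[b, d] * dtb
            snap_t[n_snap] = t
            snap_pe[n_snap] = pe
            snap_ke[n_snap] = ke
            snap_ncoll[n_snap] = ncoll
            snap_nhb[n_snap] = nhb
            inter = 0
            for b in range(n):
                p_ = hb_partner[b]
                if p_ >= 0 and b < p_ and chain_of[b] != chain_of[p_]:
                    inter += 1
            snap_nhb_inter[n_snap] = inter
            n_snap += 1
            next_snap += snap_every

    # synchronize all beads at the final time
    for b in range(n):
        dtb = t - tb[b]
        for d in range(3):
            pos[b, d] += vel[b, d] * dtb
        tb[b] = t

    return t, ncoll, pe, ke, n_snap, counts
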