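"""Numba-compiled core: switch integration, basin maps, and the SSA event loop.

Everything in this module works on plain numpy arrays and scalars so that it
can be jit-compiled; the user-facing wrappers live in :mod:`stemdish.switches`
and :mod:`stemdish.engine`.

Lattice state is flattened to 1-D arrays of length ``N = height * width``.
Per-mesh total propensities are kept in a Fenwick (binary indexed) tree so a
single SSA event costs ``O(log N)`` for selection plus a handful of local
mesh recomputations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# parameter-vector layout (values pre-processed by the engine: the beta
# entries hold beta**n, P_DIFF holds D/h**2)
P_IOTA_XS = 0   # stem X synthesis base rate (density feedback applied on top)
P_IOTA_YS = 1
P_BSN = 2       # stem beta**n
P_HN_S = 3
P_G_S = 4
P_AX = 5        # progenitor alpha_x
P_AY = 6
P_IX = 7
P_IY = 8
P_BPN = 9       # progenitor beta**n
P_HN_P = 10
P_G_P = 11
P_EA = 12       # signal-effect a
P_EB = 13       # signal-effect b
P_AS1 = 14
P_AS2 = 15
P_BGN = 16      # signal beta**n
P_HN_G = 17
P_K = 18
P_DIFF = 19     # D / h**2
P_RS = 20
P_GS = 21
P_WP = 22
P_MS = 23
P_RP = 24
P_GP = 25
P_WS = 26
P_MP = 27
P_GA = 28
P_GB = 29
P_N0 = 30       # iota_xs(n) calibration census
P_TERM = 31
P_SIG_ON = 32
P_DIFF_COUNT = 33
P_DIFF_WEIGHTED = 34
N_PRM = 35

# population-level event counters (mean-field bridge)
C_ETA = 0        # S -> S + P
C_ETA_S = 1      # S -> S + S
C_ETA_P = 2      # S -> P + P
C_GAMMA_S = 3
C_W_P = 4        # S -> P
C_W_S = 5        # P -> S
C_GAMMA_P = 6
C_LAM_P = 7      # P -> P + P
C_LAM_A = 8
C_LAM_B = 9
C_MU_D = 10      # P -> A + B
C_MU_A = 11
C_MU_B = 12
C_GAMMA_A = 13
C_GAMMA_B = 14
C_MOVE_S = 15
C_MOVE_P = 16
C_S1_PROD = 17
C_S1_DEG = 18
C_S2_PROD = 19
C_S2_DEG = 20
C_S1_DIFF = 21
C_S2_DIFF = 22
C_XS_PROD = 23
C_XS_DEG = 24
C_YS_PROD = 25
C_YS_DEG = 26
C_XP_PROD = 27
C_XP_DEG = 28
C_YP_PROD = 29
C_YP_DEG = 30
N_COUNTS = 31

STATUS_OK = 0
STATUS_DEADLOCK = 1
STATUS_EXTINCT = 2
STATUS_MAX_EVENTS = 3

_CLASSIFY_DT = 0.01
_CLASSIFY_MAX_STEPS = 100_000
_CLASSIFY_BALL = 1.0       # Euclidean capture radius around a stable fixed point
_CLASSIFY_DRIFT_TOL = 1e-10


# ---------------------------------------------------------------------------
# switch integration / fate classification

@njit(cache=True, inline="always")
def _pow_clip(v, n):
    if v <= 0.0:
        return 0.0
    if n == 4.0:
        w = v * v
        return w * w
    return v ** n


@njit(cache=True)
def classify_stem(x0, y0, iota_x, iota_y, bsn, n, g, fps, labels):
    """Integrate the bistable drift from (x0, y0); return the attractor label.

    A trajectory is assigned as soon as it enters the unit ball around a
    stable fixed point; a stall outside every ball (separatrix/saddle) falls
    back to the tie label P (=2).
    """
    x = float(x0)
    y = float(y0)
    dt = _CLASSIFY_DT
    for _ in range(_CLASSIFY_MAX_STEPS):
        for i in range(fps.shape[0]):
            dx = x - fps[i, 0]
            dy = y - fps[i, 1]
            if dx * dx + dy * dy <= _CLASSIFY_BALL * _CLASSIFY_BALL:
                return labels[i]
        k1x = iota_x * bsn / (bsn + _pow_clip(y, n)) - g * x
        k1y = iota_y * bsn / (bsn + _pow_clip(x, n)) - g * y
        if abs(k1x) + abs(k1y) < _CLASSIFY_DRIFT_TOL:
            return np.int8(2)
        x2 = x + 0.5 * dt * k1x
        y2 = y + 0.5 * dt * k1y
        k2x = iota_x * bsn / (bsn + _pow_clip(y2, n)) - g * x2
        k2y = iota_y * bsn / (bsn + _pow_clip(x2, n)) - g * y2
        x3 = x + 0.5 * dt * k2x
        y3 = y + 0.5 * dt * k2y
        k3x = iota_x * bsn / (bsn + _pow_clip(y3, n)) - g * x3
        k3y = iota_y * bsn / (bsn + _pow_clip(x3, n)) - g * y3
        x4 = x + dt * k3x
        y4 = y + dt * k3y
        k4x = iota_x * bsn / (bsn + _pow_clip(y4, n)) - g * x4
        k4y = iota_y * bsn / (bsn + _pow_clip(x4, n)) - g * y4
        x += dt * (k1x + 2.0 * k2x + 2.0 * k3x + k4x) / 6.0
        y += dt * (k1y + 2.0 * k2y + 2.0 * k3y + k4y) / 6.0
    return np.int8(2)


@njit(cache=True, inline="always")
def _prog_drift_x(x, y, ax, ix, bpn, n, g, eps):
    xn = _pow_clip(x, n)
    return (ax + eps) * xn / (bpn + xn) + ix * bpn / (bpn + _pow_clip(y, n)) - g * x


@njit(cache=True)
def classify_prog(x0, y0, ax, ay, ix, iy, bpn, n, g, eps_x, eps_y, fps, nfp, labels):
    """Tristable analogue of :func:`classify_stem`; tie label is P (=2)."""
    x = float(x0)
    y = float(y0)
    dt = _CLASSIFY_DT
    for _ in range(_CLASSIFY_MAX_STEPS):
        for i in range(nfp):
            dx = x - fps[i, 0]
            dy = y - fps[i, 1]
            if dx * dx + dy * dy <= _CLASSIFY_BALL * _CLASSIFY_BALL:
                return labels[i]
        k1x = _prog_drift_x(x, y, ax, ix, bpn, n, g, eps_x)
        k1y = _prog_drift_x(y, x, ay, iy, bpn, n, g, eps_y)
        if abs(k1x) + abs(k1y) < _CLASSIFY_DRIFT_TOL:
            return np.int8(2)
        x2 = x + 0.5 * dt * k1x
        y2 = y + 0.5 * dt * k1y
        k2x = _prog_drift_x(x2, y2, ax, ix, bpn, n, g, eps_x)
        k2y = _prog_drift_x(y2, x2, ay, iy, bpn, n, g, eps_y)
        x3 = x + 0.5 * dt * k2x
        y3 = y + 0.5 * dt * k2y
        k3x = _prog_drift_x(x3, y3, ax, ix, bpn, n, g, eps_x)
        k3y = _prog_drift_x(y3, x3, ay, iy, bpn, n, g, eps_y)
        x4 = x + dt * k3x
        y4 = y + dt * k3y
        k4x = _prog_drift_x(x4, y4, ax, ix, bpn, n, g, eps_x)
        k4y = _prog_drift_x(y4, x4, ay, iy, bpn, n, g, eps_y)
        x += dt * (k1x + 2.0 * k2x + 2.0 * k3x + k4x) / 6.0
        y += dt * (k1y + 2.0 * k2y + 2.0 * k3y + k4y) / 6.0
    return np.int8(2)


@njit(cache=True)
def build_stem_map(res, iota_x, iota_y, bsn, n, g, fps, labels):
    out = np.empty((res, res), np.int8)
    for i in range(res):
        for j in range(res):
            out[i, j] = classify_stem(float(i), float(j), iota_x, iota_y, bsn, n, g,
                                      fps, labels)
    return out


@njit(cache=True)
def build_prog_map(res, ax, ay, ix, iy, bpn, n, g, eps_x, eps_y, fps, nfp, labels):
    out = np.empty((res, res), np.int8)
    for i in range(res):
        for j in range(res):
            out[i, j] = classify_prog(float(i), float(j), ax, ay, ix, iy, bpn, n, g,
                                      eps_x, eps_y, fps, nfp, labels)
    return out


# ---------------------------------------------------------------------------
# Fenwick tree over per-mesh total propensities

@njit(cache=True, inline="always")
def _fenwick_add(tree, i, delta):
    i += 1
    n = tree.shape[0]
    while i < n:
        tree[i] += delta
        i += i & (-i)


@njit(cache=True)
def _fenwick_find(tree, top_bit, r):
    """Largest index with prefix sum <= r; returns (0-based mesh, residual)."""
    pos = 0
    k = top_bit
    n = tree.shape[0]
    while k > 0:
        nxt = pos + k
        if nxt < n and tree[nxt] <= r:
            r -= tree[nxt]
            pos = nxt
        k >>= 1
    return pos, r


# ---------------------------------------------------------------------------
# per-mesh reaction channels (codes follow the published rate-table rows)

@njit(cache=True)
def _mesh_channels(m, ctype, cx, cy, s1, s2, nbr8, n8, prm, iota_now, codes, props):
    """Fill (codes, props) with the active channels of mesh ``m``.

    Returns the channel count.  Channel codes: 1-8 stem cell, 9-16 progenitor
    cell, 17/18 terminal death, 19-24 signal production/decay/diffusion.
    """
    k = 0
    t = ctype[m]
    if t == 1:  # stem cell
        n = prm[P_HN_S]
        bsn = prm[P_BSN]
        g = prm[P_G_S]
        codes[k] = 1
        props[k] = iota_now * bsn / (bsn + _pow_clip(float(cy[m]), n))
        k += 1
        codes[k] = 2
        props[k] = g * cx[m]
        k += 1
        codes[k] = 3
        props[k] = prm[P_IOTA_YS] * bsn / (bsn + _pow_clip(float(cx[m]), n))
        k += 1
        codes[k] = 4
        props[k] = g * cy[m]
        k += 1
        has_room = False
        for q in range(n8[m]):
            if ctype[nbr8[m, q]] == 0:
                has_room = True
                break
        if has_room:
            codes[k] = 5
            props[k] = prm[P_RS]
            k += 1
        codes[k] = 6
        props[k] = prm[P_GS]
        k += 1
        codes[k] = 7
        props[k] = prm[P_WP]
        k += 1
        codes[k] = 8
        props[k] = prm[P_MS]
        k += 1
    elif t == 2:  # progenitor cell
        n = prm[P_HN_P]
        bpn = prm[P_BPN]
        g = prm[P_G_P]
        if prm[P_SIG_ON] > 0.5:
            a = prm[P_EA]
            b = prm[P_EB]
            e1 = a * s1[m] / b if s1[m] <= b else a
            e2 = a * s2[m] / b if s2[m] <= b else a
        else:
            e1 = 0.0
            e2 = 0.0
        xn = _pow_clip(float(cx[m]), n)
        yn = _pow_clip(float(cy[m]), n)
        codes[k] = 9
        props[k] = (prm[P_AX] + e1) * xn / (bpn + xn) + prm[P_IX] * bpn / (bpn + yn)
        k += 1
        codes[k] = 10
        props[k] = g * cx[m]
        k += 1
        codes[k] = 11
        props[k] = (prm[P_AY] + e2) * yn / (bpn + yn) + prm[P_IY] * bpn / (bpn + xn)
        k += 1
        codes[k] = 12
        props[k] = g * cy[m]
        k += 1
        has_room = False
        for q in range(n8[m]):
            if ctype[nbr8[m, q]] == 0:
                has_room = True
                break
        if has_room:
            codes[k] = 13
            props[k] = prm[P_RP]
            k += 1
        codes[k] = 14
        props[k] = prm[P_GP]
        k += 1
        codes[k] = 15
        props[k] = prm[P_WS]
        k += 1
        codes[k] = 16
        props[k] = prm[P_MP]
        k += 1
    elif t == 3:
        codes[k] = 17
        props[k] = prm[P_GA]
        k += 1
    elif t == 4:
        codes[k] = 18
        props[k] = prm[P_GB]
        k += 1
    if prm[P_SIG_ON] > 0.5:
        ng = prm[P_HN_G]
        bgn = prm[P_BGN]
        if t == 3:
            codes[k] = 19
            props[k] = prm[P_AS1] * bgn / (bgn + _pow_clip(float(s2[m]), ng))
            k += 1
        if s1[m] > 0:
            codes[k] = 20
            props[k] = prm[P_K] * s1[m]
            k += 1
        if t == 4:
            codes[k] = 21
            props[k] = prm[P_AS2] * bgn / (bgn + _pow_clip(float(s1[m]), ng))
            k += 1
        if s2[m] > 0:
            codes[k] = 22
            props[k] = prm[P_K] * s2[m]
            k += 1
        if s1[m] > 0:
            codes[k] = 23
            props[k] = prm[P_DIFF] * s1[m] if prm[P_DIFF_COUNT] > 0.5 else prm[P_DIFF]
            k += 1
        if s2[m] > 0:
            codes[k] = 24
            props[k] = prm[P_DIFF] * s2[m] if prm[P_DIFF_COUNT] > 0.5 else prm[P_DIFF]
            k += 1
    return k


@njit(cache=True)
def _mesh_total(m, ctype, cx, cy, s1, s2, nbr8, n8, prm, iota_now, codes, props):
    k = _mesh_channels(m, ctype, cx, cy, s1, s2, nbr8, n8, prm, iota_now, codes, props)
    tot = 0.0
    for i in range(k):
        tot += props[i]
    return tot


# ---------------------------------------------------------------------------
# the SSA loop

@njit(cache=True)
def run_kernel(seed,
               ctype, cx, cy, cdiv, s1, s2, valid,
               nbr4, n4, nbr8, n8,
               prm,
               stem_fps, stem_labels,
               prog_fps, prog_nfp, prog_labels,
               stem_map, prog_map,
               inj_mask, inj_trigger,
               snaps, snap_t, snap_ab, snap_md,
               counts, exposure,
               snap_dt0, max_events):
    np.random.seed(seed)
    N = ctype.shape[0]

    # --- bookkeeping structures -------------------------------------------
    tree = np.zeros(N + 1, np.float64)
    ptot = np.zeros(N, np.float64)
    top_bit = 1
    while top_bit * 2 <= N:
        top_bit *= 2
    codes = np.empty(16, np.int64)
    props = np.empty(16, np.float64)

    # membership lists with O(1) removal
    s_list = np.empty(N, np.int64)
    s_pos = np.full(N, -1, np.int64)
    p_list = np.empty(N, np.int64)
    p_pos = np.full(N, -1, np.int64)
    e_list = np.empty(N, np.int64)
    e_pos = np.full(N, -1, np.int64)
    n_s = 0
    n_p = 0
    n_e = 0
    n_a = 0
    n_b = 0
    div_sum = 0.0   # sum of per-cell counters (bookkeeping only)
    cum_div = 0.0   # cumulative count of P-division events (termination statistic)
    for m in range(N):
        if valid[m] == 0:
            continue
        t = ctype[m]
        if t == 0:
            e_list[n_e] = m
            e_pos[m] = n_e
            n_e += 1
        elif t == 1:
            s_list[n_s] = m
            s_pos[m] = n_s
            n_s += 1
        elif t == 2:
            p_list[n_p] = m
            p_pos[m] = n_p
            n_p += 1
            div_sum += cdiv[m]
        elif t == 3:
            n_a += 1
        elif t == 4:
            n_b += 1

    n0 = prm[P_N0]
    base = prm[P_IOTA_XS]
    nd = float(n_s + n_p)
    iota_now = base * 2.0 * n0 / (n0 + nd)

    total = 0.0
    for m in range(N):
        if valid[m] == 1:
            ptot[m] = _mesh_total(m, ctype, cx, cy, s1, s2, nbr8, n8, prm, iota_now,
                                  codes, props)
            _fenwick_add(tree, m, ptot[m])
            total += ptot[m]

    mb = int(prm[P_EB])  # signal-effect saturation count (table index bound)
    nb_a = prm[P_EA]
    term = prm[P_TERM]
    weighted = prm[P_DIFF_WEIGHTED] > 0.5
    n_inj = inj_trigger.shape[0]
    next_inj = 0

    # --- snapshot ring buffer ---------------------------------------------
    buf = snaps.shape[0]
    snap_dt = snap_dt0
    n_snap = 0
    snaps[0, :] = ctype
    snap_t[0] = 0.0
    snap_ab[0, 0] = n_s
    snap_ab[0, 1] = n_p
    snap_ab[0, 2] = n_a
    snap_ab[0, 3] = n_b
    snap_md[0] = cum_div / n_p if n_p > 0 else 0.0
    n_snap = 1
    next_snap = snap_dt

    t_now = 0.0
    status = STATUS_MAX_EVENTS
    n_events = 0

    while n_events < max_events:
        # periodic exact rebuild to keep float drift at bay
        if (n_events & 0xFFFFF) == 0xFFFFF:
            tree[:] = 0.0
            total = 0.0
            for m in range(N):
                if valid[m] == 1:
                    ptot[m] = _mesh_total(m, ctype, cx, cy, s1, s2, nbr8, n8, prm,
                                          iota_now, codes, props)
                    _fenwick_add(tree, m, ptot[m])
                    total += ptot[m]
                else:
                    ptot[m] = 0.0

        if total <= 1e-12:
            status = STATUS_EXTINCT if (n_s + n_p + n_a + n_b) == 0 else STATUS_DEADLOCK
            break

        wait = np.random.exponential(1.0 / total)
        t_new = t_now + wait
        exposure[0] += n_s * wait
        exposure[1] += n_p * wait
        exposure[2] += n_a * wait
        exposure[3] += n_b * wait

        while next_snap <= t_new:
            if n_snap == buf:
                half = buf // 2
                for i in range(half):
                    snaps[i, :] = snaps[2 * i, :]
                    snap_t[i] = snap_t[2 * i]
                    snap_ab[i, 0] = snap_ab[2 * i, 0]
                    snap_ab[i, 1] = snap_ab[2 * i, 1]
                    snap_ab[i, 2] = snap_ab[2 * i, 2]
                    snap_ab[i, 3] = snap_ab[2 * i, 3]
                    snap_md[i] = snap_md[2 * i]
                n_snap = half
                snap_dt *= 2.0
                next_snap = snap_t[n_snap - 1] + snap_dt
                continue
            snaps[n_snap, :] = ctype
            snap_t[n_snap] = next_snap
            snap_ab[n_snap, 0] = n_s
            snap_ab[n_snap, 1] = n_p
            snap_ab[n_snap, 2] = n_a
            snap_ab[n_snap, 3] = n_b
            snap_md[n_snap] = cum_div / n_p if n_p > 0 else 0.0
            n_snap += 1
            next_snap += snap_dt

        t_now = t_new
        n_events += 1

        u = np.random.random() * total
        if u >= total:
            u = total * (1.0 - 1e-16)
        m, rem = _fenwick_find(tree, top_bit, u)
        if m >= N:
            m = N - 1
        nk = _mesh_channels(m, ctype, cx, cy, s1, s2, nbr8, n8, prm, iota_now,
                            codes, props)
        if nk == 0:
            continue  # stale float residue on an inactive mesh
        code = codes[nk - 1]
        for i in range(nk):
            if rem < props[i]:
                code = codes[i]
                break
            rem -= props[i]

        nd_changed = False
        pop_changed = False  # n_p or div_sum changed -> check termination/injury

        # ----- determinant updates ------------------------------------
        if code == 1:
            cx[m] += 1
            counts[C_XS_PROD] += 1
        elif code == 2:
            cx[m] -= 1
            counts[C_XS_DEG] += 1
        elif code == 3:
            cy[m] += 1
            counts[C_YS_PROD] += 1
        elif code == 4:
            cy[m] -= 1
            counts[C_YS_DEG] += 1
        elif code == 9:
            cx[m] += 1
            counts[C_XP_PROD] += 1
        elif code == 10:
            cx[m] -= 1
            counts[C_XP_DEG] += 1
        elif code == 11:
            cy[m] += 1
            counts[C_YP_PROD] += 1
        elif code == 12:
            cy[m] -= 1
            counts[C_YP_DEG] += 1

        # ----- signal production / decay ------------------------------
        elif code == 19:
            s1[m] += 1
            counts[C_S1_PROD] += 1
        elif code == 20:
            s1[m] -= 1
            counts[C_S1_DEG] += 1
        elif code == 21:
            s2[m] += 1
            counts[C_S2_PROD] += 1
        elif code == 22:
            s2[m] -= 1
            counts[C_S2_DEG] += 1

        # ----- signal diffusion ---------------------------------------
        elif code == 23 or code == 24:
            nn = n4[m]
            if nn > 0:
                if weighted:
                    wsum = 0.0
                    for q in range(nn):
                        tgt = nbr4[m, q]
                        wsum += 1.0 + (s1[tgt] if code == 23 else s2[tgt])
                    r = np.random.random() * wsum
                    tgt = nbr4[m, nn - 1]
                    for q in range(nn):
                        cand = nbr4[m, q]
                        w = 1.0 + (s1[cand] if code == 23 else s2[cand])
                        if r < w:
                            tgt = cand
                            break
                        r -= w
                else:
                    tgt = nbr4[m, np.random.randint(0, nn)]
                if code == 23:
                    s1[m] -= 1
                    s1[tgt] += 1
                    counts[C_S1_DIFF] += 1
                else:
                    s2[m] -= 1
                    s2[tgt] += 1
                    counts[C_S2_DIFF] += 1
                ptot_new = _mesh_total(tgt, ctype, cx, cy, s1, s2, nbr8, n8, prm,
                                       iota_now, codes, props)
                delta = ptot_new - ptot[tgt]
                ptot[tgt] = ptot_new
                _fenwick_add(tree, tgt, delta)
                total += delta

        # ----- death / injury-style removal ---------------------------
        elif code == 6 or code == 14 or code == 17 or code == 18:
            t = ctype[m]
            if t == 1:
                counts[C_GAMMA_S] += 1
                idx = s_pos[m]
                n_s -= 1
                s_list[idx] = s_list[n_s]
                s_pos[s_list[idx]] = idx
                s_pos[m] = -1
                nd_changed = True
            elif t == 2:
                counts[C_GAMMA_P] += 1
                idx = p_pos[m]
                n_p -= 1
                p_list[idx] = p_list[n_p]
                p_pos[p_list[idx]] = idx
                p_pos[m] = -1
                div_sum -= cdiv[m]
                nd_changed = True
                pop_changed = True
            elif t == 3:
                counts[C_GAMMA_A] += 1
                n_a -= 1
            else:
                counts[C_GAMMA_B] += 1
                n_b -= 1
            ctype[m] = 0
            cx[m] = 0
            cy[m] = 0
            cdiv[m] = 0
            e_list[n_e] = m
            e_pos[m] = n_e
            n_e += 1
            for q in range(n8[m]):
                nb = nbr8[m, q]
                ptot_new = _mesh_total(nb, ctype, cx, cy, s1, s2, nbr8, n8, prm,
                                       iota_now, codes, props)
                delta = ptot_new - ptot[nb]
                ptot[nb] = ptot_new
                _fenwick_add(tree, nb, delta)
                total += delta

        # ----- transformation -----------------------------------------
        elif code == 7:  # S -> P, determinants resampled from the P basin
            counts[C_W_P] += 1
            idx = s_pos[m]
            n_s -= 1
            s_list[idx] = s_list[n_s]
            s_pos[s_list[idx]] = idx
            s_pos[m] = -1
            ctype[m] = 2
            res = prog_map.shape[0]
            for _ in range(100000):
                gi = np.random.randint(0, res)
                gj = np.random.randint(0, res)
                if prog_map[gi, gj] == 2:
                    cx[m] = gi
                    cy[m] = gj
                    break
            cdiv[m] = 0
            p_list[n_p] = m
            p_pos[m] = n_p
            n_p += 1
            pop_changed = True
        elif code == 15:  # P -> S
            counts[C_W_S] += 1
            idx = p_pos[m]
            n_p -= 1
            p_list[idx] = p_list[n_p]
            p_pos[p_list[idx]] = idx
            p_pos[m] = -1
            div_sum -= cdiv[m]
            ctype[m] = 1
            res = stem_map.shape[0]
            for _ in range(100000):
                gi = np.random.randint(0, res)
                gj = np.random.randint(0, res)
                if stem_map[gi, gj] == 1:
                    cx[m] = gi
                    cy[m] = gj
                    break
            cdiv[m] = 0
            s_list[n_s] = m
            s_pos[m] = n_s
            n_s += 1
            pop_changed = True

        # ----- movement ------------------------------------------------
        elif code == 8 or code == 16:
            if n_e > 0:  # otherwise a logged no-op
                tgt = e_list[np.random.randint(0, n_e)]
                t = ctype[m]
                ctype[tgt] = t
                cx[tgt] = cx[m]
                cy[tgt] = cy[m]
                cdiv[tgt] = cdiv[m]
                ctype[m] = 0
                cx[m] = 0
                cy[m] = 0
                cdiv[m] = 0
                # swap membership: tgt leaves empties, m joins
                idx = e_pos[tgt]
                e_list[idx] = m
                e_pos[m] = idx
                e_pos[tgt] = -1
                if t == 1:
                    counts[C_MOVE_S] += 1
                    idx = s_pos[m]
                    s_list[idx] = tgt
                    s_pos[tgt] = idx
                    s_pos[m] = -1
                else:
                    counts[C_MOVE_P] += 1
                    idx = p_pos[m]
                    p_list[idx] = tgt
                    p_pos[tgt] = idx
                    p_pos[m] = -1
                ptot_new = _mesh_total(tgt, ctype, cx, cy, s1, s2, nbr8, n8, prm,
                                       iota_now, codes, props)
                delta = ptot_new - ptot[tgt]
                ptot[tgt] = ptot_new
                _fenwick_add(tree, tgt, delta)
                total += delta
                for q in range(n8[tgt]):
                    nb = nbr8[tgt, q]
                    ptot_new = _mesh_total(nb, ctype, cx, cy, s1, s2, nbr8, n8, prm,
                                           iota_now, codes, props)
                    delta = ptot_new - ptot[nb]
                    ptot[nb] = ptot_new
                    _fenwick_add(tree, nb, delta)
                    total += delta
                for q in range(n8[m]):
                    nb = nbr8[m, q]
                    ptot_new = _mesh_total(nb, ctype, cx, cy, s1, s2, nbr8, n8, prm,
                                           iota_now, codes, props)
                    delta = ptot_new - ptot[nb]
                    ptot[nb] = ptot_new
                    _fenwick_add(tree, nb, delta)
                    total += delta

        # ----- division -------------------------------------------------
        elif code == 5 or code == 13:
            ne_loc = 0
            for q in range(n8[m]):
                if ctype[nbr8[m, q]] == 0:
                    ne_loc += 1
            if ne_loc > 0:
                pick = np.random.randint(0, ne_loc)
                tgt = -1
                for q in range(n8[m]):
                    if ctype[nbr8[m, q]] == 0:
                        if pick == 0:
                            tgt = nbr8[m, q]
                            break
                        pick -= 1
                mother_t = ctype[m]
                mother_div = cdiv[m]
                if mother_t == 2:
                    cum_div += 1.0
                x1 = np.random.binomial(cx[m], 0.5)
                x2 = cx[m] - x1
                y1 = np.random.binomial(cy[m], 0.5)
                y2 = cy[m] - y1

                if mother_t == 1:
                    # density feedback acts on the synthesis channel only; the
                    # fate-calling basins stay at the base switch parameters
                    l1 = classify_stem(x1, y1, prm[P_IOTA_XS], prm[P_IOTA_YS],
                                       prm[P_BSN], prm[P_HN_S], prm[P_G_S],
                                       stem_fps, stem_labels)
                    l2 = classify_stem(x2, y2, prm[P_IOTA_XS], prm[P_IOTA_YS],
                                       prm[P_BSN], prm[P_HN_S], prm[P_G_S],
                                       stem_fps, stem_labels)
                else:
                    if prm[P_SIG_ON] > 0.5:
                        i1a = s1[m] if s1[m] < mb else mb
                        i1b = s2[m] if s2[m] < mb else mb
                        i2a = s1[tgt] if s1[tgt] < mb else mb
                        i2b = s2[tgt] if s2[tgt] < mb else mb
                    else:
                        i1a = 0
                        i1b = 0
                        i2a = 0
                        i2b = 0
                    l1 = classify_prog(x1, y1, prm[P_AX], prm[P_AY], prm[P_IX],
                                       prm[P_IY], prm[P_BPN], prm[P_HN_P], prm[P_G_P],
                                       nb_a * i1a / mb, nb_a * i1b / mb,
                                       prog_fps[i1a, i1b], prog_nfp[i1a, i1b],
                                       prog_labels[i1a, i1b])
                    l2 = classify_prog(x2, y2, prm[P_AX], prm[P_AY], prm[P_IX],
                                       prm[P_IY], prm[P_BPN], prm[P_HN_P], prm[P_G_P],
                                       nb_a * i2a / mb, nb_a * i2b / mb,
                                       prog_fps[i2a, i2b], prog_nfp[i2a, i2b],
                                       prog_labels[i2a, i2b])

                # event counters keyed by the unordered daughter pair
                if mother_t == 1:
                    if l1 == 1 and l2 == 1:
                        counts[C_ETA_S] += 1
                    elif l1 == 2 and l2 == 2:
                        counts[C_ETA_P] += 1
                    else:
                        counts[C_ETA] += 1
                else:
                    if l1 == 2 and l2 == 2:
                        counts[C_LAM_P] += 1
                    elif (l1 == 2 and l2 == 3) or (l1 == 3 and l2 == 2):
                        counts[C_LAM_A] += 1
                    elif (l1 == 2 and l2 == 4) or (l1 == 4 and l2 == 2):
                        counts[C_LAM_B] += 1
                    elif (l1 == 3 and l2 == 4) or (l1 == 4 and l2 == 3):
                        counts[C_MU_D] += 1
                    elif l1 == 3 and l2 == 3:
                        counts[C_MU_A] += 1
                    else:
                        counts[C_MU_B] += 1

                # remove the mother from the membership bookkeeping
                if mother_t == 1:
                    idx = s_pos[m]
                    n_s -= 1
                    s_list[idx] = s_list[n_s]
                    s_pos[s_list[idx]] = idx
                    s_pos[m] = -1
                else:
                    idx = p_pos[m]
                    n_p -= 1
                    p_list[idx] = p_list[n_p]
                    p_pos[p_list[idx]] = idx
                    p_pos[m] = -1
                    div_sum -= mother_div

                # occupy the placement target
                idx = e_pos[tgt]
                n_e -= 1
                e_list[idx] = e_list[n_e]
                e_pos[e_list[idx]] = idx
                e_pos[tgt] = -1

                for d in range(2):
                    dst = m if d == 0 else tgt
                    lab = l1 if d == 0 else l2
                    dx = x1 if d == 0 else x2
                    dy = y1 if d == 0 else y2
                    ctype[dst] = lab
                    if lab == 1:
                        if mother_t != 1:  # system change: resample stem S basin
                            res = stem_map.shape[0]
                            for _ in range(100000):
                                gi = np.random.randint(0, res)
                                gj = np.random.randint(0, res)
                                if stem_map[gi, gj] == 1:
                                    dx = gi
                                    dy = gj
                                    break
                        cx[dst] = dx
                        cy[dst] = dy
                        cdiv[dst] = 0
                        s_list[n_s] = dst
                        s_pos[dst] = n_s
                        n_s += 1
                    elif lab == 2:
                        if mother_t != 2:  # system change: resample P basin
                            res = prog_map.shape[0]
                            for _ in range(100000):
                                gi = np.random.randint(0, res)
                                gj = np.random.randint(0, res)
                                if prog_map[gi, gj] == 2:
                                    dx = gi
                                    dy = gj
                                    break
                            cdiv[dst] = 0
                        else:
                            cdiv[dst] = mother_div + 1
                            div_sum += mother_div + 1
                        cx[dst] = dx
                        cy[dst] = dy
                        p_list[n_p] = dst
                        p_pos[dst] = n_p
                        n_p += 1
                    else:  # terminal cell: no determinant dynamics
                        cx[dst] = 0
                        cy[dst] = 0
                        cdiv[dst] = 0
                        if lab == 3:
                            n_a += 1
                        else:
                            n_b += 1

                for q in range(n8[tgt]):
                    nb = nbr8[tgt, q]
                    ptot_new = _mesh_total(nb, ctype, cx, cy, s1, s2, nbr8, n8, prm,
                                           iota_now, codes, props)
                    delta = ptot_new - ptot[nb]
                    ptot[nb] = ptot_new
                    _fenwick_add(tree, nb, delta)
                    total += delta
                ptot_new = _mesh_total(tgt, ctype, cx, cy, s1, s2, nbr8, n8, prm,
                                       iota_now, codes, props)
                delta = ptot_new - ptot[tgt]
                ptot[tgt] = ptot_new
                _fenwick_add(tree, tgt, delta)
                total += delta
                nd_changed = True
                pop_changed = True

        # refresh the event mesh itself (cheap and always safe)
        ptot_new = _mesh_total(m, ctype, cx, cy, s1, s2, nbr8, n8, prm, iota_now,
                               codes, props)
        delta = ptot_new - ptot[m]
        ptot[m] = ptot_new
        _fenwick_add(tree, m, delta)
        total += delta

        # density feedback on the stem X synthesis rate
        if nd_changed:
            nd = float(n_s + n_p)
            iota_new = base * 2.0 * n0 / (n0 + nd)
            if iota_new != iota_now:
                iota_now = iota_new
                for i in range(n_s):
                    sm = s_list[i]
                    ptot_new = _mesh_total(sm, ctype, cx, cy, s1, s2, nbr8, n8, prm,
                                           iota_now, codes, props)
                    delta = ptot_new - ptot[sm]
                    ptot[sm] = ptot_new
                    _fenwick_add(tree, sm, delta)
                    total += delta

        if pop_changed and n_p > 0:
            mean_div = cum_div / n_p
            # fire pending injuries
            while next_inj < n_inj and mean_div >= inj_trigger[next_inj]:
                for mm in range(N):
                    if inj_mask[next_inj, mm] == 1 and ctype[mm] > 0:
                        t = ctype[mm]
                        if t == 1:
                            idx = s_pos[mm]
                            n_s -= 1
                            s_list[idx] = s_list[n_s]
                            s_pos[s_list[idx]] = idx
                            s_pos[mm] = -1
                        elif t == 2:
                            idx = p_pos[mm]
                            n_p -= 1
                            p_list[idx] = p_list[n_p]
                            p_pos[p_list[idx]] = idx
                            p_pos[mm] = -1
                            div_sum -= cdiv[mm]
                        elif t == 3:
                            n_a -= 1
                        else:
                            n_b -= 1
                        ctype[mm] = 0
                        cx[mm] = 0
                        cy[mm] = 0
                        cdiv[mm] = 0
                        e_list[n_e] = mm
                        e_pos[mm] = n_e
                        n_e += 1
                next_inj += 1
                nd = float(n_s + n_p)
                iota_now = base * 2.0 * n0 / (n0 + nd)
                tree[:] = 0.0
                total = 0.0
                for mm in range(N):
                    if valid[mm] == 1:
                        ptot[mm] = _mesh_total(mm, ctype, cx, cy, s1, s2, nbr8, n8,
                                               prm, iota_now, codes, props)
                        _fenwick_add(tree, mm, ptot[mm])
                        total += ptot[mm]
                    else:
                        ptot[mm] = 0.0
                mean_div = cum_div / n_p if n_p > 0 else 0.0
                if n_p == 0:
                    break
            if n_p > 0 and cum_div / n_p >= term and next_inj >= n_inj:
                status = STATUS_OK
                break

    # final snapshot at the exact stopping time
    if n_snap == buf:
        half = buf // 2
        for i in range(half):
            snaps[i, :] = snaps[2 * i, :]
            snap_t[i] = snap_t[2 * i]
            snap_ab[i, 0] = snap_ab[2 * i, 0]
            snap_ab[i, 1] = snap_ab[2 * i, 1]
            snap_ab[i, 2] = snap_ab[2 * i, 2]
            snap_ab[i, 3] = snap_ab[2 * i, 3]
            snap_md[i] = snap_md[2 * i]
        n_snap = half
    snaps[n_snap, :] = ctype
    snap_t[n_snap] = t_now
    snap_ab[n_snap, 0] = n_s
    snap_ab[n_snap, 1] = n_p
    snap_ab[n_snap, 2] = n_a
    snap_ab[n_snap, 3] = n_b
    snap_md[n_snap] = cum_div / n_p if n_p > 0 else 0.0
    n_snap += 1

    return status, n_snap, t_now, n_events
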