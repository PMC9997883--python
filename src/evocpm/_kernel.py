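"""Numba kernel for Act-CPM dynamics.

Implements the same physics as :mod:`evocpm.hamiltonian` but rejection-free:
copy attempts whose source and target share a cell id never change the state,
so instead of iterating over all ``width x height`` attempts per MCS the
kernel draws the geometric waiting time (in attempts) until the next
id-mismatched attempt. The mismatch probability is ``B / (8 N)`` where ``B``
is the number of ordered unlike Moore pixel pairs, maintained incrementally.
The resulting per-MCS state distribution is identical to the naive sweep.

Activity is stored lazily as the MCS at which each pixel was gained
(``gain``); the current activity is ``max(0, max_act - (t - gain))``, which
reproduces the decay-by-1-per-MCS rule without touching the grid every MCS.

Scalar bookkeeping lives in an int64 array ``scalars``; see the SC_* indices.
All randomness comes from a self-contained xorshift128+ state per simulation.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# scalars[] indices
SC_B = 0  # ordered unlike Moore pairs
SC_T = 1  # current MCS
SC_DONE = 2  # attempts already consumed within the current MCS
SC_EXPLORED = 3  # pixels ever occupied by the tracked cell
SC_ANNIHILATED = 4  # id of the most recently annihilated cell, -1 if none
SC_NBORDER = 5  # number of pixels with mismatch > 0

GAIN_NEVER = np.int64(-(1 << 40))

_DX = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
_DY = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)

_U64 = np.uint64
_DBL = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True)
def seed_rng_state(seed, rng_state):
    """Initialise an xorshift128+ state from an integer seed (splitmix64)."""
    z = _U64(seed) + _U64(0x9E3779B97F4A7C15)
    for i in range(2):
        z = z + _U64(0x9E3779B97F4A7C15)
        x = z
        x = (x ^ (x >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> _U64(27))) * _U64(0x94D049BB133111EB)
        x = x ^ (x >> _U64(31))
        rng_state[i] = x
    if rng_state[0] == _U64(0) and rng_state[1] == _U64(0):
        rng_state[0] = _U64(1)


@njit(inline="always")
def _next64(s):
    x = s[0]
    y = s[1]
    s[0] = y
    x ^= x << _U64(23)
    x ^= x >> _U64(17)
    x ^= y ^ (y >> _U64(26))
    s[1] = x
    return x + y


@njit(inline="always")
def _rand(s):
    """Uniform double in [0, 1)."""
    return float(_next64(s) >> _U64(11)) * _DBL


@njit(inline="always")
def _randint(s, n):
    k = int(_rand(s) * n)
    if k >= n:
        k = n - 1
    return k


@njit(inline="always")
def _wrap(a, n):
    if a < 0:
        return a + n
    if a >= n:
        return a - n
    return a


@njit(cache=True)
def build_geometry(ids, mismatch, border_list, border_pos, scalars, volumes, perims):
    """Recompute volumes, perimeters, mismatch counts and the border list."""
    w, h = ids.shape
    volumes[:] = 0
    perims[:] = 0
    b_total = 0
    nb = 0
    for x in range(w):
        for y in range(h):
            cid = ids[x, y]
            if cid > 0:
                volumes[cid] += 1
            m = 0
            for d in range(8):
                nx = _wrap(x + _DX[d], w)
                ny = _wrap(y + _DY[d], h)
                if ids[nx, ny] != cid:
                    m += 1
            mismatch[x, y] = m
            if cid > 0:
                perims[cid] += m
            b_total += m
            if m > 0:
                border_list[nb] = x * h + y
                border_pos[x, y] = nb
                nb += 1
            else:
                border_pos[x, y] = -1
    scalars[SC_B] = b_total
    scalars[SC_NBORDER] = nb


@njit(inline="always")
def _activity(gain, max_act, t, x, y):
    a = max_act - (t - gain[x, y])
    return a if a > 0.0 else 0.0


@njit(cache=True)
def gm_act_kernel(ids, gain, cell_kind, max_act_of_kind, t, x, y):
    """Geometric mean of activity over the pixel and same-cell Moore pixels."""
    w, h = ids.shape
    cid = ids[x, y]
    if cid == 0:
        return 0.0
    ma = max_act_of_kind[cell_kind[cid]]
    if ma <= 0.0:
        return 0.0
    a = _activity(gain, ma, t, x, y)
    if a <= 0.0:
        return 0.0
    prod = a
    n = 1
    for d in range(8):
        nx = _wrap(x + _DX[d], w)
        ny = _wrap(y + _DY[d], h)
        if ids[nx, ny] == cid:
            a = _activity(gain, ma, t, nx, ny)
            if a <= 0.0:
                return 0.0
            prod *= a
            n += 1
    return prod ** (1.0 / n)


@njit(cache=True)
def delta_h_kernel(
    ids,
    gain,
    cell_kind,
    volumes,
    perims,
    v_star,
    lam_v,
    p_star,
    lam_p,
    adhesion,
    lam_act,
    max_act,
    t,
    sx,
    sy,
    tx,
    ty,
):
    """Full copy-attempt energy change: adhesion + volume + perimeter + Act."""
    w, h = ids.shape
    new_id = ids[sx, sy]
    old_id = ids[tx, ty]
    kn = cell_kind[new_id]
    ko = cell_kind[old_id]
    dh = 0.0
    n_new = 0
    n_old = 0
    for d in range(8):
        nx = _wrap(tx + _DX[d], w)
        ny = _wrap(ty + _DY[d], h)
        rid = ids[nx, ny]
        kr = cell_kind[rid]
        if rid != new_id:
            dh += adhesion[kn, kr]
        else:
            n_new += 1
        if rid != old_id:
            dh -= adhesion[ko, kr]
        else:
            n_old += 1
    if new_id > 0:
        v = float(volumes[new_id])
        vs = v_star[kn]
        dh += lam_v[kn] * ((v + 1 - vs) ** 2 - (v - vs) ** 2)
        p = float(perims[new_id])
        ps = p_star[kn]
        dp = 8.0 - 2.0 * n_new
        dh += lam_p[kn] * ((p + dp - ps) ** 2 - (p - ps) ** 2)
    if old_id > 0:
        v = float(volumes[old_id])
        vs = v_star[ko]
        dh += lam_v[ko] * ((v - 1 - vs) ** 2 - (v - vs) ** 2)
        p = float(perims[old_id])
        ps = p_star[ko]
        dp = 2.0 * n_old - 8.0
        dh += lam_p[ko] * ((p + dp - ps) ** 2 - (p - ps) ** 2)
    # Act feedback, per cell kind: -(lam/max) GM(s) + (lam/max) GM(t)
    if max_act[kn] > 0.0 and lam_act[kn] > 0.0:
        gm_s = gm_act_kernel(ids, gain, cell_kind, max_act, t, sx, sy)
        dh -= lam_act[kn] / max_act[kn] * gm_s
    if max_act[ko] > 0.0 and lam_act[ko] > 0.0:
        gm_t = gm_act_kernel(ids, gain, cell_kind, max_act, t, tx, ty)
        dh += lam_act[ko] / max_act[ko] * gm_t
    return dh


@njit(inline="always")
def _refresh_pixel(ids, mismatch, border_list, border_pos, scalars, x, y):
    w, h = ids.shape
    cid = ids[x, y]
    m = 0
    for d in range(8):
        nx = _wrap(x + _DX[d], w)
        ny = _wrap(y + _DY[d], h)
        if ids[nx, ny] != cid:
            m += 1
    old = mismatch[x, y]
    if m != old:
        scalars[SC_B] += m - old
        mismatch[x, y] = m
    pos = border_pos[x, y]
    if m > 0 and pos < 0:
        nb = scalars[SC_NBORDER]
        border_list[nb] = x * h + y
        border_pos[x, y] = nb
        scalars[SC_NBORDER] = nb + 1
    elif m == 0 and pos >= 0:
        nb = scalars[SC_NBORDER] - 1
        last = border_list[nb]
        border_list[pos] = last
        border_pos[last // h, last % h] = pos
        border_pos[x, y] = -1
        scalars[SC_NBORDER] = nb


@njit(cache=True)
def apply_copy_kernel(
    ids,
    gain,
    mismatch,
    border_list,
    border_pos,
    scalars,
    volumes,
    perims,
    cell_kind,
    max_act,
    tx,
    ty,
    new_id,
    explored,
    explored_cell,
):
    w, h = ids.shape
    old_id = ids[tx, ty]
    n_new = 0
    n_old = 0
    for d in range(8):
        nx = _wrap(tx + _DX[d], w)
        ny = _wrap(ty + _DY[d], h)
        rid = ids[nx, ny]
        if rid == new_id:
            n_new += 1
        if rid == old_id:
            n_old += 1
    if new_id > 0:
        volumes[new_id] += 1
        perims[new_id] += 8 - 2 * n_new
    if old_id > 0:
        volumes[old_id] -= 1
        perims[old_id] += 2 * n_old - 8
    ids[tx, ty] = new_id
    if new_id > 0 and max_act[cell_kind[new_id]] > 0.0:
        gain[tx, ty] = scalars[SC_T]
    else:
        gain[tx, ty] = GAIN_NEVER
    _refresh_pixel(ids, mismatch, border_list, border_pos, scalars, tx, ty)
    for d in range(8):
        nx = _wrap(tx + _DX[d], w)
        ny = _wrap(ty + _DY[d], h)
        _refresh_pixel(ids, mismatch, border_list, border_pos, scalars, nx, ny)
    if new_id == explored_cell and explored[tx, ty] == 0:
        explored[tx, ty] = 1
        scalars[SC_EXPLORED] += 1
    if old_id > 0 and volumes[old_id] == 0:
        scalars[SC_ANNIHILATED] = old_id


@njit(cache=True)
def advance_kernel(
    ids,
    gain,
    mismatch,
    border_list,
    border_pos,
    scalars,
    volumes,
    perims,
    cell_kind,
    v_star,
    lam_v,
    p_star,
    lam_p,
    adhesion,
    lam_act,
    max_act,
    temperature,
    n_mcs,
    explored,
    explored_cell,
    rng_state,
):
    """Advance the state by ``n_mcs`` Monte Carlo steps."""
    w, h = ids.shape
    n_pix = w * h
    mcs_done = 0
    done = scalars[SC_DONE]
    while mcs_done < n_mcs:
        b_total = scalars[SC_B]
        if b_total <= 0:
            scalars[SC_T] += n_mcs - mcs_done
            done = 0
            break
        p = b_total / (8.0 * n_pix)
        u = _rand(rng_state)
        if u <= 0.0:
            u = _DBL
        if p >= 1.0:
            step = 1
        else:
            step = 1 + int(np.log(u) / np.log(1.0 - p))
        ended = False
        while done + step > n_pix:
            step -= n_pix - done
            done = 0
            scalars[SC_T] += 1
            mcs_done += 1
            if mcs_done == n_mcs:
                ended = True
                break
        if ended:
            break
        done += step
        # the id-mismatched attempt: uniform over ordered unlike pairs
        t = scalars[SC_T]
        while True:
            k = _randint(rng_state, scalars[SC_NBORDER])
            code = border_list[k]
            sx = code // h
            sy = code % h
            d = _randint(rng_state, 8)
            tx = _wrap(sx + _DX[d], w)
            ty = _wrap(sy + _DY[d], h)
            if ids[tx, ty] != ids[sx, sy]:
                break
        dh = delta_h_kernel(
            ids, gain, cell_kind, volumes, perims,
            v_star, lam_v, p_star, lam_p, adhesion, lam_act, max_act,
            t, sx, sy, tx, ty,
        )
        accept = dh <= 0.0
        if not accept:
            accept = _rand(rng_state) < np.exp(-dh / temperature)
        if accept:
            apply_copy_kernel(
                ids, gain, mismatch, border_list, border_pos, scalars,
                volumes, perims, cell_kind, max_act,
                tx, ty, ids[sx, sy], explored, explored_cell,
            )
        if done == n_pix:
            done = 0
            scalars[SC_T] += 1
            mcs_done += 1
    scalars[SC_DONE] = done


@njit(cache=True)
def connectedness_kernel(ids, cid, labels, stack):
    """Connectedness C = sum_k (n_k / N)^2 over Moore components on the torus.

    ``labels`` is an int32 scratch grid, ``stack`` an int64 scratch vector of
    at least grid-size length. Returns -1.0 for an absent cell.
    """
    w, h = ids.shape
    labels[:, :] = 0
    total = 0
    sum_sq = 0.0
    label = 0
    for x0 in range(w):
        for y0 in range(h):
            if ids[x0, y0] != cid or labels[x0, y0] != 0:
                continue
            label += 1
            size = 0
            top = 0
            stack[top] = x0 * h + y0
            labels[x0, y0] = label
            top += 1
            while top > 0:
                top -= 1
                code = stack[top]
                x = code // h
                y = code % h
                size += 1
                for d in range(8):
                    nx = _wrap(x + _DX[d], w)
                    ny = _wrap(y + _DY[d], h)
                    if ids[nx, ny] == cid and labels[nx, ny] == 0:
                        labels[nx, ny] = label
                        stack[top] = nx * h + ny
                        top += 1
            total += size
            sum_sq += float(size) * float(size)
    if total == 0:
        return -1.0
    return sum_sq / (float(total) * float(total))


@njit(cache=True)
def centroid_kernel(ids, cid, ref_x, ref_y):
    """Centroid of a cell relative to a reference point (minimal image).

    Returns ``(dx, dy, n)``: the mean displacement of the cell's pixels from
    ``(ref_x, ref_y)`` with each pixel mapped to its nearest periodic image,
    and the pixel count. Valid while the cell's diameter is below half the
    grid size.
    """
    w, h = ids.shape
    sx = 0.0
    sy = 0.0
    n = 0
    for x in range(w):
        for y in range(h):
            if ids[x, y] == cid:
                dx = x - ref_x
                dx -= w * np.round(dx / w)
                dy = y - ref_y
                dy -= h * np.round(dy / h)
                sx += dx
                sy += dy
                n += 1
    if n == 0:
        return 0.0, 0.0, 0
    return sx / n, sy / n, n
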