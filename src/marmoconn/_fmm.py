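"""Numba kernels: first-order upwind Fast Marching and geodesic backtracing.

The Eikonal equation |grad T| = 1/speed is solved on a regular grid with
(possibly anisotropic) voxel spacing.  T is the first-arrival time of a
front expanding from the seed; voxels with speed 0 (outside the brain) are
never accepted and keep T = +inf.  Geodesics are extracted by fixed-step
gradient descent on a trilinear interpolation of T, with a discrete
fall-back move when the continuous descent stalls in a local plateau.
"""

from __future__ import annotations

import numpy as np
from numba import njit

FAR, TRIAL, KNOWN = np.uint8(0), np.uint8(1), np.uint8(2)


@njit(cache=True)
def _heap_push(heap_t, heap_i, size, t, idx):
    i = size
    heap_t[i] = t
    heap_i[i] = idx
    while i > 0:
        parent = (i - 1) // 2
        if heap_t[parent] <= heap_t[i]:
            break
        heap_t[parent], heap_t[i] = heap_t[i], heap_t[parent]
        heap_i[parent], heap_i[i] = heap_i[i], heap_i[parent]
        i = parent
    return size + 1


@njit(cache=True)
def _heap_pop(heap_t, heap_i, size):
    t = heap_t[0]
    idx = heap_i[0]
    size -= 1
    heap_t[0] = heap_t[size]
    heap_i[0] = heap_i[size]
    i = 0
    while True:
        left = 2 * i + 1
        right = left + 1
        smallest = i
        if left < size and heap_t[left] < heap_t[smallest]:
            smallest = left
        if right < size and heap_t[right] < heap_t[smallest]:
            smallest = right
        if smallest == i:
            break
        heap_t[smallest], heap_t[i] = heap_t[i], heap_t[smallest]
        heap_i[smallest], heap_i[i] = heap_i[i], heap_i[smallest]
        i = smallest
    return t, idx, size


@njit(cache=True)
def _update_time(t0, h0, t1, h1, t2, h2, inv_speed):
    """Solve the upwind quadratic sum_a ((T - t_a)/h_a)^2 = inv_speed^2.

    t_a are the smaller accepted neighbor times along each axis (inf when
    no accepted neighbor exists); the largest consistent subset of axes is
    used, per the standard first-order scheme.
    """
    # sort the three (t, h) pairs by t ascending
    ts = np.empty(3)
    hs = np.empty(3)
    ts[0], ts[1], ts[2] = t0, t1, t2
    hs[0], hs[1], hs[2] = h0, h1, h2
    for i in range(1, 3):
        tv = ts[i]
        hv = hs[i]
        j = i - 1
        while j >= 0 and ts[j] > tv:
            ts[j + 1] = ts[j]
            hs[j + 1] = hs[j]
            j -= 1
        ts[j + 1] = tv
        hs[j + 1] = hv
    if not np.isfinite(ts[0]):
        return np.inf
    # try m = 3, 2, 1 axes
    for m in range(3, 0, -1):
        if not np.isfinite(ts[m - 1]):
            continue
        a = 0.0
        b = 0.0
        c = -inv_speed * inv_speed
        for k in range(m):
            w = 1.0 / (hs[k] * hs[k])
            a += w
            b -= 2.0 * w * ts[k]
            c += w * ts[k] * ts[k]
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            continue
        t = (-b + np.sqrt(disc)) / (2.0 * a)
        if t >= ts[m - 1]:
            return t
    return ts[0] + inv_speed * hs[0]


@njit(cache=True)
def fast_march(speed, h0, h1, h2, s0, s1, s2, r_init_vox=3.0):
    """Arrival-time grid from an exact seed point (s0, s1, s2) in mm
    relative to the grid origin (voxel (0,0,0) center at 0).

    Near-source accuracy: voxels within ``r_init_vox`` voxel diagonals of
    the seed that share the seed voxel's speed are initialized with their
    exact straight-ray time, removing both the sub-voxel seed offset and
    the large front-curvature error of the first-order scheme close to a
    point source.
    """
    n0, n1, n2 = speed.shape
    n = n0 * n1 * n2
    T = np.full(n, np.inf)
    state = np.zeros(n, dtype=np.uint8)
    heap_t = np.empty(4 * n)
    heap_i = np.empty(4 * n, dtype=np.int64)
    size = 0

    si = int(min(max(round(s0 / h0), 0), n0 - 1))
    sj = int(min(max(round(s1 / h1), 0), n1 - 1))
    sk = int(min(max(round(s2 / h2), 0), n2 - 1))
    sp_seed = speed[si, sj, sk]
    if sp_seed <= 0.0:
        return T.reshape(n0, n1, n2)
    inv_seed = 1.0 / sp_seed
    hmin = min(h0, min(h1, h2))
    r_mm = r_init_vox * np.sqrt(h0 * h0 + h1 * h1 + h2 * h2)
    ri = int(r_mm / h0) + 1
    rj = int(r_mm / h1) + 1
    rk = int(r_mm / h2) + 1
    for i in range(max(0, si - ri), min(n0, si + ri + 1)):
        for j in range(max(0, sj - rj), min(n1, sj + rj + 1)):
            for k in range(max(0, sk - rk), min(n2, sk + rk + 1)):
                if speed[i, j, k] != sp_seed:
                    continue
                d0 = i * h0 - s0
                d1 = j * h1 - s1
                d2 = k * h2 - s2
                dist = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
                if dist > r_mm:
                    continue
                flat = (i * n1 + j) * n2 + k
                T[flat] = dist * inv_seed
                size = _heap_push(heap_t, heap_i, size, T[flat], flat)
                state[flat] = TRIAL

    while size > 0:
        t, flat, size = _heap_pop(heap_t, heap_i, size)
        if state[flat] == KNOWN:
            continue  # lazy-deleted duplicate
        state[flat] = KNOWN
        i = flat // (n1 * n2)
        j = (flat // n2) % n1
        k = flat % n2
        # relax the 6 face neighbors
        for d in range(6):
            ni, nj, nk = i, j, k
            if d == 0:
                ni -= 1
            elif d == 1:
                ni += 1
            elif d == 2:
                nj -= 1
            elif d == 3:
                nj += 1
            elif d == 4:
                nk -= 1
            else:
                nk += 1
            if ni < 0 or ni >= n0 or nj < 0 or nj >= n1 or nk < 0 or nk >= n2:
                continue
            sp = speed[ni, nj, nk]
            if sp <= 0.0:
                continue
            nflat = (ni * n1 + nj) * n2 + nk
            if state[nflat] == KNOWN:
                continue
            # upwind neighbor times along each axis (accepted voxels only)
            ta = np.inf
            if ni > 0:
                f = ((ni - 1) * n1 + nj) * n2 + nk
                if state[f] == KNOWN:
                    ta = T[f]
            if ni < n0 - 1:
                f = ((ni + 1) * n1 + nj) * n2 + nk
                if state[f] == KNOWN and T[f] < ta:
                    ta = T[f]
            tb = np.inf
            if nj > 0:
                f = (ni * n1 + (nj - 1)) * n2 + nk
                if state[f] == KNOWN:
                    tb = T[f]
            if nj < n1 - 1:
                f = (ni * n1 + (nj + 1)) * n2 + nk
                if state[f] == KNOWN and T[f] < tb:
                    tb = T[f]
            tc = np.inf
            if nk > 0:
                f = (ni * n1 + nj) * n2 + (nk - 1)
                if state[f] == KNOWN:
                    tc = T[f]
            if nk < n2 - 1:
                f = (ni * n1 + nj) * n2 + (nk + 1)
                if state[f] == KNOWN and T[f] < tc:
                    tc = T[f]
            tnew = _update_time(ta, h0, tb, h1, tc, h2, 1.0 / sp)
            if tnew < T[nflat]:
                T[nflat] = tnew
                size = _heap_push(heap_t, heap_i, size, tnew, nflat)
                state[nflat] = TRIAL
    return T.reshape(n0, n1, n2)


@njit(cache=True, inline="always")
def _clamp(x, lo, hi):
    if x < lo:
        return lo
    if x > hi:
        return hi
    return x


@njit(cache=True)
def _interp_T(T, big, u0, u1, u2):
    """Trilinear interpolation of T at continuous voxel coords, inf -> big."""
    n0, n1, n2 = T.shape
    u0 = _clamp(u0, 0.0, n0 - 1.000001)
    u1 = _clamp(u1, 0.0, n1 - 1.000001)
    u2 = _clamp(u2, 0.0, n2 - 1.000001)
    i0 = int(u0)
    i1 = int(u1)
    i2 = int(u2)
    f0 = u0 - i0
    f1 = u1 - i1
    f2 = u2 - i2
    acc = 0.0
    for a in range(2):
        wa = f0 if a == 1 else 1.0 - f0
        for b in range(2):
            wb = f1 if b == 1 else 1.0 - f1
            for c in range(2):
                wc = f2 if c == 1 else 1.0 - f2
                v = T[i0 + a, i1 + b, i2 + c]
                if not np.isfinite(v):
                    v = big
                acc += wa * wb * wc * v
    return acc


@njit(cache=True)
def _finite_ceiling(T):
    """2 * max finite T + 1, used to replace +inf during interpolation."""
    big = 0.0
    flat = T.ravel()
    for i in range(flat.size):
        v = flat[i]
        if np.isfinite(v) and v > big:
            big = v
    return 2.0 * big + 1.0


@njit(cache=True)
def _trace_core(T, big, h0, h1, h2, o0, o1, o2,
                start0, start1, start2, seed0, seed1, seed2,
                step_frac, stop_radius, max_steps):
    """Backtrace a geodesic from a start point (mm) to the seed of T.

    Fixed-step steepest descent on trilinearly interpolated T; steps are
    step_frac * min(voxel size).  When the continuous descent stalls the
    walker jumps to the lowest-T voxel among the 26 neighbors of its
    current voxel.  Returns (arclength_mm, ok_flag).
    """
    n0, n1, n2 = T.shape
    hmin = min(h0, min(h1, h2))
    step = step_frac * hmin

    p0, p1, p2 = start0, start1, start2
    u0 = (p0 - o0) / h0
    u1 = (p1 - o1) / h1
    u2 = (p2 - o2) / h2
    if not np.isfinite(_interp_T(T, big * 10.0, u0, u1, u2)):
        return -1.0, False

    length = 0.0
    best_t = _interp_T(T, big, u0, u1, u2)
    stall = 0
    for _ in range(max_steps):
        d0 = p0 - seed0
        d1 = p1 - seed1
        d2 = p2 - seed2
        dist_seed = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        if dist_seed <= stop_radius:
            return length + dist_seed, True
        u0 = (p0 - o0) / h0
        u1 = (p1 - o1) / h1
        u2 = (p2 - o2) / h2
        # central-difference gradient of the interpolated field (mm units)
        e0 = 0.5 * h0
        e1 = 0.5 * h1
        e2 = 0.5 * h2
        g0 = (_interp_T(T, big, u0 + 0.5, u1, u2) - _interp_T(T, big, u0 - 0.5, u1, u2)) / (2 * e0)
        g1 = (_interp_T(T, big, u0, u1 + 0.5, u2) - _interp_T(T, big, u0, u1 - 0.5, u2)) / (2 * e1)
        g2 = (_interp_T(T, big, u0, u1, u2 + 0.5) - _interp_T(T, big, u0, u1, u2 - 0.5)) / (2 * e2)
        gn = np.sqrt(g0 * g0 + g1 * g1 + g2 * g2)
        moved = False
        if gn > 1e-12:
            q0 = p0 - step * g0 / gn
            q1 = p1 - step * g1 / gn
            q2 = p2 - step * g2 / gn
            v0 = (q0 - o0) / h0
            v1 = (q1 - o1) / h1
            v2 = (q2 - o2) / h2
            tq = _interp_T(T, big, v0, v1, v2)
            if tq < best_t - 1e-12:
                p0, p1, p2 = q0, q1, q2
                length += step
                best_t = tq
                stall = 0
                moved = True
        if not moved:
            stall += 1
            # discrete fall-back: hop to the lowest-T 26-neighbor voxel center
            ci = int(_clamp(np.rint(u0), 0, n0 - 1))
            cj = int(_clamp(np.rint(u1), 0, n1 - 1))
            ck = int(_clamp(np.rint(u2), 0, n2 - 1))
            bt = T[ci, cj, ck] if np.isfinite(T[ci, cj, ck]) else big
            bi, bj, bk = ci, cj, ck
            for a in range(-1, 2):
                for b in range(-1, 2):
                    for c in range(-1, 2):
                        ii = ci + a
                        jj = cj + b
                        kk = ck + c
                        if ii < 0 or ii >= n0 or jj < 0 or jj >= n1 or kk < 0 or kk >= n2:
                            continue
                        v = T[ii, jj, kk]
                        if np.isfinite(v) and v < bt:
                            bt = v
                            bi, bj, bk = ii, jj, kk
            if bi == ci and bj == cj and bk == ck:
                # true local minimum away from the seed: give up gracefully
                return length + dist_seed, False
            q0 = o0 + bi * h0
            q1 = o1 + bj * h1
            q2 = o2 + bk * h2
            dd0 = q0 - p0
            dd1 = q1 - p1
            dd2 = q2 - p2
            length += np.sqrt(dd0 * dd0 + dd1 * dd1 + dd2 * dd2)
            p0, p1, p2 = q0, q1, q2
            best_t = bt
            if stall > 200:
                return length + np.sqrt((p0 - seed0) ** 2 + (p1 - seed1) ** 2
                                        + (p2 - seed2) ** 2), False
    return length, False


@njit(cache=True)
def trace_geodesic(T, h0, h1, h2, o0, o1, o2,
                   start0, start1, start2, seed0, seed1, seed2,
                   step_frac, stop_radius, max_steps):
    big = _finite_ceiling(T)
    return _trace_core(T, big, h0, h1, h2, o0, o1, o2,
                       start0, start1, start2, seed0, seed1, seed2,
                       step_frac, stop_radius, max_steps)


@njit(cache=True)
def trace_many(T, h0, h1, h2, o0, o1, o2, starts, seed0, seed1, seed2,
               step_frac, stop_radius, max_steps):
    """Vector of geodesic lengths from many start points to the seed of T."""
    big = _finite_ceiling(T)
    m = starts.shape[0]
    out = np.empty(m)
    ok = np.empty(m, dtype=np.bool_)
    for i in range(m):
        L, good = _trace_core(T, big, h0, h1, h2, o0, o1, o2,
                              starts[i, 0], starts[i, 1], starts[i, 2],
                              seed0, seed1, seed2,
                              step_frac, stop_radius, max_steps)
        out[i] = L
        ok[i] = good
    return out, ok


@njit(cache=True)
def trace_polyline(T, h0, h1, h2, o0, o1, o2,
                   start0, start1, start2, seed0, seed1, seed2,
                   step_frac, stop_radius, max_steps):
    """Like trace_geodesic but also returns the path vertices (mm)."""
    # duplicated walk recording positions; used for QC / visualization only
    n0, n1, n2 = T.shape
    hmin = min(h0, min(h1, h2))
    step = step_frac * hmin
    big = _finite_ceiling(T)
    pts = np.empty((max_steps + 2, 3))
    npts = 0
    p0, p1, p2 = start0, start1, start2
    pts[npts, 0] = p0
    pts[npts, 1] = p1
    pts[npts, 2] = p2
    npts += 1
    best_t = _interp_T(T, big, (p0 - o0) / h0, (p1 - o1) / h1, (p2 - o2) / h2)
    length = 0.0
    for _ in range(max_steps):
        d0 = p0 - seed0
        d1 = p1 - seed1
        d2 = p2 - seed2
        dist_seed = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        if dist_seed <= stop_radius:
            pts[npts, 0] = seed0
            pts[npts, 1] = seed1
            pts[npts, 2] = seed2
            npts += 1
            return pts[:npts].copy(), length + dist_seed, True
        u0 = (p0 - o0) / h0
        u1 = (p1 - o1) / h1
        u2 = (p2 - o2) / h2
        g0 = (_interp_T(T, big, u0 + 0.5, u1, u2) - _interp_T(T, big, u0 - 0.5, u1, u2)) / h0
        g1 = (_interp_T(T, big, u0, u1 + 0.5, u2) - _interp_T(T, big, u0, u1 - 0.5, u2)) / h1
        g2 = (_interp_T(T, big, u0, u1, u2 + 0.5) - _interp_T(T, big, u0, u1, u2 - 0.5)) / h2
        gn = np.sqrt(g0 * g0 + g1 * g1 + g2 * g2)
        moved = False
        if gn > 1e-12:
            q0 = p0 - step * g0 / gn
            q1 = p1 - step * g1 / gn
            q2 = p2 - step * g2 / gn
            tq = _interp_T(T, big, (q0 - o0) / h0, (q1 - o1) / h1, (q2 - o2) / h2)
            if tq < best_t - 1e-12:
                p0, p1, p2 = q0, q1, q2
                best_t = tq
                length += step
                moved = True
        if not moved:
            ci = int(_clamp(np.rint(u0), 0, n0 - 1))
            cj = int(_clamp(np.rint(u1), 0, n1 - 1))
            ck = int(_clamp(np.rint(u2), 0, n2 - 1))
            bt = T[ci, cj, ck] if np.isfinite(T[ci, cj, ck]) else big
            bi, bj, bk = ci, cj, ck
            for a in range(-1, 2):
                for b in range(-1, 2):
                    for c in range(-1, 2):
                        ii = ci + a
                        jj = cj + b
                        kk = ck + c
                        if ii < 0 or ii >= n0 or jj < 0 or jj >= n1 or kk < 0 or kk >= n2:
                            continue
                        v = T[ii, jj, kk]
                        if np.isfinite(v) and v < bt:
                            bt = v
                            bi, bj, bk = ii, jj, kk
                    # fall through
            if bi == ci and bj == cj and bk == ck:
                return pts[:npts].copy(), length + dist_seed, False
            q0 = o0 + bi * h0
            q1 = o1 + bj * h1
            q2 = o2 + bk * h2
            length += np.sqrt((q0 - p0) ** 2 + (q1 - p1) ** 2 + (q2 - p2) ** 2)
            p0, p1, p2 = q0, q1, q2
            best_t = bt
        pts[npts, 0] = p0
        pts[npts, 1] = p1
        pts[npts, 2] = p2
        npts += 1
    return pts[:npts].copy(), length, False
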