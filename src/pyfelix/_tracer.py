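"""Numba kernels for geodesic ray tracing through the four orientation charts.

A geodesic (the set of rotations mapping a reflection direction h-hat onto
an observed direction g-hat) is a straight line in Rodrigues-Frank space,
i.e. the central projection of a great circle of the unit-quaternion sphere
spanned by the orthonormal pair

    u = (1, r_min) / sqrt(1 + |r_min|^2),    v = (0, d-hat),

with r_min = (h x g)/|h x g| * tan(theta_hg / 2) and d-hat || h + g.
In chart k (divide the quaternion by its k-th component) the circle maps to
the straight line p0 + s*d with

    p0 = (u_k u + v_k v) / (u_k^2 + v_k^2),    d = v_k u - u_k v,

restricted to the cube [-1, 1]^3 (exactly where component k dominates).
Each chart segment is rasterized with exact cell-boundary stepping
(Amanatides-Woo 3D DDA), so every voxel the line crosses is incremented
exactly once per geodesic.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _trace_segment(p0, p1, p2, d0, d1, d2, grid):
    """DDA over one chart; returns the number of voxels incremented."""
    n = grid.shape[0]
    s0 = -1e30
    s1 = 1e30
    # Liang-Barsky clip of p + s*d against [-1, 1]^3
    for a in range(3):
        if a == 0:
            pa, da = p0, d0
        elif a == 1:
            pa, da = p1, d1
        else:
            pa, da = p2, d2
        if -1e-15 < da < 1e-15:
            if pa < -1.0 or pa > 1.0:
                return 0
        else:
            t1 = (-1.0 - pa) / da
            t2 = (1.0 - pa) / da
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > s0:
                s0 = t1
            if t2 < s1:
                s1 = t2
    if s1 <= s0:
        return 0
    eps = 1e-12 * (abs(s0) + abs(s1) + 1.0)
    s0 += eps
    s1 -= eps
    if s1 <= s0:
        return 0
    h = 2.0 / n

    x0 = p0 + s0 * d0
    x1 = p1 + s0 * d1
    x2 = p2 + s0 * d2
    i0 = int((x0 + 1.0) / h)
    i1 = int((x1 + 1.0) / h)
    i2 = int((x2 + 1.0) / h)
    if i0 < 0:
        i0 = 0
    elif i0 > n - 1:
        i0 = n - 1
    if i1 < 0:
        i1 = 0
    elif i1 > n - 1:
        i1 = n - 1
    if i2 < 0:
        i2 = 0
    elif i2 > n - 1:
        i2 = n - 1

    if d0 > 1e-15:
        st0 = 1
        tm0 = (((i0 + 1) * h - 1.0) - p0) / d0
        td0 = h / d0
    elif d0 < -1e-15:
        st0 = -1
        tm0 = ((i0 * h - 1.0) - p0) / d0
        td0 = -h / d0
    else:
        st0 = 0
        tm0 = 1e30
        td0 = 1e30
    if d1 > 1e-15:
        st1 = 1
        tm1 = (((i1 + 1) * h - 1.0) - p1) / d1
        td1 = h / d1
    elif d1 < -1e-15:
        st1 = -1
        tm1 = ((i1 * h - 1.0) - p1) / d1
        td1 = -h / d1
    else:
        st1 = 0
        tm1 = 1e30
        td1 = 1e30
    if d2 > 1e-15:
        st2 = 1
        tm2 = (((i2 + 1) * h - 1.0) - p2) / d2
        td2 = h / d2
    elif d2 < -1e-15:
        st2 = -1
        tm2 = ((i2 * h - 1.0) - p2) / d2
        td2 = -h / d2
    else:
        st2 = 0
        tm2 = 1e30
        td2 = 1e30

    visits = 0
    while True:
        grid[i0, i1, i2] += 1
        visits += 1
        if tm0 <= tm1 and tm0 <= tm2:
            if tm0 > s1:
                break
            i0 += st0
            if i0 < 0 or i0 >= n:
                break
            tm0 += td0
        elif tm1 <= tm2:
            if tm1 > s1:
                break
            i1 += st1
            if i1 < 0 or i1 >= n:
                break
            tm1 += td1
        else:
            if tm2 > s1:
                break
            i2 += st2
            if i2 < 0 or i2 >= n:
                break
            tm2 += td2
    return visits


@njit(cache=True, fastmath=True)
def _trace_plane(u0, u1, u2, u3, v0, v1, v2, v3, counts):
    """Trace one quaternion great circle through all four charts."""
    total = 0
    for k in range(4):
        if k == 0:
            uk, vk = u0, v0
            a0, a1, a2 = u1, u2, u3
            b0, b1, b2 = v1, v2, v3
        elif k == 1:
            uk, vk = u1, v1
            a0, a1, a2 = u0, u2, u3
            b0, b1, b2 = v0, v2, v3
        elif k == 2:
            uk, vk = u2, v2
            a0, a1, a2 = u0, u1, u3
            b0, b1, b2 = v0, v1, v3
        else:
            uk, vk = u3, v3
            a0, a1, a2 = u0, u1, u2
            b0, b1, b2 = v0, v1, v2
        den = uk * uk + vk * vk
        if den < 1e-30:
            continue
        p0 = (uk * a0 + vk * b0) / den
        p1 = (uk * a1 + vk * b1) / den
        p2 = (uk * a2 + vk * b2) / den
        d0 = vk * a0 - uk * b0
        d1 = vk * a1 - uk * b1
        d2 = vk * a2 - uk * b2
        total += _trace_segment(p0, p1, p2, d0, d1, d2, counts[k])
    return total


@njit(cache=True)
def trace_plane_single(u, v, counts):
    """Entry point for tracing one geodesic given its (u, v) plane basis."""
    return _trace_plane(u[0], u[1], u[2], u[3],
                        v[0], v[1], v[2], v[3], counts)


@njit(cache=True, fastmath=True)
def trace_pairs(ghat, hhat, counts, visits):
    """Trace one geodesic per (g-hat, h-hat) row pair.

    Antipodal pairs (g = -h) are degenerate (no finite RF anchor) and are
    skipped with a visit count of 0.
    """
    m = ghat.shape[0]
    for i in range(m):
        gx = ghat[i, 0]
        gy = ghat[i, 1]
        gz = ghat[i, 2]
        hx = hhat[i, 0]
        hy = hhat[i, 1]
        hz = hhat[i, 2]
        c = gx * hx + gy * hy + gz * hz
        cx = hy * gz - hz * gy
        cy = hz * gx - hx * gz
        cz = hx * gy - hy * gx
        s = math.sqrt(cx * cx + cy * cy + cz * cz)
        if s < 1e-12:
            if c < 0.0:
                visits[i] = 0          # antipodal: degenerate geodesic
                continue
            r0 = 0.0
            r1 = 0.0
            r2 = 0.0
            dx, dy, dz = hx, hy, hz    # identity lies on the geodesic
        else:
            theta = math.atan2(s, c)
            t = math.tan(0.5 * theta)
            r0 = cx / s * t
            r1 = cy / s * t
            r2 = cz / s * t
            sx = hx + gx
            sy = hy + gy
            sz = hz + gz
            sn = math.sqrt(sx * sx + sy * sy + sz * sz)
            dx = sx / sn
            dy = sy / sn
            dz = sz / sn
        un = math.sqrt(1.0 + r0 * r0 + r1 * r1 + r2 * r2)
        visits[i] = _trace_plane(1.0 / un, r0 / un, r1 / un, r2 / un,
                                 0.0, dx, dy, dz, counts)
    return visits


def trace_plane_python(u: np.ndarray, v: np.ndarray, incr) -> int:
    """Pure-Python twin of :func:`trace_plane_single` for sparse storage.

    ``incr(chart, i, j, k)`` is called once per visited voxel.  Used by the
    sparse accumulator (very large grids) and as a cross-check of the
    compiled path; the chart/clip/DDA logic is the same.
    """
    total = 0
    for k in range(4):
        uk, vk = u[k], v[k]
        den = uk * uk + vk * vk
        if den < 1e-30:
            continue
        idx = [i for i in range(4) if i != k]
        p = [(uk * u[i] + vk * v[i]) / den for i in idx]
        d = [vk * u[i] - uk * v[i] for i in idx]
        total += _trace_segment_python(p, d, k, incr)
    return total


def _trace_segment_python(p, d, chart, incr) -> int:
    n = incr.n_voxels
    s0, s1 = -1e30, 1e30
    for a in range(3):
        if abs(d[a]) < 1e-15:
            if p[a] < -1.0 or p[a] > 1.0:
                return 0
        else:
            t1 = (-1.0 - p[a]) / d[a]
            t2 = (1.0 - p[a]) / d[a]
            if t1 > t2:
                t1, t2 = t2, t1
            s0 = max(s0, t1)
            s1 = min(s1, t2)
    if s1 <= s0:
        return 0
    eps = 1e-12 * (abs(s0) + abs(s1) + 1.0)
    s0 += eps
    s1 -= eps
    if s1 <= s0:
        return 0
    h = 2.0 / n
    ijk = [min(n - 1, max(0, int((p[a] + s0 * d[a] + 1.0) / h)))
           for a in range(3)]
    step, tmax, tdel = [0] * 3, [1e30] * 3, [1e30] * 3
    for a in range(3):
        if d[a] > 1e-15:
            step[a] = 1
            tmax[a] = (((ijk[a] + 1) * h - 1.0) - p[a]) / d[a]
            tdel[a] = h / d[a]
        elif d[a] < -1e-15:
            step[a] = -1
            tmax[a] = ((ijk[a] * h - 1.0) - p[a]) / d[a]
            tdel[a] = -h / d[a]
    visits = 0
    while True:
        incr(chart, ijk[0], ijk[1], ijk[2])
        visits += 1
        a = min(range(3), key=lambda i: tmax[i])
        if tmax[a] > s1:
            break
        ijk[a] += step[a]
        if ijk[a] < 0 or ijk[a] >= n:
            break
        tmax[a] += tdel[a]
    return visits
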