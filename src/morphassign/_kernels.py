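"""Numerical kernels for the shift search, JIT-compiled with numba.

The inner loop of morphing evaluates, for thousands of candidate
translations, the Pearson correlation between fixed map samples and the
local model density sampled at translated positions.  A fused numba kernel
keeps this fast; a pure-numpy fallback is used when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is a hard dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=False)
def _trilinear_one(vals, ox, oy, oz, sx, sy, sz, x, y, z):
    fx = (x - ox) / sx
    fy = (y - oy) / sy
    fz = (z - oz) / sz
    nx, ny, nz = vals.shape
    ix = int(np.floor(fx))
    iy = int(np.floor(fy))
    iz = int(np.floor(fz))
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix > nx - 2:
        ix = nx - 2
    if iy > ny - 2:
        iy = ny - 2
    if iz > nz - 2:
        iz = nz - 2
    tx = fx - ix
    ty = fy - iy
    tz = fz - iz
    if tx < 0.0:
        tx = 0.0
    if ty < 0.0:
        ty = 0.0
    if tz < 0.0:
        tz = 0.0
    if tx > 1.0:
        tx = 1.0
    if ty > 1.0:
        ty = 1.0
    if tz > 1.0:
        tz = 1.0
    c000 = vals[ix, iy, iz]
    c100 = vals[ix + 1, iy, iz]
    c010 = vals[ix, iy + 1, iz]
    c001 = vals[ix, iy, iz + 1]
    c110 = vals[ix + 1, iy + 1, iz]
    c101 = vals[ix + 1, iy, iz + 1]
    c011 = vals[ix, iy + 1, iz + 1]
    c111 = vals[ix + 1, iy + 1, iz + 1]
    return (c000 * (1 - tx) * (1 - ty) * (1 - tz)
            + c100 * tx * (1 - ty) * (1 - tz)
            + c010 * (1 - tx) * ty * (1 - tz)
            + c001 * (1 - tx) * (1 - ty) * tz
            + c110 * tx * ty * (1 - tz)
            + c101 * tx * (1 - ty) * tz
            + c011 * (1 - tx) * ty * tz
            + c111 * tx * ty * tz)


@njit(cache=True, fastmath=False)
def shift_correlations(map_vals, model_vals, origin, spacing,
                       sphere_pts, shifts):
    """Pearson correlation of ``map_vals`` with local model density sampled
    at ``sphere_pts - shift`` for every candidate shift.

    Parameters are raw arrays: ``map_vals`` (m,), ``model_vals`` a local
    density grid with its ``origin``/``spacing``, ``sphere_pts`` (m, 3) Å
    and ``shifts`` (k, 3) Å.  Returns an array (k,) of correlations (0 where
    either side has zero variance).
    """
    m = sphere_pts.shape[0]
    k = shifts.shape[0]
    out = np.zeros(k)
    a_mean = 0.0
    for i in range(m):
        a_mean += map_vals[i]
    a_mean /= m
    a_var = 0.0
    for i in range(m):
        d = map_vals[i] - a_mean
        a_var += d * d
    if a_var == 0.0:
        return out
    ox, oy, oz = origin[0], origin[1], origin[2]
    sx, sy, sz = spacing[0], spacing[1], spacing[2]
    for j in range(k):
        tx, ty, tz = shifts[j, 0], shifts[j, 1], shifts[j, 2]
        s_b = 0.0
        s_bb = 0.0
        s_ab = 0.0
        for i in range(m):
            b = _trilinear_one(model_vals, ox, oy, oz, sx, sy, sz,
                               sphere_pts[i, 0] - tx,
                               sphere_pts[i, 1] - ty,
                               sphere_pts[i, 2] - tz)
            s_b += b
            s_bb += b * b
            s_ab += (map_vals[i] - a_mean) * b
        b_var = s_bb - s_b * s_b / m
        if b_var <= 0.0:
            out[j] = 0.0
        else:
            c = s_ab / np.sqrt(a_var * b_var)
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            out[j] = c
    return out
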