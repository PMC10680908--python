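"""Numba kernels for the hot inner loops (hash encoding, B-spline evaluation).

These are pure performance implementations of the math defined in
``encoding`` and ``bspline``; the slow-path numpy code remains the reference
in the oracle tests.  Backward kernels recompute interpolation weights
instead of caching them, trading a little arithmetic for memory.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_P1 = np.uint64(2654435761)
_P2 = np.uint64(805459861)


@njit(cache=True)
def _hash3(x, y, z, res, table_size):
    if res * res * res <= table_size:
        idx = (np.uint64(x) * np.uint64(res) + np.uint64(y)) * np.uint64(res) \
            + np.uint64(z)
    else:
        idx = np.uint64(x) ^ (np.uint64(y) * _P1) ^ (np.uint64(z) * _P2)
    return np.int64(idx & np.uint64(table_size - 1))


@njit(cache=True)
def hash_encode3_fw(c, res, tables):
    M = c.shape[0]
    L, T, F = tables.shape
    out = np.zeros((M, L * F))
    for m in range(M):
        for lv in range(L):
            r = res[lv]
            scale = (r - 1) * 0.5
            ux = min(max((c[m, 0] + 1.0) * scale, 0.0), r - 1 - 1e-9)
            uy = min(max((c[m, 1] + 1.0) * scale, 0.0), r - 1 - 1e-9)
            uz = min(max((c[m, 2] + 1.0) * scale, 0.0), r - 1 - 1e-9)
            ix, iy, iz = int(ux), int(uy), int(uz)
            fx, fy, fz = ux - ix, uy - iy, uz - iz
            for a in range(2):
                wa = fx if a == 1 else 1.0 - fx
                for b in range(2):
                    wb = fy if b == 1 else 1.0 - fy
                    for d in range(2):
                        wd = fz if d == 1 else 1.0 - fz
                        w = wa * wb * wd
                        idx = _hash3(ix + a, iy + b, iz + d, r, T)
                        for ff in range(F):
                            out[m, lv * F + ff] += w * tables[lv, idx, ff]
    return out


@njit(cache=True)
def hash_encode3_bw(c, res, tables, gout, need_gc):
    M = c.shape[0]
    L, T, F = tables.shape
    gtab = np.zeros_like(tables)
    gc = np.zeros((M, 3))
    for m in range(M):
        for lv in range(L):
            r = res[lv]
            scale = (r - 1) * 0.5
            ux = min(max((c[m, 0] + 1.0) * scale, 0.0), r - 1 - 1e-9)
            uy = min(max((c[m, 1] + 1.0) * scale, 0.0), r - 1 - 1e-9)
            uz = min(max((c[m, 2] + 1.0) * scale, 0.0), r - 1 - 1e-9)
            ix, iy, iz = int(ux), int(uy), int(uz)
            fx, fy, fz = ux - ix, uy - iy, uz - iz
            for a in range(2):
                wa = fx if a == 1 else 1.0 - fx
                da = 1.0 if a == 1 else -1.0
                for b in range(2):
                    wb = fy if b == 1 else 1.0 - fy
                    db = 1.0 if b == 1 else -1.0
                    for d in range(2):
                        wd = fz if d == 1 else 1.0 - fz
                        dd = 1.0 if d == 1 else -1.0
                        w = wa * wb * wd
                        idx = _hash3(ix + a, iy + b, iz + d, r, T)
                        dot = 0.0
                        for ff in range(F):
                            g = gout[m, lv * F + ff]
                            gtab[lv, idx, ff] += w * g
                            dot += g * tables[lv, idx, ff]
                        if need_gc:
                            gc[m, 0] += scale * da * wb * wd * dot
                            gc[m, 1] += scale * wa * db * wd * dot
                            gc[m, 2] += scale * wa * wb * dd * dot
    return gtab, gc


@njit(cache=True)
def hash_encode1_fw(c, res, tables):
    M = c.shape[0]
    L, T, F = tables.shape
    out = np.zeros((M, L * F))
    for m in range(M):
        for lv in range(L):
            r = res[lv]
            u = min(max((c[m, 0] + 1.0) * (r - 1) * 0.5, 0.0), r - 1 - 1e-9)
            i0 = int(u)
            f = u - i0
            mask = np.uint64(T - 1)
            idx0 = np.int64(np.uint64(i0) & mask)
            idx1 = np.int64(np.uint64(i0 + 1) & mask)
            for ff in range(F):
                out[m, lv * F + ff] = (1.0 - f) * tables[lv, idx0, ff] \
                    + f * tables[lv, idx1, ff]
    return out


@njit(cache=True)
def hash_encode1_bw(c, res, tables, gout, need_gc):
    M = c.shape[0]
    L, T, F = tables.shape
    gtab = np.zeros_like(tables)
    gc = np.zeros((M, 1))
    for m in range(M):
        for lv in range(L):
            r = res[lv]
            scale = (r - 1) * 0.5
            u = min(max((c[m, 0] + 1.0) * scale, 0.0), r - 1 - 1e-9)
            i0 = int(u)
            f = u - i0
            mask = np.uint64(T - 1)
            idx0 = np.int64(np.uint64(i0) & mask)
            idx1 = np.int64(np.uint64(i0 + 1) & mask)
            for ff in range(F):
                g = gout[m, lv * F + ff]
                gtab[lv, idx0, ff] += (1.0 - f) * g
                gtab[lv, idx1, ff] += f * g
                if need_gc:
                    gc[m, 0] += scale * g * (tables[lv, idx1, ff]
                                             - tables[lv, idx0, ff])
    return gtab, gc


@njit(cache=True)
def _cubic_weights(f, w):
    f2 = f * f
    f3 = f2 * f
    w[0] = (1.0 - f) ** 3 / 6.0
    w[1] = (3.0 * f3 - 6.0 * f2 + 4.0) / 6.0
    w[2] = (-3.0 * f3 + 3.0 * f2 + 3.0 * f + 1.0) / 6.0
    w[3] = f3 / 6.0


@njit(cache=True)
def bspline3_fw(ctrl, query):
    n = ctrl.shape[0]
    spans = n - 3
    M = query.shape[0]
    out = np.zeros((M, 3))
    wx = np.empty(4)
    wy = np.empty(4)
    wz = np.empty(4)
    for m in range(M):
        ux = min(max(query[m, 0], 0.0), 1.0) * spans
        uy = min(max(query[m, 1], 0.0), 1.0) * spans
        uz = min(max(query[m, 2], 0.0), 1.0) * spans
        ix = min(int(ux), spans - 1)
        iy = min(int(uy), spans - 1)
        iz = min(int(uz), spans - 1)
        _cubic_weights(ux - ix, wx)
        _cubic_weights(uy - iy, wy)
        _cubic_weights(uz - iz, wz)
        for a in range(4):
            for b in range(4):
                wab = wx[a] * wy[b]
                for d in range(4):
                    w = wab * wz[d]
                    for k in range(3):
                        out[m, k] += w * ctrl[ix + a, iy + b, iz + d, k]
    return out


@njit(cache=True)
def bspline3_bw(ctrl_shape0, query, gout):
    n = ctrl_shape0
    spans = n - 3
    M = query.shape[0]
    gP = np.zeros((n, n, n, 3))
    wx = np.empty(4)
    wy = np.empty(4)
    wz = np.empty(4)
    for m in range(M):
        ux = min(max(query[m, 0], 0.0), 1.0) * spans
        uy = min(max(query[m, 1], 0.0), 1.0) * spans
        uz = min(max(query[m, 2], 0.0), 1.0) * spans
        ix = min(int(ux), spans - 1)
        iy = min(int(uy), spans - 1)
        iz = min(int(uz), spans - 1)
        _cubic_weights(ux - ix, wx)
        _cubic_weights(uy - iy, wy)
        _cubic_weights(uz - iz, wz)
        for a in range(4):
            for b in range(4):
                wab = wx[a] * wy[b]
                for d in range(4):
                    w = wab * wz[d]
                    for k in range(3):
                        gP[ix + a, iy + b, iz + d, k] += w * gout[m, k]
    return gP


@njit(cache=True)
def grid_project_fw(vol, fidx, w):
    """Line integrals from a voxel array: trilinear gather at fractional
    indices fidx (R, S, 3), weighted sum over samples with w (R, S).
    Samples outside the voxel-center domain contribute 0 (the same
    convention as scipy.ndimage.map_coordinates with constant padding)."""
    R, S = fidx.shape[0], fidx.shape[1]
    nx, ny, nz = vol.shape
    out = np.zeros(R)
    for r in range(R):
        acc = 0.0
        for s in range(S):
            x, y, z = fidx[r, s, 0], fidx[r, s, 1], fidx[r, s, 2]
            if x < 0.0 or x > nx - 1 or y < 0.0 or y > ny - 1 \
                    or z < 0.0 or z > nz - 1:
                continue
            ix = min(int(x), nx - 2)
            iy = min(int(y), ny - 2)
            iz = min(int(z), nz - 2)
            fx, fy, fz = x - ix, y - iy, z - iz
            v = 0.0
            for a in range(2):
                wa = fx if a == 1 else 1.0 - fx
                for b in range(2):
                    wb = fy if b == 1 else 1.0 - fy
                    for d in range(2):
                        wd = fz if d == 1 else 1.0 - fz
                        v += wa * wb * wd * vol[ix + a, iy + b, iz + d]
            acc += w[r, s] * v
        out[r] = acc
    return out


@njit(cache=True)
def grid_project_bw(nx, ny, nz, fidx, w, gout):
    R, S = fidx.shape[0], fidx.shape[1]
    gvol = np.zeros((nx, ny, nz))
    for r in range(R):
        g = gout[r]
        if g == 0.0:
            continue
        for s in range(S):
            x, y, z = fidx[r, s, 0], fidx[r, s, 1], fidx[r, s, 2]
            if x < 0.0 or x > nx - 1 or y < 0.0 or y > ny - 1 \
                    or z < 0.0 or z > nz - 1:
                continue
            ix = min(int(x), nx - 2)
            iy = min(int(y), ny - 2)
            iz = min(int(z), nz - 2)
            fx, fy, fz = x - ix, y - iy, z - iz
            gw = g * w[r, s]
            for a in range(2):
                wa = fx if a == 1 else 1.0 - fx
                for b in range(2):
                    wb = fy if b == 1 else 1.0 - fy
                    for d in range(2):
                        wd = fz if d == 1 else 1.0 - fz
                        gvol[ix + a, iy + b, iz + d] += gw * wa * wb * wd
    return gvol
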