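"""Multilinear (bi-/tri-linear) gather and scatter with exact adjoint pairing.

All image sampling in the package goes through these helpers so that every
pull operator (``gather``) has a scatter counterpart built from the *same*
corner weights, making ``<pull(x), y> == <x, push(y)>`` hold to rounding
error by construction.

Coordinates are in voxel units (0-based lattice indices, voxel centres).
A sample is *valid* when its coordinate lies inside ``[0, n-1]`` on every
axis; invalid samples read as 0 and are flagged so callers can exclude them.

Implementation note: corners are addressed through flattened indices with
precomputed strides — one index computation serves all 2^d corners, which
is substantially faster than repeated n-d fancy indexing at the sample
counts the slice operators use.
"""

from __future__ import annotations

from itertools import product

import numpy as np

try:  # numba accelerates the hot 2D/3D kernels; numpy path remains the reference
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["gather", "gather_with_gradient", "scatter"]


def _strides(shape: tuple[int, ...]) -> np.ndarray:
    return np.cumprod((tuple(shape[1:]) + (1,))[::-1])[::-1].astype(np.int64)


def _prep(coords: np.ndarray, shape: tuple[int, ...]):
    """Corner bookkeeping: (floor (N,d), frac (N,d), valid (N,), flat base)."""
    coords = np.asarray(coords, dtype=np.float64)
    d = coords.shape[-1]
    n = np.asarray(shape[:d], dtype=np.int64)
    valid = np.all((coords >= 0.0) & (coords <= (n - 1)), axis=-1)
    f = np.floor(coords).astype(np.int64)
    np.clip(f, 0, np.maximum(n - 2, 0), out=f)
    t = coords - f
    st = _strides(shape[:d])
    base = f @ st
    return f, t, valid, base, st


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=False)
    def _gather3_nb(vals, n0, n1, n2, pts, want_grad):
        N = pts.shape[0]
        out = np.zeros(N)
        grad = np.zeros((N, 3))
        valid = np.ones(N, dtype=np.bool_)
        for i in range(N):
            x, y, z = pts[i, 0], pts[i, 1], pts[i, 2]
            if not (0.0 <= x <= n0 - 1 and 0.0 <= y <= n1 - 1 and 0.0 <= z <= n2 - 1):
                valid[i] = False
                continue
            f0 = int(x)
            f1 = int(y)
            f2 = int(z)
            if f0 > n0 - 2:
                f0 = n0 - 2
            if f1 > n1 - 2:
                f1 = n1 - 2
            if f2 > n2 - 2:
                f2 = n2 - 2
            t0 = x - f0
            t1 = y - f1
            t2 = z - f2
            base = (f0 * n1 + f1) * n2 + f2
            v000 = vals[base]
            v001 = vals[base + 1]
            v010 = vals[base + n2]
            v011 = vals[base + n2 + 1]
            v100 = vals[base + n1 * n2]
            v101 = vals[base + n1 * n2 + 1]
            v110 = vals[base + n1 * n2 + n2]
            v111 = vals[base + n1 * n2 + n2 + 1]
            c00 = v000 * (1 - t2) + v001 * t2
            c01 = v010 * (1 - t2) + v011 * t2
            c10 = v100 * (1 - t2) + v101 * t2
            c11 = v110 * (1 - t2) + v111 * t2
            c0 = c00 * (1 - t1) + c01 * t1
            c1 = c10 * (1 - t1) + c11 * t1
            out[i] = c0 * (1 - t0) + c1 * t0
            if want_grad:
                grad[i, 0] = c1 - c0
                grad[i, 1] = (c01 - c00) * (1 - t0) + (c11 - c10) * t0
                gz0 = (v001 - v000) * (1 - t1) + (v011 - v010) * t1
                gz1 = (v101 - v100) * (1 - t1) + (v111 - v110) * t1
                grad[i, 2] = gz0 * (1 - t0) + gz1 * t0
        return out, grad, valid

    @numba.njit(cache=True, fastmath=False)
    def _gather2_nb(vals, n0, n1, pts, want_grad):
        N = pts.shape[0]
        out = np.zeros(N)
        grad = np.zeros((N, 2))
        valid = np.ones(N, dtype=np.bool_)
        for i in range(N):
            x, y = pts[i, 0], pts[i, 1]
            if not (0.0 <= x <= n0 - 1 and 0.0 <= y <= n1 - 1):
                valid[i] = False
                continue
            f0 = int(x)
            f1 = int(y)
            if f0 > n0 - 2:
                f0 = n0 - 2
            if f1 > n1 - 2:
                f1 = n1 - 2
            t0 = x - f0
            t1 = y - f1
            base = f0 * n1 + f1
            v00 = vals[base]
            v01 = vals[base + 1]
            v10 = vals[base + n1]
            v11 = vals[base + n1 + 1]
            c0 = v00 * (1 - t1) + v01 * t1
            c1 = v10 * (1 - t1) + v11 * t1
            out[i] = c0 * (1 - t0) + c1 * t0
            if want_grad:
                grad[i, 0] = c1 - c0
                grad[i, 1] = (v01 - v00) * (1 - t0) + (v11 - v10) * t0
        return out, grad, valid

    @numba.njit(cache=True, fastmath=False)
    def _scatter3_nb(out, n0, n1, n2, pts, vals):
        for i in range(pts.shape[0]):
            x, y, z = pts[i, 0], pts[i, 1], pts[i, 2]
            if not (0.0 <= x <= n0 - 1 and 0.0 <= y <= n1 - 1 and 0.0 <= z <= n2 - 1):
                continue
            f0 = int(x)
            f1 = int(y)
            f2 = int(z)
            if f0 > n0 - 2:
                f0 = n0 - 2
            if f1 > n1 - 2:
                f1 = n1 - 2
            if f2 > n2 - 2:
                f2 = n2 - 2
            t0 = x - f0
            t1 = y - f1
            t2 = z - f2
            v = vals[i]
            base = (f0 * n1 + f1) * n2 + f2
            out[base] += v * (1 - t0) * (1 - t1) * (1 - t2)
            out[base + 1] += v * (1 - t0) * (1 - t1) * t2
            out[base + n2] += v * (1 - t0) * t1 * (1 - t2)
            out[base + n2 + 1] += v * (1 - t0) * t1 * t2
            out[base + n1 * n2] += v * t0 * (1 - t1) * (1 - t2)
            out[base + n1 * n2 + 1] += v * t0 * (1 - t1) * t2
            out[base + n1 * n2 + n2] += v * t0 * t1 * (1 - t2)
            out[base + n1 * n2 + n2 + 1] += v * t0 * t1 * t2


def gather(values: np.ndarray, coords: np.ndarray):
    """Sample ``values`` at fractional voxel coordinates.

    Returns (sampled values with 0 where invalid, valid mask); both shaped
    like ``coords`` without its last axis.
    """
    coords = np.asarray(coords, dtype=np.float64)
    lead = coords.shape[:-1]
    d = coords.shape[-1]
    pts = coords.reshape(-1, d)
    if _HAVE_NUMBA and values.ndim == d and d in (2, 3):
        flat = np.ascontiguousarray(values, dtype=np.float64).reshape(-1)
        pts_c = np.ascontiguousarray(pts)
        if d == 3:
            out, _, valid = _gather3_nb(flat, *values.shape, pts_c, False)
        else:
            out, _, valid = _gather2_nb(flat, *values.shape, pts_c, False)
        return out.reshape(lead), valid.reshape(lead)
    _, t, valid, base, st = _prep(pts, values.shape)
    flat = values.reshape(-1)
    w_axis = [(1.0 - t[:, a], t[:, a]) for a in range(d)]
    out = np.zeros(pts.shape[0], dtype=np.float64)
    for offs in product((0, 1), repeat=d):
        w = w_axis[0][offs[0]].copy()
        for a in range(1, d):
            w *= w_axis[a][offs[a]]
        off = int(sum(o * st[a] for a, o in enumerate(offs)))
        out += w * flat.take(base + off)
    out[~valid] = 0.0
    return out.reshape(lead), valid.reshape(lead)


def gather_with_gradient(values: np.ndarray, coords: np.ndarray):
    """As :func:`gather` but also returns d(out)/d(coords).

    The gradient is that of the multilinear interpolant itself (the exact
    derivative of the sampled function, piecewise constant along the
    derivative axis).
    """
    coords = np.asarray(coords, dtype=np.float64)
    lead = coords.shape[:-1]
    d = coords.shape[-1]
    pts = coords.reshape(-1, d)
    if _HAVE_NUMBA and values.ndim == d and d in (2, 3):
        flat = np.ascontiguousarray(values, dtype=np.float64).reshape(-1)
        pts_c = np.ascontiguousarray(pts)
        if d == 3:
            out, g, valid = _gather3_nb(flat, *values.shape, pts_c, True)
        else:
            out, g, valid = _gather2_nb(flat, *values.shape, pts_c, True)
        return out.reshape(lead), g.reshape(lead + (d,)), valid.reshape(lead)
    _, t, valid, base, st = _prep(pts, values.shape)
    flat = values.reshape(-1)
    w_axis = [(1.0 - t[:, a], t[:, a]) for a in range(d)]
    out = np.zeros(pts.shape[0], dtype=np.float64)
    grad = np.zeros((d, pts.shape[0]), dtype=np.float64)
    for offs in product((0, 1), repeat=d):
        off = int(sum(o * st[a] for a, o in enumerate(offs)))
        v = flat.take(base + off)
        w = w_axis[0][offs[0]].copy()
        for a in range(1, d):
            w *= w_axis[a][offs[a]]
        out += w * v
        for a in range(d):
            wa = None
            for b in range(d):
                if b == a:
                    continue
                wb = w_axis[b][offs[b]]
                wa = wb.copy() if wa is None else wa * wb
            if wa is None:
                wa = np.ones(pts.shape[0])
            if offs[a]:
                grad[a] += wa * v
            else:
                grad[a] -= wa * v
    out[~valid] = 0.0
    grad[:, ~valid] = 0.0
    return out.reshape(lead), np.moveaxis(grad, 0, -1).reshape(lead + (d,)), valid.reshape(lead)


def scatter(shape: tuple[int, ...], coords: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`gather`: spread ``values`` into a zero array.

    Invalid coordinates contribute nothing (mirroring gather's zero read).
    """
    coords = np.asarray(coords, dtype=np.float64)
    d = coords.shape[-1]
    pts = coords.reshape(-1, d)
    vals = np.asarray(values, dtype=np.float64).reshape(-1)
    if vals.shape[0] != pts.shape[0]:
        raise ValueError("values and coords length mismatch")
    if _HAVE_NUMBA and len(shape) == d == 3:
        out = np.zeros(int(np.prod(shape)), dtype=np.float64)
        _scatter3_nb(out, *shape, np.ascontiguousarray(pts), np.ascontiguousarray(vals))
        return out.reshape(shape)
    _, t, valid, base, st = _prep(pts, shape)
    vals = np.where(valid, vals, 0.0)
    w_axis = [(1.0 - t[:, a], t[:, a]) for a in range(d)]
    size = int(np.prod(shape[:d]))
    out = np.zeros(size, dtype=np.float64)
    for offs in product((0, 1), repeat=d):
        w = vals.copy()
        for a in range(d):
            w *= w_axis[a][offs[a]]
        off = int(sum(o * st[a] for a, o in enumerate(offs)))
        out += np.bincount(base + off, weights=w, minlength=size)
    return out.reshape(shape[:d])
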