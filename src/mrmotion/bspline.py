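"""Cubic B-spline lattice machinery shared by the FFD transform.

A displacement component on one axis is ``f(u) = sum_j c_j B(u - j)`` where
``u`` is the continuous lattice index (``(world - origin)/spacing``) and
``B`` is the centred cubic B-spline with support ``(-2, 2)``:

    B(x) = 2/3 - x^2 + |x|^3 / 2        for |x| <= 1
    B(x) = (2 - |x|)^3 / 6              for 1 < |x| < 2

With ``n`` control points per axis the field is fully supported for
``u in [1, n-2]`` (four basis functions available everywhere).

Regular output lattices use per-axis dense weight matrices (4 non-zeros per
row) applied separably; scattered points use the 4^d tensor-product stencil.
"""

from __future__ import annotations

import numpy as np

SUPPORT_MARGIN = 2  # control points needed on each side of a supported cell


def bspline3(x: np.ndarray, deriv: int = 0) -> np.ndarray:
    """Centred cubic B-spline and its first/second derivatives."""
    x = np.asarray(x, dtype=np.float64)
    ax = np.abs(x)
    s = np.sign(x)
    out = np.zeros_like(ax)
    inner = ax <= 1.0
    outer = (ax > 1.0) & (ax < 2.0)
    if deriv == 0:
        out[inner] = 2.0 / 3.0 - ax[inner] ** 2 + 0.5 * ax[inner] ** 3
        out[outer] = (2.0 - ax[outer]) ** 3 / 6.0
    elif deriv == 1:
        out[inner] = s[inner] * (-2.0 * ax[inner] + 1.5 * ax[inner] ** 2)
        out[outer] = s[outer] * (-0.5 * (2.0 - ax[outer]) ** 2)
    elif deriv == 2:
        out[inner] = -2.0 + 3.0 * ax[inner]
        out[outer] = 2.0 - ax[outer]
    else:
        raise ValueError("deriv must be 0, 1 or 2")
    return out


class SupportError(ValueError):
    """Raised when a point falls outside the supported control lattice."""


def stencil(u: np.ndarray, n: int, deriv: int = 0, check: bool = True):
    """4-point stencil along one axis.

    Returns (base indices (N,) pointing at the first of four control points,
    weights (N, 4)).
    """
    u = np.asarray(u, dtype=np.float64)
    if check and (np.any(u < 1.0 - 1e-9) or np.any(u > n - 2 + 1e-9)):
        raise SupportError(
            f"lattice coordinate outside supported range [1, {n - 2}]: "
            f"[{u.min():.3f}, {u.max():.3f}]"
        )
    cell = np.clip(np.floor(u).astype(np.int64), 1, n - 3)
    offs = np.arange(-1, 3)
    w = bspline3(u[:, None] - (cell[:, None] + offs[None, :]), deriv=deriv)
    return cell - 1, w


def weight_matrix(u: np.ndarray, n: int, deriv: int = 0) -> np.ndarray:
    """Dense (len(u), n) B-spline evaluation matrix for one axis."""
    u = np.atleast_1d(np.asarray(u, dtype=np.float64))
    base, w = stencil(u, n, deriv=deriv)
    mat = np.zeros((u.shape[0], n), dtype=np.float64)
    rows = np.arange(u.shape[0])
    for k in range(4):
        mat[rows, base + k] += w[:, k]
    return mat


def separable_apply(mats: list[np.ndarray], arr: np.ndarray) -> np.ndarray:
    """Apply one matrix per leading axis of ``arr`` (trailing axes untouched)."""
    out = arr
    for d, m in enumerate(mats):
        out = np.moveaxis(np.tensordot(m, out, axes=(1, d)), 0, d)
    return out


def scattered_eval(coeffs: np.ndarray, u: np.ndarray, derivs=None) -> np.ndarray:
    """Evaluate the tensor-product spline at scattered lattice coordinates.

    coeffs : (n0, ..., nd-1[, c]) control values
    u      : (N, d) lattice coordinates
    derivs : optional per-axis derivative orders (default all 0)
    """
    u = np.asarray(u, dtype=np.float64)
    d = u.shape[1]
    spatial = coeffs.shape[:d]
    if derivs is None:
        derivs = (0,) * d
    bases, weights = [], []
    for a in range(d):
        b, w = stencil(u[:, a], spatial[a], deriv=derivs[a])
        bases.append(b)
        weights.append(w)
    lead = coeffs.shape[d:]
    out = np.zeros((u.shape[0],) + lead, dtype=np.float64)
    from itertools import product as _product

    for offs in _product(range(4), repeat=d):
        w = np.ones(u.shape[0])
        idx = []
        for a, o in enumerate(offs):
            w = w * weights[a][:, o]
            idx.append(bases[a] + o)
        out += w.reshape((-1,) + (1,) * len(lead)) * coeffs[tuple(idx)]
    return out


# Dyadic subdivision: f(u) = sum_j c'_j B(2u - j) reproduces the coarse field
# exactly with the classic (1/8, 6/8, 1/8) / (1/2, 1/2) masks.
def subdivide_1d(c: np.ndarray, axis: int) -> np.ndarray:
    c = np.moveaxis(c, axis, 0)
    n = c.shape[0]
    pad = np.zeros((1,) + c.shape[1:], dtype=c.dtype)
    cp = np.concatenate([pad, c, pad], axis=0)  # indices -1 .. n
    even = (cp[:-2] + 6.0 * cp[1:-1] + cp[2:]) / 8.0  # j = 2i, i = 0..n-1
    odd = (cp[1:-1][:-1] + cp[1:-1][1:]) / 2.0  # j = 2i+1, i = 0..n-2
    out = np.zeros((2 * n - 1,) + c.shape[1:], dtype=c.dtype)
    out[0::2] = even
    out[1::2] = odd
    return np.moveaxis(out, 0, axis)
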