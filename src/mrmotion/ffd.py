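"""Cubic B-spline free-form deformation (FFD).

An :class:`FFDGrid` stores a displacement vector (in world mm) on a regular
control-point lattice; the continuous displacement field is the
tensor-product cubic B-spline interpolation of those vectors.  The grid is
dimension-agnostic (2D for in-plane slice registration, 3D for the motion
model) so both uses share one tested code path.

Provided operations:

* ``displacement`` / ``displacement_on_lattice`` — field evaluation,
* ``warp_pull`` — T(I, M): resample an image at ``x + u(x)``,
* ``splat_push`` — the exact linear-algebra adjoint of ``warp_pull``,
* ``bending_energy`` — mean squared second derivative penalty + gradient,
* ``refine`` — dyadic subdivision preserving the continuous field.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import bspline, interp
from .geometry import VolumeImage

__all__ = ["FFDGrid", "DVF", "warp_pull", "splat_push"]


@dataclass
class DVF:
    """Displacement field sampled on a volume lattice, with direction tag."""

    values: np.ndarray  # (n0, n1, n2, 3) mm
    spacing: np.ndarray
    origin: np.ndarray
    direction: str  # e.g. "t->r"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if not self.direction:
            raise ValueError("DVF requires a direction tag")

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.values, axis=-1)


@dataclass
class FFDGrid:
    """Control-point lattice of displacements (world mm)."""

    spacing: np.ndarray  # (d,) control-point pitch, mm
    origin: np.ndarray  # (d,) world position of control point (0, ..., 0)
    displacements: np.ndarray  # (n0, ..., nd-1, d)

    def __post_init__(self):
        self.spacing = np.atleast_1d(np.asarray(self.spacing, dtype=np.float64))
        self.origin = np.atleast_1d(np.asarray(self.origin, dtype=np.float64))
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        d = self.spacing.shape[0]
        if self.displacements.ndim != d + 1 or self.displacements.shape[-1] != d:
            raise ValueError("displacements must have shape (n0..nd-1, d)")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacements must be finite")

    # -- construction -------------------------------------------------
    @classmethod
    def for_fov(cls, fov_min, fov_max, spacing) -> "FFDGrid":
        """Grid whose supported region covers [fov_min, fov_max] with margin.

        Knots are placed at integer multiples of the spacing (canonical
        phase), so any two grids with the same spacing are aligned and a
        field representable on one is exactly representable on the other —
        and dyadic refinement stays phase-aligned across resolutions.
        """
        fov_min = np.atleast_1d(np.asarray(fov_min, dtype=np.float64))
        fov_max = np.atleast_1d(np.asarray(fov_max, dtype=np.float64))
        d = fov_min.shape[0]
        spacing = np.broadcast_to(np.atleast_1d(np.asarray(spacing, dtype=np.float64)), (d,))
        origin = (np.floor(fov_min / spacing) - 2.0) * spacing
        n = np.ceil((fov_max - origin) / spacing).astype(int) + 3
        return cls(
            spacing=spacing.copy(),
            origin=origin,
            displacements=np.zeros(tuple(n) + (d,)),
        )

    @property
    def ndim(self) -> int:
        return self.spacing.shape[0]

    @property
    def n_points(self) -> tuple[int, ...]:
        return self.displacements.shape[:-1]

    def same_lattice(self, other: "FFDGrid") -> bool:
        return (
            self.n_points == other.n_points
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def zeros_like(self) -> "FFDGrid":
        return replace(self, displacements=np.zeros_like(self.displacements))

    def with_displacements(self, disp: np.ndarray) -> "FFDGrid":
        return replace(self, displacements=np.asarray(disp, dtype=np.float64))

    def lattice_coords(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=np.float64) - self.origin) / self.spacing

    def supported_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """World bounds inside which the field is fully supported."""
        n = np.asarray(self.n_points, dtype=np.float64)
        return self.origin + self.spacing, self.origin + (n - 2) * self.spacing

    # -- evaluation ----------------------------------------------------
    def displacement(self, points: np.ndarray, derivs=None) -> np.ndarray:
        """Field (or a spatial derivative of it) at scattered world points.

        ``derivs`` gives per-axis derivative orders; derivative values are
        per-mm (chain rule through the lattice spacing applied).
        """
        pts = np.asarray(points, dtype=np.float64)
        lead = pts.shape[:-1]
        u = self.lattice_coords(pts.reshape(-1, self.ndim))
        out = bspline.scattered_eval(self.displacements, u, derivs=derivs)
        if derivs is not None:
            scale = np.prod(self.spacing ** np.asarray(derivs, dtype=np.float64))
            out = out / scale
        return out.reshape(lead + (self.ndim,))

    def axis_matrices(self, axis_world_coords: list[np.ndarray], derivs=None) -> list[np.ndarray]:
        """Per-axis B-spline weight matrices for a regular world lattice."""
        if derivs is None:
            derivs = (0,) * self.ndim
        mats = []
        for a in range(self.ndim):
            u = (np.asarray(axis_world_coords[a], dtype=np.float64) - self.origin[a]) / self.spacing[a]
            m = bspline.weight_matrix(u, self.n_points[a], deriv=derivs[a])
            mats.append(m / self.spacing[a] ** derivs[a])
        return mats

    def displacement_on_lattice(self, axis_world_coords: list[np.ndarray], derivs=None) -> np.ndarray:
        """Separable evaluation on a regular world lattice -> (m0.., d)."""
        mats = self.axis_matrices(axis_world_coords, derivs=derivs)
        return bspline.separable_apply(mats, self.displacements)

    def dvf(self, vol: VolumeImage, direction: str) -> DVF:
        """Sample the field on a volume lattice."""
        coords = [vol.axis_coords(a) for a in range(3)]
        return DVF(
            values=self.displacement_on_lattice(coords),
            spacing=vol.spacing,
            origin=vol.origin,
            direction=direction,
        )

    # -- algebra -------------------------------------------------------
    def __add__(self, other: "FFDGrid") -> "FFDGrid":
        if not self.same_lattice(other):
            raise ValueError("FFD grids live on different lattices")
        return self.with_displacements(self.displacements + other.displacements)

    def __sub__(self, other: "FFDGrid") -> "FFDGrid":
        if not self.same_lattice(other):
            raise ValueError("FFD grids live on different lattices")
        return self.with_displacements(self.displacements - other.displacements)

    def __mul__(self, scalar: float) -> "FFDGrid":
        return self.with_displacements(self.displacements * float(scalar))

    __rmul__ = __mul__

    # -- refinement ----------------------------------------------------
    def refine(self) -> "FFDGrid":
        """Halve the control spacing; the continuous field is unchanged."""
        disp = self.displacements
        for a in range(self.ndim):
            disp = bspline.subdivide_1d(disp, axis=a)
        return FFDGrid(spacing=self.spacing / 2.0, origin=self.origin.copy(), displacements=disp)

    # -- bending energy ------------------------------------------------
    def bending_energy(self, fov_min=None, fov_max=None, samples_per_knot: int = 2):
        """Mean squared second derivative over a regular FOV sample lattice.

        All six unique second-derivative tensors enter, mixed terms doubled;
        the value is normalised by the sample count.  Returns
        ``(scalar, gradient)`` with the analytic gradient per control point.
        """
        d = self.ndim
        if fov_min is None or fov_max is None:
            fov_min, fov_max = self.supported_bounds()
        fov_min = np.atleast_1d(np.asarray(fov_min, dtype=np.float64))
        fov_max = np.atleast_1d(np.asarray(fov_max, dtype=np.float64))
        coords = []
        for a in range(d):
            n = max(2, int(np.ceil((fov_max[a] - fov_min[a]) / self.spacing[a])) * samples_per_knot + 1)
            coords.append(np.linspace(fov_min[a], fov_max[a], n))
        n_samples = int(np.prod([c.shape[0] for c in coords]))
        energy = 0.0
        grad = np.zeros_like(self.displacements)
        for a in range(d):
            for b in range(a, d):
                derivs = [0] * d
                derivs[a] += 1
                derivs[b] += 1
                mats = self.axis_matrices(coords, derivs=tuple(derivs))
                field = bspline.separable_apply(mats, self.displacements)
                mult = 1.0 if a == b else 2.0
                energy += mult * np.sum(field**2)
                back = bspline.separable_apply([m.T for m in mats], field)
                grad += (2.0 * mult) * back
        return energy / n_samples, grad / n_samples


def warp_pull(vol: VolumeImage, grid_or_dvf, out_geometry: VolumeImage | None = None) -> VolumeImage:
    """T(I, M): output voxel x takes ``vol`` sampled at ``x + u(x)``.

    Trilinear image interpolation; samples falling outside ``vol`` are
    flagged invalid rather than zero-filled.
    """
    ref = out_geometry if out_geometry is not None else vol
    coords = [ref.axis_coords(a) for a in range(3)]
    if isinstance(grid_or_dvf, FFDGrid):
        u = grid_or_dvf.displacement_on_lattice(coords)
    else:
        u = np.asarray(grid_or_dvf.values, dtype=np.float64)
    world = np.stack(np.meshgrid(*coords, indexing="ij"), axis=-1) + u
    vox = (world - vol.origin) / vol.spacing
    vals, valid = interp.gather(vol.values, vox)
    if vol.valid is not None:
        inside, _ = interp.gather(vol.valid.astype(np.float64), vox)
        valid = valid & (inside > 0.999)
    return VolumeImage(values=vals, spacing=ref.spacing, origin=ref.origin, valid=valid)


def splat_push(data: VolumeImage, grid_or_dvf, target_geometry: VolumeImage | None = None):
    """Exact adjoint of :func:`warp_pull`.

    ``data`` lives on the *output* lattice of ``warp_pull``; each of its
    voxels is scattered into the target lattice with the same trilinear
    weights ``warp_pull`` would use to read it there.  Returns
    (accumulated VolumeImage, weight VolumeImage) on the target lattice.
    """
    target = target_geometry if target_geometry is not None else data
    coords = [data.axis_coords(a) for a in range(3)]
    if isinstance(grid_or_dvf, FFDGrid):
        u = grid_or_dvf.displacement_on_lattice(coords)
    else:
        u = np.asarray(grid_or_dvf.values, dtype=np.float64)
    world = np.stack(np.meshgrid(*coords, indexing="ij"), axis=-1) + u
    vox = (world - target.origin) / target.spacing
    mask = np.ones(data.values.shape) if data.valid is None else data.valid.astype(np.float64)
    acc = interp.scatter(target.shape, vox, data.values * mask)
    wts = interp.scatter(target.shape, vox, mask)
    return (
        VolumeImage(values=acc, spacing=target.spacing, origin=target.origin),
        VolumeImage(values=wts, spacing=target.spacing, origin=target.origin),
    )
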