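"""Surrogate-signal generation from the fixed sagittal surrogate slices.

Pipeline: select a mid-position reference slice from the first shift of the
first repetition -> register every surrogate slice to it with a 2D cubic
B-spline FFD (SSD + bending energy, conjugate gradient, coarse-to-fine
control spacing) -> PCA on the control-point displacements (loadings fitted
on building-phase rows only, applied to all rows) -> fix component signs so
each correlates positively with the mean SI displacement -> normalise to
the building-phase vector median, defining the reference time t_r with
S(t_r) = 0 -> interpolate signal values to the motion-slice times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from . import interp
from .ffd import FFDGrid
from .geometry import DynamicSlice
from .optimize import minimize_cg

__all__ = [
    "RegistrationParams",
    "SurrogateSignal",
    "select_reference_slice",
    "register_2d",
    "compute_signals",
    "normalise_vector_median",
    "interpolate_to_times",
    "generate_signals",
]


class InsufficientDataError(ValueError):
    pass


class RankError(ValueError):
    pass


@dataclass
class RegistrationParams:
    control_spacings: tuple[float, ...] = (40.0, 20.0, 10.0)
    bending_weight: float = 0.01
    # zeroth-order ridge on the displacement.  The similarity term cannot
    # constrain weakly textured regions, and unanchored displacements there
    # wander (especially with warm starts).  With ``anchor_air_only`` the
    # ridge acts only outside the dilated image foreground, which keeps
    # in-body magnitudes unbiased (preferred when the displacement size
    # itself is the measurement); the uniform ridge maximally stabilises
    # the control-point trajectories (preferred for surrogate extraction,
    # where a consistent linear response matters and shrinkage does not).
    displacement_weight: float = 0.01
    anchor_air_only: bool = False
    foreground_fraction: float = 0.05  # of the 99th intensity percentile
    smoothing_factor: float = 0.3  # image pyramid: sigma_px = factor*spacing/pixel (coarse levels)
    max_iter: int = 80
    grad_tol: float = 3e-4


@dataclass
class Registration2DResult:
    grid: FFDGrid
    params_flat: np.ndarray
    ssd_initial: float
    ssd_final: float
    converged: bool


def select_reference_slice(candidates: list[DynamicSlice]) -> int:
    """Mid-position slice: minimal L1 distance to the voxelwise temporal
    median image of the candidates; ties broken by earliest t_index."""
    if len(candidates) < 3:
        raise InsufficientDataError("need at least 3 candidate surrogate slices")
    order = np.argsort([s.t_index for s in candidates])
    stack = np.stack([candidates[i].values for i in order])
    median = np.median(stack, axis=0)
    scores = np.sum(np.abs(stack - median[None]), axis=(1, 2))
    return int(candidates[order[int(np.argmin(scores))]].t_index)


def _plane_setup(slc: DynamicSlice):
    p0, p1 = slc.geometry.shape
    sp = slc.geometry.in_plane_spacing
    extent = ((p0 - 1) * sp[0], (p1 - 1) * sp[1])
    base = np.stack(
        np.meshgrid(np.arange(p0, dtype=float), np.arange(p1, dtype=float), indexing="ij"),
        axis=-1,
    )
    return extent, base, sp


def register_2d(
    reference: DynamicSlice,
    moving: DynamicSlice,
    params: RegistrationParams | None = None,
    init: FFDGrid | None = None,
) -> Registration2DResult:
    """Deformable 2D registration: find u with moving(x + u(x)) ~ reference(x).

    Multi-resolution over control-point spacing (each level refines the
    previous grid); SSD similarity over jointly valid pixels plus a bending
    energy penalty; Polak-Ribiere conjugate gradient.  An ``init`` grid at
    the finest spacing (e.g. the previous frame's result when registering a
    temporally coherent stream) skips the coarse levels.
    Returns the final-level control-point displacements.
    """
    if params is None:
        params = RegistrationParams()
    if reference.geometry.shape != moving.geometry.shape or not np.allclose(
        reference.geometry.in_plane_spacing, moving.geometry.in_plane_spacing
    ):
        raise ValueError("reference and moving slices must share geometry")
    extent, base, sp = _plane_setup(reference)
    # normalise intensities so the similarity scale (and hence the meaning
    # of the regularisation weights) is image-independent
    scale = max(float(np.percentile(np.abs(reference.values), 99)), 1e-12)
    ref_raw = reference.values / scale
    ref_valid = reference.valid
    mov_raw = moving.values / scale
    if params.anchor_air_only:
        # ridge weight: 1 over air, 0 on/near the imaged anatomy
        fg = (reference.values > params.foreground_fraction * np.percentile(reference.values, 99)) & ref_valid
        dil = int(round(1.5 * params.control_spacings[-1] / float(np.min(reference.geometry.in_plane_spacing))))
        anchor = 1.0 - ndimage.binary_dilation(fg, iterations=max(dil, 1)).astype(np.float64)
    else:
        anchor = np.ones_like(ref_raw)

    grid = None
    converged = True
    spacings = params.control_spacings
    if init is not None:
        if not np.isclose(init.spacing[0], spacings[-1]):
            raise ValueError("init grid must be at the finest control spacing")
        grid = init
        spacings = spacings[-1:]
    for level, spacing in enumerate(spacings):
        if grid is None:
            grid = FFDGrid.for_fov((0.0, 0.0), extent, spacing)
        elif init is None:
            while grid.spacing[0] > spacing * 1.0000001:
                grid = grid.refine()
        # smoothed images at coarse levels widen the capture range
        if level < len(spacings) - 1 and params.smoothing_factor > 0:
            sig_px = params.smoothing_factor * spacing / float(np.min(sp))
            ref_vals = ndimage.gaussian_filter(ref_raw, sig_px)
            mov_vals = ndimage.gaussian_filter(mov_raw, sig_px)
        else:
            ref_vals, mov_vals = ref_raw, mov_raw
        mats = grid.axis_matrices(
            [np.arange(s, dtype=float) * sp[a] for a, s in enumerate(reference.geometry.shape)]
        )
        from . import bspline

        fov_lo, fov_hi = (0.0, 0.0), extent
        shape = grid.displacements.shape

        def fun_grad(x, _mats=mats, _grid=grid, _shape=shape, _mov=mov_vals, _ref=ref_vals):
            g = _grid.with_displacements(x.reshape(_shape))
            u = bspline.separable_apply(_mats, g.displacements)
            coords = base + u / sp
            vals, gimg, valid = interp.gather_with_gradient(_mov, coords)
            mask = valid & ref_valid
            n = max(int(mask.sum()), 1)
            r = np.where(mask, vals - _ref, 0.0)
            c = float(np.sum(r**2)) / n
            dq = (2.0 / n) * r[..., None] * gimg / sp
            grad = bspline.separable_apply([m.T for m in _mats], dq)
            be, gbe = g.bending_energy(fov_lo, fov_hi)
            # support-weighted ridge: pulls only air-region displacement to 0
            npix = u.shape[0] * u.shape[1]
            wu = anchor[..., None] * u
            ridge = float(np.sum(wu * u)) / npix
            gridge = bspline.separable_apply([m.T for m in _mats], (2.0 / npix) * wu)
            return (
                c + params.bending_weight * be + params.displacement_weight * ridge,
                (grad + params.bending_weight * gbe + params.displacement_weight * gridge).ravel(),
            )

        x0 = grid.displacements.ravel()
        # tolerance referenced to the zero-displacement gradient so that
        # warm starts near the optimum still converge to the same accuracy
        gref = float(np.linalg.norm(fun_grad(np.zeros_like(x0))[1]))
        res = minimize_cg(
            fun_grad, x0, max_iter=params.max_iter, grad_tol=params.grad_tol, grad_norm_ref=gref
        )
        converged = converged and (res.converged or res.message.startswith("line search"))
        grid = grid.with_displacements(res.x.reshape(shape))

    def raw_ssd(g: FFDGrid) -> float:
        from . import bspline

        mats = g.axis_matrices(
            [np.arange(s, dtype=float) * sp[a] for a, s in enumerate(reference.geometry.shape)]
        )
        u = bspline.separable_apply(mats, g.displacements)
        vals, valid = interp.gather(mov_raw, base + u / sp)
        mask = valid & ref_valid
        n = max(int(mask.sum()), 1)
        return float(np.sum(np.where(mask, vals - ref_raw, 0.0) ** 2)) / n

    return Registration2DResult(
        grid=grid,
        params_flat=grid.displacements.ravel().copy(),
        ssd_initial=raw_ssd(grid.zeros_like()),
        ssd_final=raw_ssd(grid),
        converged=converged,
    )


@dataclass
class SurrogateSignal:
    """Per-time surrogate values with PCA metadata and reference time."""

    t_indices: np.ndarray
    t_seconds: np.ndarray
    values: np.ndarray  # (n_times, n_components)
    building: np.ndarray  # bool mask over rows
    reference_t_index: int  # registration reference slice
    t_r: int | None = None  # vector-median (zero-signal) time point
    loadings: np.ndarray | None = None
    mean_row: np.ndarray | None = None
    explained_variance_ratio: np.ndarray | None = None
    sign_flips: np.ndarray | None = None
    normalised: bool = False
    median_value: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    def value_at(self, t_index: int) -> np.ndarray:
        i = int(np.where(self.t_indices == t_index)[0][0])
        return self.values[i]


def compute_signals(
    rows: np.ndarray,
    t_indices,
    t_seconds,
    building: np.ndarray,
    mean_si: np.ndarray,
    n_components: int = 2,
    reference_t_index: int = 0,
) -> SurrogateSignal:
    """PCA scores of registration displacement rows (unnormalised signal).

    The PCA basis (and the row mean) is fitted on building rows only and
    frozen before being applied to all rows; component signs are fixed so
    each score correlates positively with the mean SI displacement.
    """
    rows = np.asarray(rows, dtype=np.float64)
    building = np.asarray(building, dtype=bool)
    n_build = int(building.sum())
    if n_build < n_components + 1:
        raise InsufficientDataError("need more building rows than components")
    b = rows[building]
    if np.linalg.matrix_rank(b - b.mean(axis=0)) < n_components:
        raise RankError("building-phase displacements have insufficient rank for PCA")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(b)
    scores = pca.transform(rows)
    flips = np.ones(n_components)
    msb = mean_si[building]
    for c in range(n_components):
        sb = scores[building, c]
        if np.std(sb) > 0 and np.std(msb) > 0:
            r = float(np.corrcoef(sb, msb)[0, 1])
            if r < 0:
                flips[c] = -1.0
    scores = scores * flips
    return SurrogateSignal(
        t_indices=np.asarray(t_indices),
        t_seconds=np.asarray(t_seconds, dtype=np.float64),
        values=scores,
        building=building,
        reference_t_index=int(reference_t_index),
        loadings=pca.components_ * flips[:, None],
        mean_row=pca.mean_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        sign_flips=flips,
    )


def normalise_vector_median(signal: SurrogateSignal) -> SurrogateSignal:
    """Subtract the building-phase vector median; its time becomes t_r.

    The vector median is the building-phase value vector minimising the sum
    of Euclidean distances to all building-phase vectors (an element of the
    set, so S(t_r) = 0 exactly).  Idempotent.
    """
    b = signal.values[signal.building]
    d = cdist(b, b)
    i = int(np.argmin(d.sum(axis=1)))  # argmin returns the earliest tie
    median = b[i].copy()
    t_r = int(signal.t_indices[np.where(signal.building)[0][i]])
    return replace(
        signal,
        values=signal.values - median[None],
        t_r=t_r,
        normalised=True,
        median_value=median,
    )


def interpolate_to_times(signal: SurrogateSignal, t_seconds_out) -> np.ndarray:
    """Componentwise linear interpolation in time; boundary times clamp."""
    t_out = np.asarray(t_seconds_out, dtype=np.float64)
    out = np.empty((t_out.shape[0], signal.n_components))
    order = np.argsort(signal.t_seconds)
    ts = signal.t_seconds[order]
    for c in range(signal.n_components):
        out[:, c] = np.interp(t_out, ts, signal.values[order, c])
    return out


def control_point_support(reference: DynamicSlice, grid: FFDGrid, intensity_frac: float = 0.05,
                          support_frac: float = 0.02) -> np.ndarray:
    """Control points whose B-spline support overlaps actual image content.

    Control points over air are unconstrained by the similarity term; their
    displacements are regularisation artefacts and would feed pure noise
    into the PCA, so rows are restricted to supported points.
    """
    img = (reference.values > intensity_frac * np.percentile(reference.values, 99)) & reference.valid
    sp = reference.geometry.in_plane_spacing
    mats = grid.axis_matrices(
        [np.arange(reference.geometry.shape[a], dtype=float) * sp[a] for a in range(2)]
    )
    sup = mats[0].T @ img.astype(np.float64) @ mats[1]
    return sup > support_frac * sup.max()


def generate_signals(
    dataset,
    params: RegistrationParams | None = None,
    n_components: int = 2,
    progress=None,
) -> SurrogateSignal:
    """Run the full surrogate pipeline on a dataset and attach the result.

    Registers all surrogate slices (building + evaluation) to the selected
    reference, computes normalised signals (PCA restricted to control
    points with image support) and stores the interpolated value for every
    motion slice in ``slice.meta['signal']``.
    """
    if params is None:
        params = RegistrationParams()
    surr = dataset.surrogate_slices()
    if not surr:
        raise InsufficientDataError("dataset has no surrogate slices")
    first_rep = min(s.meta.get("repetition", 1) for s in surr)
    candidates = [
        s
        for s in surr
        if s.meta.get("repetition", 1) == first_rep and s.meta.get("shift_mm", 0.0) == 0.0
    ]
    ref_t = select_reference_slice(candidates)
    reference = dataset.slice_at(ref_t)

    rows, t_idx, t_sec, building = [], [], [], []
    building_reps = set(dataset.building_repetitions)
    prev_grid = None  # warm start: surrogate stream is temporally coherent
    zero_row = register_zero_row(reference, params)
    for k, s in enumerate(surr):
        if s.t_index == ref_t:
            res_flat = zero_row.copy()
        else:
            res = register_2d(reference, s, params, init=prev_grid)
            res_flat = res.params_flat
            prev_grid = res.grid
        rows.append(res_flat)
        t_idx.append(s.t_index)
        t_sec.append(s.t_seconds)
        building.append(s.meta.get("repetition", 1) in building_reps)
        if progress is not None:
            progress(k + 1, len(surr))
    rows = np.asarray(rows)
    # restrict PCA to control points with image support
    grid_template = prev_grid if prev_grid is not None else None
    if grid_template is None:
        raise InsufficientDataError("no non-reference surrogate slices to register")
    cp_mask = control_point_support(reference, grid_template)
    col_sel = np.repeat(cp_mask.ravel(), 2)
    rows_sel = rows[:, col_sel]
    # sagittal surrogate slices: in-plane axes are (AP, SI) -> SI is component 1
    mean_si = rows_sel.reshape(rows_sel.shape[0], -1, 2)[:, :, 1].mean(axis=1)
    signal = compute_signals(
        rows_sel,
        t_idx,
        t_sec,
        np.asarray(building),
        mean_si,
        n_components=n_components,
        reference_t_index=ref_t,
    )
    signal.meta["control_point_mask"] = cp_mask
    signal = normalise_vector_median(signal)
    motion = dataset.motion_slices()
    interpolated = interpolate_to_times(signal, [m.t_seconds for m in motion])
    for m, v in zip(motion, interpolated):
        m.meta["signal"] = v
    dataset.signals = signal
    return signal


def register_zero_row(reference: DynamicSlice, params: RegistrationParams) -> np.ndarray:
    """Shape-matched zero parameter vector for the self-registration row."""
    extent, _, _ = _plane_setup(reference)
    grid = FFDGrid.for_fov((0.0, 0.0), extent, params.control_spacings[0])
    while grid.spacing[0] > params.control_spacings[-1] * 1.0000001:
        grid = grid.refine()
    return grid.displacements.ravel()
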