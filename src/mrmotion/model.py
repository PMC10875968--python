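"""Linear surrogate-to-motion correspondence model and its fit.

The model holds one B-spline control-point grid R_i per surrogate component
and predicts, for a signal vector s_t, the transformation parameters

    M_t = sum_i s_{t,i} R_i   (optionally plus a constant component),

so zero signal (the vector-median reference state) means zero motion.

The fit minimises, over the building-phase motion slices,

    C = sum_t SSD(P_t, A_t(T(I_r, M_t))) / N_t  +  lambda * sum_t BE(M_t)

with per-slice mean SSD over valid pixels (so sagittal and axial slices
with different valid-pixel counts contribute comparably), BE the bending
energy, optimised by Polak-Ribiere conjugate gradient with a multi-level
control-point refinement.  Because M_t is linear in the signals, the sum of
bending terms reduces to a quadratic form through the signal Gram matrix,
which keeps the penalty cost independent of the number of slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .acquisition import SliceOperator, TRUNCATION_FWHM
from .ffd import DVF, FFDGrid
from .geometry import VolumeImage
from .optimize import minimize_cg


@dataclass
class FitConfig:
    control_spacings: tuple[float, ...] = (32.0, 16.0)
    # bending weight on the p99-normalised similarity.  The slice data
    # leaves a near-flat valley of deformations that reproduce it equally
    # well; the bending term resolves that null space toward smooth fields.
    # Chosen at the knee of the accuracy/data-fidelity trade-off measured
    # on synthetic ground truth (see docs/methods.md).
    lambda_be: float = 1.0
    # support-weighted displacement ridge: anchors control points whose
    # B-spline support sees no image content (air), where the similarity
    # term cannot constrain the motion; without it the line search can
    # drift such regions (and their slices) out of the FOV
    lambda_disp: float = 0.05
    max_iter_per_level: int = 50
    grad_tol: float = 1e-5
    # "lbfgs": limited-memory quasi-Newton (scipy), the default - it
    # reaches a given deformation accuracy several times faster here than
    # nonlinear CG; "cg": Polak-Ribiere conjugate gradient with Armijo
    # backtracking (the classical choice for this model family)
    optimizer: str = "lbfgs"
    use_constant: bool = False  # optional intercept component for drifting data
    # image pyramid: at non-final levels the reference image and slices are
    # Gaussian-smoothed with sigma = smoothing_factor * control spacing,
    # widening the capture range for large displacements
    smoothing_factor: float = 0.3

    def __post_init__(self):
        sp = tuple(self.control_spacings)
        if any(b >= a for a, b in zip(sp, sp[1:])):
            raise ValueError("control spacings must be strictly decreasing")
        if self.lambda_be < 0:
            raise ValueError("lambda_be must be >= 0")


@dataclass
class MotionModel:
    components: list[FFDGrid]  # one grid per surrogate component (+ optional constant)
    has_constant: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        base = self.components[0]
        for c in self.components[1:]:
            if not base.same_lattice(c):
                raise ValueError("model components must share one lattice")

    @property
    def n_signals(self) -> int:
        return len(self.components) - (1 if self.has_constant else 0)

    @property
    def lattice(self) -> FFDGrid:
        return self.components[0]

    def params_at(self, s_t) -> FFDGrid:
        """Eq.-style linear combination M_t = sum_i s_i R_i."""
        s_t = np.atleast_1d(np.asarray(s_t, dtype=np.float64))
        if s_t.shape[0] != self.n_signals:
            raise ValueError(f"signal has {s_t.shape[0]} components, model expects {self.n_signals}")
        disp = np.zeros_like(self.components[0].displacements)
        for i in range(self.n_signals):
            disp += s_t[i] * self.components[i].displacements
        if self.has_constant:
            disp += self.components[-1].displacements
        return self.components[0].with_displacements(disp)

    def dvf(self, s_t, vol: VolumeImage, direction: str = "t->r") -> DVF:
        return self.params_at(s_t).dvf(vol, direction)

    @classmethod
    def zero(cls, lattice: FFDGrid, n_signals: int, has_constant: bool = False) -> "MotionModel":
        n = n_signals + (1 if has_constant else 0)
        return cls(components=[lattice.zeros_like() for _ in range(n)], has_constant=has_constant)

    def refine(self) -> "MotionModel":
        return replace(self, components=[c.refine() for c in self.components])


def _smoothed_level(ref_image: VolumeImage, slices, sigma_mm: float):
    """Gaussian-smoothed copies of the reference and slices for one
    pyramid level (raw data is used at the finest level)."""
    import copy

    from scipy import ndimage

    ref = ref_image.copy_with(
        ndimage.gaussian_filter(ref_image.values, sigma_mm / ref_image.spacing),
        valid=ref_image.valid,
    )
    out = []
    for s in slices:
        s2 = copy.copy(s)
        s2.values = ndimage.gaussian_filter(
            s.values, sigma_mm / s.geometry.in_plane_spacing
        )
        out.append(s2)
    return ref, out


def model_lattice_for(ref: VolumeImage, thickness: float, spacing: float) -> FFDGrid:
    """Control lattice covering the reference FOV plus the slice-profile
    support margin (quadrature samples reach 1.5 x thickness beyond a
    slice plane at the FOV edge)."""
    lo, hi = ref.fov_bounds()
    pad = TRUNCATION_FWHM * thickness
    return FFDGrid.for_fov(lo - pad, hi + pad, spacing)


class FitProblem:
    """Objective/gradient of the correspondence-model fit on one lattice."""

    def __init__(
        self,
        slices,
        ref_image: VolumeImage,
        lattice: FFDGrid,
        lambda_be: float,
        lambda_disp: float = 0.05,
        use_constant: bool = False,
        op_cache: dict | None = None,
    ):
        self.slices = [s for s in slices if "signal" in s.meta]
        if len(self.slices) != len(slices):
            raise ValueError("every motion slice needs an interpolated surrogate signal")
        self.ref = ref_image
        self.lattice = lattice
        self.lambda_be = lambda_be
        self.lambda_disp = lambda_disp
        # similarity is computed on p99-normalised intensities so the
        # regularisation weights have an image-independent meaning
        self.scale = max(float(np.percentile(np.abs(ref_image.values), 99)), 1e-12)
        self._ref_vals = ref_image.values / self.scale
        self.ops = []
        cache = op_cache if op_cache is not None else {}
        for s in self.slices:
            g = s.geometry
            key = (tuple(g.origin), tuple(g.normal), g.shape, g.thickness)
            if key not in cache:
                cache[key] = SliceOperator(g, ref_image)
            self.ops.append(cache[key])
        sigs = np.stack([np.atleast_1d(s.meta["signal"]) for s in self.slices])
        if use_constant:
            sigs = np.hstack([sigs, np.ones((sigs.shape[0], 1))])
        self.signals = sigs
        self.n_comp = sigs.shape[1]
        self.gram = sigs.T @ sigs
        self.shape = (self.n_comp,) + lattice.displacements.shape
        self._warned_empty: set = set()
        self._last_f = float("nan")
        lo, hi = ref_image.fov_bounds()
        self._be_fov = (lo, hi)
        # frozen per-slice normaliser: the valid-pixel count at zero
        # displacement.  Normalising by the *current* valid count would let
        # the optimiser lower the objective by pushing pixels out of the
        # FOV instead of explaining them.
        self.n0 = []
        self._pvals = []
        for s, op in zip(self.slices, self.ops):
            self.n0.append(max(int((op.pixel_valid & s.valid).sum()), 1))
            self._pvals.append(s.values / self.scale)
        self._setup_anchor()

    def _setup_anchor(self):
        """Support-weighted displacement ridge on a FOV sample lattice."""
        from scipy import ndimage

        from . import bspline, interp

        lo, hi = self._be_fov
        coords = []
        for a in range(3):
            n = max(2, int(np.ceil((hi[a] - lo[a]) / self.lattice.spacing[a])) * 2 + 1)
            coords.append(np.linspace(lo[a], hi[a], n))
        self._anchor_mats = self.lattice.axis_matrices(coords)
        fg = self.ref.values > 0.05 * np.percentile(self.ref.values, 99)
        dil = max(1, int(round(1.5 * float(self.lattice.spacing[0]) / float(np.min(self.ref.spacing)))))
        fg = ndimage.binary_dilation(fg, iterations=dil)
        pts = np.stack(np.meshgrid(*coords, indexing="ij"), axis=-1)
        vox = (pts - self.ref.origin) / self.ref.spacing
        inside, _ = interp.gather(fg.astype(np.float64), vox)
        self._anchor = (inside < 0.5).astype(np.float64)
        self._anchor_n = float(self._anchor.size)
        self._bspline = bspline

    def _anchor_fields(self, R: np.ndarray):
        return [
            self._bspline.separable_apply(self._anchor_mats, R[i]) for i in range(self.n_comp)
        ]

    def _anchor_energy(self, fields):
        """sum_t ridge(M_t) collapsed through the signal Gram matrix."""
        total = 0.0
        for i in range(self.n_comp):
            for j in range(self.n_comp):
                total += self.gram[i, j] * float(
                    np.sum(self._anchor[..., None] * fields[i] * fields[j])
                )
        return total / self._anchor_n

    def _anchor_gradient(self, fields):
        grads = []
        for i in range(self.n_comp):
            acc = np.zeros_like(fields[0])
            for j in range(self.n_comp):
                acc += self.gram[i, j] * fields[j]
            g = self._bspline.separable_apply(
                [m.T for m in self._anchor_mats], (2.0 / self._anchor_n) * self._anchor[..., None] * acc
            )
            grads.append(g)
        return np.stack(grads)

    def pack(self, model: MotionModel) -> np.ndarray:
        return np.stack([c.displacements for c in model.components]).ravel()

    def unpack(self, x: np.ndarray, has_constant: bool) -> MotionModel:
        comps = [
            self.lattice.with_displacements(d) for d in x.reshape(self.shape)
        ]
        return MotionModel(components=comps, has_constant=has_constant)

    def __call__(self, x: np.ndarray):
        R = x.reshape(self.shape)
        grad = np.zeros_like(R)
        total = 0.0
        for s, op, sig, n, pv in zip(self.slices, self.ops, self.signals, self.n0, self._pvals):
            ctrl = np.einsum("i,i...->...", sig, R)
            grid = self.lattice.with_displacements(ctrl)
            disp_quad = op.displacement_from_grid(grid)
            est, pixel_valid, backproject = op.forward_deformed_with_backprojection(
                self._ref_vals, disp_quad
            )
            mask = pixel_valid & s.valid
            if not mask.any():
                if s.t_index not in self._warned_empty:
                    self._warned_empty.add(s.t_index)
                    warnings.warn(f"slice t={s.t_index} has no valid pixels; excluded from fit")
                continue
            r = np.where(mask, est - pv, 0.0)
            total += float(np.sum(r * r)) / n
            g_quad = backproject((2.0 / n) * r)
            ctrl_grad = op.scatter_to_grid(grid, g_quad)
            grad += sig[:, None, None, None, None] * ctrl_grad[None]
        if self.lambda_disp > 0:
            fields = self._anchor_fields(R)
            total += self.lambda_disp * self._anchor_energy(fields)
            grad += self.lambda_disp * self._anchor_gradient(fields)
        self._last_f = total
        if self.lambda_be > 0:
            be = np.empty(self.n_comp)
            gbe = np.empty_like(R)
            for i in range(self.n_comp):
                be[i], gbe[i] = self.lattice.with_displacements(R[i]).bending_energy(*self._be_fov)
            for i in range(self.n_comp):
                for j in range(self.n_comp):
                    if i == j:
                        total += self.lambda_be * self.gram[i, i] * be[i]
                    elif i < j:
                        bij, _ = self.lattice.with_displacements(R[i] + R[j]).bending_energy(
                            *self._be_fov
                        )
                        cross = 0.5 * (bij - be[i] - be[j])
                        total += 2.0 * self.lambda_be * self.gram[i, j] * cross
                    grad[i] += self.lambda_be * self.gram[i, j] * gbe[j]
        return total, grad.ravel()

    def fun_grad(self, x: np.ndarray):
        f, g = self(x)
        return f, g

    def gn_diagonal(self, floor_rel: float = 1e-3) -> np.ndarray:
        """Jacobi preconditioner: Gauss-Newton diagonal of the similarity
        term at zero displacement.

        diag_j ~ sum_t s_{t,i}^2 sum_q (2/N_t) (w_q dI/dx / sp)^2 B_j(q)^2,
        which is separable through squared B-spline weight matrices.  The
        diagonal is floored at ``floor_rel`` of its maximum so control
        points without data support still take bounded steps (their motion
        is governed by the bending term).
        """
        from . import bspline

        diag = np.zeros(self.shape)
        for s, op, sig, n in zip(self.slices, self.ops, self.signals, self.n0):
            est, pixel_valid, backproject = op.forward_deformed_with_backprojection(
                self._ref_vals, None
            )
            # (w * grad / sp) per quadrature sample, squared
            gq = backproject(np.ones(est.shape))
            gq2 = (2.0 / n) * gq**2
            mats = [m**2 for m in op.ffd_world_mats(self.lattice)]
            inv = np.argsort(op.world_axes)
            world = np.transpose(gq2, tuple(int(a) for a in inv) + (3,))
            contrib = bspline.separable_apply([m.T for m in mats], world)
            diag += (sig**2)[:, None, None, None, None] * contrib[None]
        if self.lambda_disp > 0:
            mats2 = [m**2 for m in self._anchor_mats]
            anchor_diag = bspline.separable_apply(
                [m.T for m in mats2], np.broadcast_to(self._anchor[..., None], self._anchor.shape + (3,)).copy()
            ) * (2.0 * self.lambda_disp / self._anchor_n)
            for i in range(self.n_comp):
                diag[i] += self.gram[i, i] * anchor_diag
        mx = float(diag.max())
        if mx <= 0:
            return np.ones(int(np.prod(self.shape)))
        return np.maximum(diag, floor_rel * mx).ravel()

    def fun_only(self, x: np.ndarray) -> float:
        """Objective without its gradient (cheaper line-search trials)."""
        R = x.reshape(self.shape)
        total = 0.0
        for s, op, sig, n, pv in zip(self.slices, self.ops, self.signals, self.n0, self._pvals):
            ctrl = np.einsum("i,i...->...", sig, R)
            grid = self.lattice.with_displacements(ctrl)
            disp_quad = op.displacement_from_grid(grid)
            est, pixel_valid = op.forward_deformed(self._ref_vals, disp_quad)
            mask = pixel_valid & s.valid
            if not mask.any():
                continue
            r = np.where(mask, est - pv, 0.0)
            total += float(np.sum(r * r)) / n
        if self.lambda_disp > 0:
            total += self.lambda_disp * self._anchor_energy(self._anchor_fields(R))
        if self.lambda_be > 0:
            be = np.empty(self.n_comp)
            for i in range(self.n_comp):
                be[i], _ = self.lattice.with_displacements(R[i]).bending_energy(*self._be_fov)
            for i in range(self.n_comp):
                total += self.lambda_be * self.gram[i, i] * be[i]
                for j in range(i + 1, self.n_comp):
                    bij, _ = self.lattice.with_displacements(R[i] + R[j]).bending_energy(
                        *self._be_fov
                    )
                    cross = 0.5 * (bij - be[i] - be[j])
                    total += 2.0 * self.lambda_be * self.gram[i, j] * cross
        self._last_f = total
        return total


def fit(
    slices,
    ref_image: VolumeImage,
    cfg: FitConfig | None = None,
    init_model: MotionModel | None = None,
    op_cache: dict | None = None,
) -> MotionModel:
    """Fit the correspondence model to building-phase motion slices.

    Multi-resolution: each level runs conjugate gradient to tolerance, then
    the components are refined by B-spline subdivision.  A warm-start
    ``init_model`` (from a previous alternation) skips the levels coarser
    than its lattice.  Deterministic given its inputs.
    """
    cfg = cfg or FitConfig()
    if not slices:
        raise ValueError("no motion slices to fit")
    thickness = slices[0].geometry.thickness
    n_signals = np.atleast_1d(slices[0].meta["signal"]).shape[0]
    spacings = list(cfg.control_spacings)
    model = init_model
    history = []
    if model is not None:
        # run only the levels at or below the warm-start resolution
        spacings = [sp for sp in spacings if sp <= model.lattice.spacing[0] * 1.0000001]
        if not spacings:
            spacings = [float(model.lattice.spacing[0])]
    for li, spacing in enumerate(spacings):
        lattice = model_lattice_for(ref_image, thickness, spacing) if model is None else model.lattice
        if model is None:
            model = MotionModel.zero(lattice, n_signals, has_constant=cfg.use_constant)
        if li < len(spacings) - 1 and cfg.smoothing_factor > 0:
            level_ref, level_slices = _smoothed_level(
                ref_image, slices, cfg.smoothing_factor * spacing
            )
        else:
            level_ref, level_slices = ref_image, slices
        problem = FitProblem(
            level_slices, level_ref, model.lattice, cfg.lambda_be,
            lambda_disp=cfg.lambda_disp, use_constant=model.has_constant,
            op_cache=op_cache if li == len(spacings) - 1 else None,
        )
        x0 = problem.pack(model)
        if cfg.optimizer == "lbfgs":
            from scipy import optimize as sopt

            hist = [problem.fun_only(x0)]
            res = sopt.minimize(
                problem.fun_grad, x0, jac=True, method="L-BFGS-B",
                callback=lambda xk: hist.append(problem._last_f),
                options=dict(maxiter=cfg.max_iter_per_level, maxcor=20,
                             ftol=1e-12, gtol=cfg.grad_tol),
            )
            model = problem.unpack(res.x, model.has_constant)
            history.append(dict(spacing=spacing, objective=hist + [float(res.fun)],
                                message=str(res.message)))
        elif cfg.optimizer == "cg":
            res = minimize_cg(
                problem.fun_grad,
                x0,
                max_iter=cfg.max_iter_per_level,
                grad_tol=cfg.grad_tol,
                fun_only=problem.fun_only,
                precond=problem.gn_diagonal(),
            )
            model = problem.unpack(res.x, model.has_constant)
            history.append(dict(spacing=spacing, objective=res.history, message=res.message))
        else:
            raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
        if li < len(spacings) - 1:
            model = model.refine()
            # snap the refined lattice: next level must match half spacing
            if not np.isclose(model.lattice.spacing[0], spacings[li + 1]):
                raise ValueError(
                    "control spacings must halve between levels "
                    f"({spacing} -> {spacings[li + 1]})"
                )
    model.provenance = dict(levels=history, lambda_be=cfg.lambda_be, config=vars(cfg))
    return model
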