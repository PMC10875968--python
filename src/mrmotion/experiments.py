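"""End-to-end validation experiments.

Each function builds its inputs from the synthetic-data generator, runs the
package's own pipeline and measures the quantities that characterise the
method: operator adjointness, FFD exactness, objective-gradient
consistency, parameter recovery (deformation-field error before/after
fitting), the AVGI/SRI/MCSRI reconstruction ordering, super-resolution
gain on a static resolution phantom, surrogate-signal recovery, the
residual-error-vs-DFE consistency, ground-truth invertibility and
determinism.  The problem sizes are desk-scale versions of the acquisition
scheme (64^3 lattice at 2 mm, 10 mm slices, five 2 mm shifts, three
building repetitions) — see docs/methods.md.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .acquisition import SliceOperator, build_schedule
from .evaluate import dfe_analysis_multi, mae, residual_error_registration
from .ffd import FFDGrid, warp_pull, splat_push
from .geometry import DynamicSlice, SliceGeometry, VolumeImage
from .model import FitConfig, FitProblem, model_lattice_for
from .reconstruct import ReconConfig, alternate_fit_reconstruct, reconstruct_average, reconstruct_ibp
from .simulator import (
    PhantomSpec,
    TraceConfig,
    build_motion,
    compose_displacement,
    generate_phantom,
    generate_trace,
    simulate_acquisition,
)
from .surrogate import generate_signals


def _sub_seed(seed: int, k: int) -> int:
    return (int(seed) * 1_000_003 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# operator-level checks
# ---------------------------------------------------------------------------
def run_adjoint_checks(seed: int, n_cases: int = 100, n_vox: int = 24) -> dict:
    """<Ax,y> vs <x,A*y> and <Tx,y> vs <x,T*y> over random geometries/grids."""
    rng = np.random.default_rng(_sub_seed(seed, 1))
    worst_a = 0.0
    worst_t = 0.0
    for _ in range(n_cases):
        n = int(rng.integers(n_vox, 33))
        vol = VolumeImage(
            values=rng.standard_normal((n, n, n)),
            spacing=rng.uniform(1.5, 3.0, 3),
            origin=rng.uniform(-5, 5, 3),
        )
        lo, hi = vol.fov_bounds()
        axis = int(rng.integers(3))
        ip = [a for a in range(3) if a != axis]
        axes = np.zeros((2, 3))
        axes[0, ip[0]] = 1.0
        axes[1, ip[1]] = 1.0
        normal = np.zeros(3)
        normal[axis] = 1.0
        origin = np.zeros(3)
        origin[ip[0]] = lo[ip[0]] + rng.uniform(0, 5)
        origin[ip[1]] = lo[ip[1]] + rng.uniform(0, 5)
        origin[axis] = rng.uniform(lo[axis], hi[axis])
        geom = SliceGeometry(
            origin=origin,
            in_plane_axes=axes,
            normal=normal,
            in_plane_spacing=rng.uniform(1.5, 3.0, 2),
            shape=(int(rng.integers(10, 24)), int(rng.integers(10, 24))),
            thickness=rng.uniform(6.0, 12.0),
        )
        op = SliceOperator(geom, vol)
        grid = FFDGrid.for_fov(lo - 20, hi + 20, rng.uniform(12, 24))
        grid = grid.with_displacements(rng.standard_normal(grid.displacements.shape) * 2)
        x = rng.standard_normal(vol.shape)
        y = rng.standard_normal(geom.shape)
        dq = op.displacement_from_grid(grid)
        fx, _ = op.forward_deformed(x, dq)
        ay, _ = op.adjoint_deformed(y, dq)
        num = float(np.sum(fx * y))
        err = abs(num - float(np.sum(x * ay))) / max(abs(num), 1e-12)
        worst_a = max(worst_a, err)
        # warp/splat pair on the volume lattice
        y3 = VolumeImage(values=rng.standard_normal(vol.shape), spacing=vol.spacing, origin=vol.origin)
        w = warp_pull(vol, grid)
        acc, _ = splat_push(y3, grid, target_geometry=vol)
        num = float(np.sum(w.values * y3.values))
        err = abs(num - float(np.sum(vol.values * acc.values))) / max(abs(num), 1e-12)
        worst_t = max(worst_t, err)
    return dict(acquisition_adjoint_max_rel_err=worst_a, warp_adjoint_max_rel_err=worst_t)


def run_ffd_checks(seed: int) -> dict:
    rng = np.random.default_rng(_sub_seed(seed, 2))
    grid = FFDGrid.for_fov((0, 0, 0), (60, 60, 60), 12.0)
    const = grid.with_displacements(np.broadcast_to(rng.uniform(-3, 3, 3), grid.displacements.shape).copy())
    pts = rng.uniform(0, 60, (300, 3))
    pou = float(np.abs(const.displacement(pts) - const.displacements[0, 0, 0]).max())
    rnd = grid.with_displacements(rng.standard_normal(grid.displacements.shape) * 2)
    fine = rnd.refine()
    subdiv = float(np.abs(rnd.displacement(pts) - fine.displacement(pts)).max())
    small = FFDGrid.for_fov((0, 0, 0), (40, 40, 40), 10.0)
    small = small.with_displacements(rng.standard_normal(small.displacements.shape))
    be0, g0 = small.bending_energy((0, 0, 0), (40, 40, 40))
    eps = 1e-5
    worst = 0.0
    flat = small.displacements.copy()
    for idx in rng.integers(0, flat.size, 20):
        d = flat.ravel().copy()
        d[idx] += eps
        bp, _ = small.with_displacements(d.reshape(flat.shape)).bending_energy((0, 0, 0), (40, 40, 40))
        d[idx] -= 2 * eps
        bm, _ = small.with_displacements(d.reshape(flat.shape)).bending_energy((0, 0, 0), (40, 40, 40))
        fd = (bp - bm) / (2 * eps)
        worst = max(worst, abs(fd - g0.ravel()[idx]) / max(np.abs(g0).max(), 1e-12))
    return dict(
        partition_of_unity_max_err_mm=pou,
        subdivision_max_err_mm=subdiv,
        bending_gradient_max_rel_err=worst,
    )


def run_gradient_check(seed: int) -> dict:
    """Fit-objective gradient vs central differences on a 5-slice toy."""
    rng = np.random.default_rng(_sub_seed(seed, 3))
    vol, _ = generate_phantom(PhantomSpec(fov_mm=(64, 64, 64), spacing_mm=4.0, seed=_sub_seed(seed, 30)))
    lo, hi = vol.fov_bounds()
    sched = build_schedule(lo, hi, surrogate_plane_lr=float((lo[0] + hi[0]) / 2),
                           in_plane_spacing=4.0, n_repetitions=1)
    slices = []
    for e in [e for e in sched.entries if e.role == "motion"][:5]:
        from .acquisition import acquire_slice

        s = acquire_slice(vol, e.geometry, t_index=e.t_index)
        s.meta["signal"] = rng.uniform(-1, 1, 2)
        slices.append(s)
    lattice = model_lattice_for(vol, 10.0, 32.0)  # 4^3-scale control lattice
    prob = FitProblem(slices, vol, lattice, lambda_be=0.01)
    x0 = rng.standard_normal(int(np.prod(prob.shape))) * 0.5
    f0, g0 = prob(x0)
    scale = max(float(np.abs(g0).max()), 1e-12)
    eps = 1e-5
    worst = 0.0
    for idx in rng.integers(0, x0.size, 24):
        xp = x0.copy()
        xp[idx] += eps
        fp, _ = prob(xp)
        xp[idx] -= 2 * eps
        fm, _ = prob(xp)
        fd = (fp - fm) / (2 * eps)
        worst = max(worst, abs(fd - g0[idx]) / scale)
    return dict(objective_gradient_max_rel_err=worst)


# ---------------------------------------------------------------------------
# the main parameter-recovery experiment (shared by several checks)
# ---------------------------------------------------------------------------
def make_recovery_dataset(
    seed: int,
    spacing_mm: float = 2.0,
    n_building: int = 3,
    n_evaluation: int = 1,
    peak_si_mm: float = 10.0,
    noise_sigma_rel: float = 0.0,
    motion_mode: str = "span",
):
    """Simulated dataset at the study conditions (64^3 / 2 mm by default)."""
    phantom, masks = generate_phantom(PhantomSpec(spacing_mm=spacing_mm, seed=_sub_seed(seed, 4)))
    lo, hi = phantom.fov_bounds()
    motion = build_motion(phantom, peak_si_mm=peak_si_mm, mode=motion_mode)
    tum = np.argwhere(masks["tumour"])
    cx = float(phantom.origin[0] + tum[:, 0].mean() * phantom.spacing[0])
    bidx = np.argwhere(masks["body"])
    bmin = phantom.origin + bidx.min(0) * phantom.spacing
    bmax = phantom.origin + bidx.max(0) * phantom.spacing
    n_rep = n_building + n_evaluation
    sched = build_schedule(
        lo, hi, cx, thickness=10.0, in_plane_spacing=spacing_mm, shift_step_mm=2.0,
        n_shifts=5, n_repetitions=n_rep, motion_extent=(bmin, bmax),
    )
    trace = generate_trace(
        TraceConfig(), len(sched.entries), sched.params["frame_interval"], seed=_sub_seed(seed, 5)
    )
    return simulate_acquisition(
        phantom, masks, motion, trace, sched,
        noise_sigma_rel=noise_sigma_rel, seed=_sub_seed(seed, 6),
        building_repetitions=tuple(range(1, n_building + 1)),
        evaluation_repetitions=tuple(range(n_building + 1, n_rep + 1)),
    )


def run_recovery(seed: int, dataset=None, progress=None) -> dict:
    """Parameter recovery + reconstruction ordering + residual-error check.

    Fits the motion model by alternation on the building repetitions of a
    model-span dataset and reports: body-mask DFE (zero model and fitted,
    building and evaluation), the DFE reduction, per-direction DFEs, MAE of
    AVGI/SRI/MCSRI against the ground-truth reference-state image, and the
    residual-error registration summary.
    """
    ds = dataset if dataset is not None else make_recovery_dataset(seed)
    generate_signals(ds, progress=progress)
    fit_cfg = FitConfig(control_spacings=(32.0, 16.0), max_iter_per_level=60)
    recon_cfg = ReconConfig(n_ibp_iterations=4, n_alternations=3, alternation_tol=1e-3)
    op_cache: dict = {}
    building = ds.motion_slices(ds.building_repetitions)
    avgi = reconstruct_average(building, None, ds.ref_geometry, op_cache=op_cache)
    sri = reconstruct_ibp(building, None, ds.ref_geometry, cfg=recon_cfg, op_cache=op_cache)
    model, mcsri, log = alternate_fit_reconstruct(ds, fit_cfg, recon_cfg)

    # ground-truth reference-state image I*_GT = I_GT(x + u_{t_r -> 0}(x))
    a_r = ds.trace.state(ds.signals.t_r)
    gt_ref = warp_pull(ds.phantom, ds.motion.dvf(*a_r, direction="backward"))
    body = ds.masks["body"]
    maes = {
        "mae_avgi": mae(avgi, gt_ref, body),
        "mae_sri": mae(sri, gt_ref, body),
        "mae_mcsri": mae(mcsri, gt_ref, body),
    }

    out = dict(maes)
    # building-phase frames are subsampled (their per-frame spatial means
    # vary slowly); evaluation frames are used in full
    for phase, reps, stride in (
        ("building", ds.building_repetitions, 3),
        ("evaluation", ds.evaluation_repetitions, 1),
    ):
        both = dfe_analysis_multi(ds, {"model": model, "zero": None}, reps, frame_stride=stride)
        _, summary_m, _ = both["model"]
        _, summary_z, _ = both["zero"]

        def roi_mean(s, roi):
            row = s[s.roi == roi]
            return float(row["mean"].iloc[0]) if len(row) else float("nan")

        out[f"dfe_body_model_{phase}_mm"] = roi_mean(summary_m, "body")
        out[f"dfe_body_zero_{phase}_mm"] = roi_mean(summary_z, "body")
        for lab in ("SI", "AP", "LR"):
            out[f"dfe_{lab}_model_{phase}_mm"] = roi_mean(summary_m, f"body_{lab}")
        if phase == "evaluation":
            out["dfe_tumour_model_mm"] = roi_mean(summary_m, "tumour")
            out["dfe_lungs_model_mm"] = roi_mean(summary_m, "lungs")
    out["dfe_reduction_pct"] = 100.0 * (
        1.0 - out["dfe_body_model_evaluation_mm"] / out["dfe_body_zero_evaluation_mm"]
    )
    out["dfe_eval_over_build_ratio"] = (
        out["dfe_body_model_evaluation_mm"] / out["dfe_body_model_building_mm"]
    )

    table, _ = residual_error_registration(
        ds, model, mcsri, ds.evaluation_repetitions, body=body, op_cache=op_cache
    )
    res_means = {}
    for lab in ("SI", "AP", "LR"):
        row = table[(table.phase == "evaluation") & (table.direction == lab)]
        res_means[lab] = float(row["mean"].iloc[0]) if len(row) else float("nan")
        out[f"residual_{lab}_mm"] = res_means[lab]
    res_norm = float(np.linalg.norm([res_means["SI"], res_means["AP"], res_means["LR"]]))
    out["residual_norm_mm"] = res_norm
    out["residual_over_dfe_ratio"] = res_norm / out["dfe_body_model_evaluation_mm"]
    out["n_building_slices"] = len(building)
    out["n_alternations_run"] = sum(1 for e in log.entries if e["stage"].startswith("alternation"))
    return out, ds, model, mcsri


def run_surrogate_recovery(seed: int, noise_sigma_rel: float = 0.05) -> dict:
    """Surrogate-signal recovery at 5% Rician noise on a one-repetition set."""
    ds = make_recovery_dataset(
        seed, n_building=1, n_evaluation=0, noise_sigma_rel=noise_sigma_rel
    )
    signal = generate_signals(ds)
    surr = ds.surrogate_slices()
    a1 = np.array([s.meta["a1"] for s in surr])
    a2 = np.array([s.meta["a2"] for s in surr])
    sv = np.array([signal.value_at(s.t_index) for s in surr])
    corr = float(np.corrcoef(sv[:, 0], a1)[0, 1])
    X = np.column_stack([sv, np.ones(len(sv))])
    resid = tot = 0.0
    for y in (a1, a2):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        resid += float((r**2).sum())
        tot += float(((y - y.mean()) ** 2).sum())
    return dict(
        surrogate_corr_pc1_a1=abs(corr),
        surrogate_r2=1.0 - resid / tot,
        signal_at_reference_norm=float(np.linalg.norm(signal.value_at(signal.t_r))),
        explained_variance_pc1=float(signal.explained_variance_ratio[0]),
    )


def make_bar_phantom(spacing_mm: float = 2.0, bar_width_mm: float = 3.0):
    """Static resolution phantom: SI-periodic bar pattern inside a slab."""
    n = int(round(128.0 / spacing_mm))
    vol = VolumeImage(values=np.zeros((n, n, n)), spacing=(spacing_mm,) * 3, origin=(0, 0, 0))
    ax = [vol.axis_coords(a) for a in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    c = (n - 1) * spacing_mm / 2.0
    body = ((X - c) / 52.0) ** 2 + ((Y - c) / 46.0) ** 2 + ((Z - c) / 56.0) ** 2 <= 1.0
    values = np.where(body, 100.0, 0.0)
    bars = body & (np.mod(Z, 2 * bar_width_mm) < bar_width_mm)
    values[bars] = 160.0
    vol = vol.copy_with(values)
    return vol, body


def run_sr_gain(seed: int, spacing_mm: float = 2.0) -> dict:
    """Super-resolution gain: SRI vs AVGI on the static bar phantom."""
    vol, body = make_bar_phantom(spacing_mm)
    lo, hi = vol.fov_bounds()
    bidx = np.argwhere(body)
    bmin = vol.origin + bidx.min(0) * vol.spacing
    bmax = vol.origin + bidx.max(0) * vol.spacing
    sched = build_schedule(
        lo, hi, float((lo[0] + hi[0]) / 2), thickness=10.0, in_plane_spacing=spacing_mm,
        n_repetitions=1, motion_extent=(bmin, bmax),
    )
    trace = generate_trace(TraceConfig(), len(sched.entries), sched.params["frame_interval"],
                           seed=_sub_seed(seed, 7))
    trace.a1[:] = 0.0
    trace.a2[:] = 0.0
    ds = simulate_acquisition(vol, None, None, trace, sched, noise_sigma_rel=0.0,
                              seed=_sub_seed(seed, 8), building_repetitions=(1,),
                              evaluation_repetitions=())
    slices = ds.motion_slices((1,))
    cache: dict = {}
    avgi = reconstruct_average(slices, None, ds.ref_geometry, op_cache=cache)
    sri = reconstruct_ibp(slices, None, ds.ref_geometry,
                          cfg=ReconConfig(n_ibp_iterations=8), op_cache=cache)
    m_a = mae(avgi, vol, body)
    m_s = mae(sri, vol, body)
    return dict(mae_avgi_bars=m_a, mae_sri_bars=m_s, sr_gain_ratio=m_s / m_a)


def run_invertibility(seed: int, spacing_mm: float = 2.0) -> dict:
    """Forward-compose-backward residual of the ground-truth motion at
    extreme trace amplitudes (in voxel units)."""
    phantom, masks = generate_phantom(PhantomSpec(spacing_mm=spacing_mm, seed=_sub_seed(seed, 9)))
    motion = build_motion(phantom, peak_si_mm=16.0, mode="svf")
    trace = generate_trace(TraceConfig(), 600, 0.35, seed=_sub_seed(seed, 10))
    extremes = [
        (float(trace.a1.max()), float(trace.a2[np.argmax(trace.a1)])),
        (float(trace.a1.min()), float(trace.a2[np.argmin(trace.a1)])),
        (float(trace.a1[np.argmax(np.abs(trace.a2))]), float(trace.a2[np.argmax(np.abs(trace.a2))])),
    ]
    body = masks["body"]
    vox = float(np.min(phantom.spacing))
    means, maxes = [], []
    for a1, a2 in extremes:
        mag = motion.invertibility_residual(a1, a2)[body] / vox
        means.append(float(mag.mean()))
        maxes.append(float(mag.max()))
    return dict(invertibility_mean_voxel=max(means), invertibility_max_voxel=max(maxes))


def run_determinism(seed: int) -> dict:
    """Bit-identical outputs for repeated runs of a small pipeline."""

    def one_run():
        ds = make_recovery_dataset(seed, spacing_mm=4.0, n_building=1, n_evaluation=0,
                                   noise_sigma_rel=0.02)
        generate_signals(ds)
        fit_cfg = FitConfig(control_spacings=(32.0,), max_iter_per_level=8)
        recon_cfg = ReconConfig(n_ibp_iterations=2, n_alternations=1)
        model, mcsri, _ = alternate_fit_reconstruct(ds, fit_cfg, recon_cfg)
        h = hashlib.sha256()
        for c in model.components:
            h.update(c.displacements.tobytes())
        h.update(mcsri.values.tobytes())
        h.update(ds.signals.values.tobytes())
        return h.hexdigest()

    h1 = one_run()
    h2 = one_run()
    return dict(determinism_identical=float(h1 == h2), pipeline_hash=h1)
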