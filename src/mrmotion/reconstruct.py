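"""Reference-image reconstruction.

Three estimators of the motion-free reference image from the thick-slice
stream, in increasing fidelity:

* AVGI  — weighted intensity averaging: back-project every slice with
  T*_t(A*_t(.)) and divide by the accumulated weights.
* SRI   — iterative back-projection (IBP) super-resolution initialised
  from the AVGI: repeatedly simulate the slices from the current volume,
  back-project the residuals and update with a step-halving safeguard so
  the data fidelity never increases.
* MCSRI — the same IBP but with the fitted motion model compensating each
  slice's motion; produced by alternating model fitting and reconstruction.

The zero model (predicting no motion anywhere) turns MCSRI into SRI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import SliceOperator
from .geometry import VolumeImage
from .model import FitConfig, MotionModel, fit, model_lattice_for


@dataclass
class ReconConfig:
    n_ibp_iterations: int = 5
    ibp_alpha: float = 1.0
    ibp_alpha_floor: float = 1.0 / 16.0
    weight_epsilon_rel: float = 1e-6
    n_alternations: int = 5
    alternation_tol: float = 1e-3


def _ops_for(slices, ref: VolumeImage, cache: dict | None):
    cache = cache if cache is not None else {}
    ops = []
    for s in slices:
        g = s.geometry
        key = (tuple(g.origin), tuple(g.normal), g.shape, g.thickness)
        if key not in cache:
            cache[key] = SliceOperator(g, ref)
        ops.append(cache[key])
    return ops


def _disp_quad(op, model: MotionModel | None, s):
    if model is None:
        return None
    return op.displacement_from_grid(model.params_at(np.atleast_1d(s.meta["signal"])))


def reconstruct_average(
    slices, model: MotionModel | None, ref: VolumeImage, op_cache: dict | None = None
) -> VolumeImage:
    """AVGI: motion-compensated weighted average of back-projected slices."""
    ops = _ops_for(slices, ref, op_cache)
    acc = np.zeros(ref.shape)
    wts = np.zeros(ref.shape)
    for s, op in zip(slices, ops):
        a, w = op.adjoint_deformed(s.values, _disp_quad(op, model, s), slice_valid=s.valid)
        acc += a
        wts += w
    eps = 1e-6 * max(wts.max(), 1e-30)
    valid = wts > eps
    values = np.where(valid, acc / np.where(valid, wts, 1.0), 0.0)
    out = VolumeImage(values=values, spacing=ref.spacing, origin=ref.origin, valid=valid)
    out.weights = wts  # total back-projection weight, reused by IBP
    return out


def reconstruct_ibp(
    slices,
    model: MotionModel | None,
    ref: VolumeImage,
    init: VolumeImage | None = None,
    cfg: ReconConfig | None = None,
    op_cache: dict | None = None,
) -> VolumeImage:
    """Iterative back-projection super-resolution.

    Each iteration simulates every slice from the current volume through
    A_t(T(., M_t)), back-projects the residuals with the adjoint and takes
    a weighted gradient step; the step size is halved whenever the data
    fidelity would increase, and the best iterate is returned if the step
    floor is reached.
    """
    cfg = cfg or ReconConfig()
    ops = _ops_for(slices, ref, op_cache)
    wts_total = None
    if init is None:
        init = reconstruct_average(slices, model, ref, op_cache=op_cache)
        wts_total = getattr(init, "weights", None)  # same model -> reusable
    if wts_total is None:
        wts_total = np.zeros(ref.shape)
        for s, op in zip(slices, ops):
            d = _disp_quad(op, model, s)
            _, w = op.adjoint_deformed(np.zeros(s.values.shape), d, slice_valid=s.valid)
            wts_total += w
    eps = cfg.weight_epsilon_rel * max(wts_total.max(), 1e-30)
    valid = wts_total > eps

    def residual_pass(vol_values):
        # per-slice displacements are re-evaluated on the fly (separable
        # B-spline evaluation is cheap; caching them all would not be)
        fid = 0.0
        acc = np.zeros(ref.shape)
        for s, op in zip(slices, ops):
            d = _disp_quad(op, model, s)
            est, pix_ok = op.forward_deformed(vol_values, d)
            mask = pix_ok & s.valid
            e = np.where(mask, s.values - est, 0.0)
            n = max(int(mask.sum()), 1)
            fid += float(np.sum(e * e)) / n
            a, _ = op.adjoint_deformed(e, d, slice_valid=mask)
            acc += a
        return fid, acc

    values = np.where(valid, init.values, 0.0)
    fid, acc = residual_pass(values)
    history = [fid]
    best = (fid, values.copy())
    alpha = cfg.ibp_alpha
    for _ in range(cfg.n_ibp_iterations):
        stepped = False
        while alpha >= cfg.ibp_alpha_floor:
            new = values + alpha * np.where(valid, acc / (wts_total + eps), 0.0)
            fid_new, acc_new = residual_pass(new)
            if fid_new <= fid * (1.0 + 1e-12):
                stepped = True
                break
            alpha *= 0.5
        if not stepped:
            break
        values, fid, acc = new, fid_new, acc_new
        history.append(fid)
        if fid < best[0]:
            best = (fid, values.copy())
    out = VolumeImage(values=best[1], spacing=ref.spacing, origin=ref.origin, valid=valid)
    out.weights = wts_total
    out.fidelity_history = history
    return out


@dataclass
class AlternationLog:
    entries: list = field(default_factory=list)


def alternate_fit_reconstruct(
    dataset,
    fit_cfg: FitConfig | None = None,
    recon_cfg: ReconConfig | None = None,
) -> tuple[MotionModel, VolumeImage, AlternationLog]:
    """Alternate correspondence-model fitting and MCSRI reconstruction.

    Starts from the zero model (iteration 0 reconstructs with no motion
    compensation), then repeats fit (warm-started) and IBP reconstruction
    (initialised from the previous image) until the relative change of the
    fit objective falls below tolerance or the alternation budget is spent.
    """
    fit_cfg = fit_cfg or FitConfig()
    recon_cfg = recon_cfg or ReconConfig()
    ref = dataset.ref_geometry
    slices = dataset.motion_slices(dataset.building_repetitions)
    if dataset.signals is None or not getattr(dataset.signals, "normalised", False):
        raise ValueError("dataset needs normalised surrogate signals (run generate_signals)")
    op_cache: dict = {}
    log = AlternationLog()

    image = reconstruct_ibp(slices, None, ref, cfg=recon_cfg, op_cache=op_cache)
    log.entries.append(dict(stage="initial_reconstruction", fidelity=image.fidelity_history))
    model = None
    prev_obj = None
    for it in range(1, recon_cfg.n_alternations + 1):
        model = fit(slices, image, fit_cfg, init_model=model, op_cache=op_cache)
        obj = model.provenance["levels"][-1]["objective"][-1]
        image = reconstruct_ibp(slices, model, ref, init=image, cfg=recon_cfg, op_cache=op_cache)
        log.entries.append(
            dict(stage=f"alternation_{it}", objective=obj, fidelity=image.fidelity_history)
        )
        if prev_obj is not None and abs(prev_obj - obj) <= recon_cfg.alternation_tol * abs(prev_obj):
            break
        prev_obj = obj
    return model, image, log
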