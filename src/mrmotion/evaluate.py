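"""Geometric-accuracy evaluation.

With known ground truth: the deformation field error (DFE), the voxelwise
l2 norm of the difference between the model-estimated and ground-truth
displacement fields (both t -> reference), summarised per region of
interest by the temporal mean, standard deviation and 95th percentile of
the per-frame spatial means, plus a voxelwise temporal-mean DFE map.

Without ground truth: residual-error registration — simulate each motion
slice from the MCSRI through the model and the acquisition operator, 2D
register the estimate to the acquired slice, and summarise the in-plane
displacement magnitudes per anatomical direction (sagittal slices
contribute SI and AP, axial slices AP and LR).

Plus the plain image mean absolute error (MAE).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import interp
from .acquisition import SliceOperator
from .ffd import DVF
from .geometry import AXIS_LABELS, VolumeImage
from .surrogate import RegistrationParams, register_2d


def dfe(model_dvf: DVF, gt_dvf: DVF, mask: np.ndarray):
    """Voxelwise deformation field error and its spatial mean over a mask."""
    if model_dvf.direction != gt_dvf.direction:
        raise ValueError(
            f"direction mismatch: {model_dvf.direction!r} vs {gt_dvf.direction!r}"
        )
    if model_dvf.values.shape != gt_dvf.values.shape:
        raise ValueError("DVFs live on different lattices")
    field = np.linalg.norm(model_dvf.values - gt_dvf.values, axis=-1)
    return field, float(field[mask].mean())


def mae(recon: VolumeImage, reference: VolumeImage, mask: np.ndarray) -> float:
    """Mean absolute intensity error over a mask, restricted to voxels
    carrying valid data in both images."""
    if recon.shape != reference.shape:
        raise ValueError("images live on different lattices")
    m = np.asarray(mask, dtype=bool)
    if recon.valid is not None:
        m = m & recon.valid
    if reference.valid is not None:
        m = m & reference.valid
    return float(np.mean(np.abs(recon.values[m] - reference.values[m])))


def quantile95(series) -> float:
    """Linear-interpolation 95th percentile (deterministic order statistic)."""
    return float(np.percentile(np.asarray(series, dtype=np.float64), 95, method="linear"))


def roi_summary(per_frame: pd.DataFrame) -> pd.DataFrame:
    """Temporal mean/sd/95th-percentile of per-frame spatial-mean DFEs.

    ``per_frame`` has one row per (t_index, roi) with a ``mean_dfe`` column.
    Empty ROIs are marked absent.
    """
    rows = []
    for roi, grp in per_frame.groupby("roi", sort=False):
        vals = grp["mean_dfe"].to_numpy()
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            rows.append(dict(roi=roi, mean=np.nan, sd=np.nan, p95=np.nan, absent=True))
        else:
            rows.append(
                dict(
                    roi=roi,
                    mean=float(vals.mean()),
                    sd=float(vals.std(ddof=0)),
                    p95=quantile95(vals),
                    absent=False,
                )
            )
    return pd.DataFrame(rows)


def dfe_analysis_multi(
    dataset,
    models: dict,
    repetitions,
    rois=("body", "tumour", "lungs", "liver", "heart"),
    restrict_valid: np.ndarray | None = None,
    frame_stride: int = 1,
):
    """DFE of several models (None = the zero model) in one sweep.

    The ground-truth field of each frame is composed once and compared
    against every model.  ``frame_stride`` subsamples the evaluation
    frames (the per-frame spatial means vary slowly, so a stride is a
    cheap variance/compute trade).  Returns
    ``{name: (per-frame DataFrame, summary DataFrame, mean DFE map)}``.
    """
    if dataset.motion is None or dataset.signals is None:
        raise ValueError("dataset needs ground-truth motion and surrogate signals")
    ref = dataset.ref_geometry
    t_r = dataset.signals.t_r
    state_r = dataset.trace.state(t_r)
    # u_{0->t_r} (padded lattice) is shared by every frame's composition
    forward_r = dataset.motion.forward_padded(*state_r)
    frames = dataset.motion_slices(repetitions)[:: max(int(frame_stride), 1)]
    masks = dataset.masks
    records = {name: [] for name in models}
    acc_map = {name: np.zeros(ref.shape) for name in models}
    zero = np.zeros(ref.shape + (3,))
    for s in frames:
        gt = dataset.motion.between_field(
            (s.meta["a1"], s.meta["a2"]), state_r, forward_b=forward_r
        )
        for name, model in models.items():
            if model is None:
                mdl = zero
            else:
                mdl = model.params_at(np.atleast_1d(s.meta["signal"])).displacement_on_lattice(
                    [ref.axis_coords(a) for a in range(3)]
                )
            err = np.linalg.norm(mdl - gt, axis=-1)
            acc_map[name] += err
            for roi in rois:
                if masks is None or roi not in masks:
                    records[name].append(dict(t_index=s.t_index, roi=roi, mean_dfe=np.nan))
                    continue
                m = masks[roi]
                if restrict_valid is not None:
                    m = m & restrict_valid
                records[name].append(
                    dict(
                        t_index=s.t_index,
                        roi=roi,
                        mean_dfe=float(err[m].mean()) if m.any() else np.nan,
                    )
                )
            # per-direction absolute errors within the body
            if masks is not None and "body" in masks:
                m = masks["body"]
                if restrict_valid is not None:
                    m = m & restrict_valid
                diff = np.abs(mdl - gt)
                for a, lab in enumerate(AXIS_LABELS):
                    records[name].append(
                        dict(t_index=s.t_index, roi=f"body_{lab}",
                             mean_dfe=float(diff[..., a][m].mean()))
                    )
    out = {}
    for name in models:
        per_frame = pd.DataFrame(records[name])
        out[name] = (per_frame, roi_summary(per_frame), acc_map[name] / max(len(frames), 1))
    return out


def dfe_analysis(
    dataset,
    model,
    repetitions,
    rois=("body", "tumour", "lungs", "liver", "heart"),
    restrict_valid: np.ndarray | None = None,
    frame_stride: int = 1,
):
    """DFE of a fitted model (or the zero model if ``model`` is None)
    against the dataset's ground-truth motion, over the motion-slice time
    points of the given repetitions.

    Returns (per-frame DataFrame, summary DataFrame, temporal-mean DFE map).
    """
    return dfe_analysis_multi(
        dataset, {"model": model}, repetitions, rois=rois,
        restrict_valid=restrict_valid, frame_stride=frame_stride,
    )["model"]


def residual_error_registration(
    dataset,
    model,
    mcsri: VolumeImage,
    repetitions,
    body: np.ndarray | None = None,
    reg_params: RegistrationParams | None = None,
    use_body_mask: bool = True,
    op_cache: dict | None = None,
):
    """Estimate model error without ground truth.

    For each motion slice: simulate the model-estimated slice (deform the
    MCSRI by M_t, apply A_t), register the estimate to the acquired slice
    in 2D, and accumulate the absolute in-plane displacements per
    anatomical direction within the body mask.  Means are pooled over
    slices weighted by masked pixel count; sd and p95 summarise the
    per-slice spatial means.
    """
    from .geometry import DynamicSlice

    # magnitude-faithful registration: anchor only air so in-body residual
    # magnitudes are not shrunk by the regularisation
    reg_params = reg_params or RegistrationParams(displacement_weight=0.05, anchor_air_only=True)
    ref = mcsri
    cache = op_cache if op_cache is not None else {}
    per_slice = []
    skipped = 0
    for s in dataset.motion_slices(repetitions):
        g = s.geometry
        key = (tuple(g.origin), tuple(g.normal), g.shape, g.thickness)
        if key not in cache:
            cache[key] = SliceOperator(g, ref)
        op = cache[key]
        disp_quad = (
            op.displacement_from_grid(model.params_at(np.atleast_1d(s.meta["signal"])))
            if model is not None
            else None
        )
        est_vals, est_valid = op.forward_deformed(mcsri.values, disp_quad, vol_valid=mcsri.valid)
        estimate = DynamicSlice(
            geometry=g, values=est_vals, t_index=s.t_index, t_seconds=s.t_seconds,
            role="motion", valid=est_valid,
        )
        res = register_2d(s, estimate, reg_params)
        # per-pixel displacement of the registration at the pixel lattice
        sp = g.in_plane_spacing
        pix = [np.arange(g.shape[0]) * sp[0], np.arange(g.shape[1]) * sp[1]]
        u = res.grid.displacement_on_lattice(pix)
        mask = s.valid & est_valid
        if use_body_mask and body is not None:
            centre = op.static_vox_coords()[:, :, op.offsets.shape[0] // 2, :]
            inside, _ = interp.gather(np.asarray(body, dtype=np.float64), centre)
            mask = mask & (inside > 0.5)
        n = int(mask.sum())
        if n == 0:
            skipped += 1
            continue
        world_axes, _ = g.world_axis_map()
        rec = dict(
            t_index=s.t_index,
            repetition=s.meta.get("repetition"),
            orientation=s.meta.get("orientation"),
            n_pixels=n,
        )
        for k in range(2):  # the two in-plane axes
            lab = AXIS_LABELS[world_axes[k]]
            rec[lab] = float(np.abs(u[..., k])[mask].mean())
        per_slice.append(rec)
    per_slice = pd.DataFrame(per_slice)
    phases = {
        "building": tuple(dataset.building_repetitions),
        "evaluation": tuple(dataset.evaluation_repetitions),
    }
    rows = []
    for phase, reps in phases.items():
        sub = per_slice[per_slice["repetition"].isin(reps)] if len(per_slice) else per_slice
        for lab in AXIS_LABELS:
            if len(sub) == 0 or lab not in sub or sub[lab].notna().sum() == 0:
                continue
            vals = sub[sub[lab].notna()]
            w = vals["n_pixels"].to_numpy(dtype=float)
            v = vals[lab].to_numpy(dtype=float)
            rows.append(
                dict(
                    phase=phase,
                    direction=lab,
                    mean=float(np.average(v, weights=w)),
                    sd=float(v.std(ddof=0)),
                    p95=quantile95(v),
                    n_slices=len(v),
                )
            )
    table = pd.DataFrame(rows)
    table.attrs["skipped_slices"] = skipped
    return table, per_slice
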