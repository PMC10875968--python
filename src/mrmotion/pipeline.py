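"""End-to-end pipeline orchestration and the model-application path.

``run_pipeline`` executes simulate -> signals -> fit -> evaluate from one
YAML-able configuration dictionary, writing every artefact (dataset,
signals, model, MCSRI, evaluation tables) plus a provenance file with
content hashes so repeated runs can be compared bit for bit.

``apply_model`` is the application phase: one new surrogate slice is
registered to the stored reference, projected with the frozen PCA and the
stored vector-median offset, and the resulting signal drives the model to
produce a DVF and the deformed reference image for that time point.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nifti
from .dataset import SliceDataset
from .evaluate import dfe_analysis, mae, residual_error_registration
from .ffd import FFDGrid, warp_pull
from .geometry import DynamicSlice, VolumeImage
from .model import FitConfig, MotionModel
from .reconstruct import ReconConfig, alternate_fit_reconstruct, reconstruct_average, reconstruct_ibp
from .simulator import (
    GroundTruthMotion,
    PhantomSpec,
    TraceConfig,
    build_motion,
    generate_phantom,
    generate_trace,
    simulate_acquisition,
)
from .acquisition import build_schedule
from .surrogate import RegistrationParams, SurrogateSignal, register_2d, generate_signals

DEFAULT_CONFIG = dict(
    seed=1,
    phantom=dict(spacing_mm=4.0),
    motion=dict(peak_si_mm=10.0, mode="svf"),
    schedule=dict(thickness=10.0, shift_step_mm=2.0, n_shifts=5, n_repetitions=2),
    noise_sigma_rel=0.05,
    building_repetitions=[1],
    evaluation_repetitions=[2],
    fit=dict(control_spacings=[32.0, 16.0], lambda_be=1.0, max_iter_per_level=15),
    recon=dict(n_ibp_iterations=3, n_alternations=2),
)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.report = dict(stage=stage, error=str(err), error_type=type(err).__name__)


def _array_hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# persistence of model / signals / motion
# ---------------------------------------------------------------------------
def save_model(model: MotionModel, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lat = model.lattice
    for i, comp in enumerate(model.components):
        nifti.write_dvf(
            comp.displacements, lat.spacing, lat.origin, out / f"component_{i}.nii.gz",
            direction_tag=f"model-component-{i}",
        )
    meta = dict(
        n_components=len(model.components),
        has_constant=model.has_constant,
        spacing=lat.spacing.tolist(),
        origin=lat.origin.tolist(),
        n_points=list(lat.n_points),
    )
    (out / "model.json").write_text(json.dumps(meta, indent=1))


def load_model(in_dir) -> MotionModel:
    src = Path(in_dir)
    meta = json.loads((src / "model.json").read_text())
    comps = []
    for i in range(meta["n_components"]):
        values, spacing, origin, _ = nifti.read_dvf(src / f"component_{i}.nii.gz")
        comps.append(FFDGrid(spacing=spacing, origin=origin, displacements=values))
    return MotionModel(components=comps, has_constant=meta["has_constant"])


def save_signals(signal: SurrogateSignal, path):
    path = Path(path)
    pd.DataFrame(
        dict(
            t_index=signal.t_indices,
            t_seconds=signal.t_seconds,
            building=signal.building.astype(int),
            **{f"s{i+1}": signal.values[:, i] for i in range(signal.n_components)},
        )
    ).to_csv(path, index=False)
    meta = dict(
        t_r=int(signal.t_r) if signal.t_r is not None else None,
        reference_t_index=int(signal.reference_t_index),
        loadings=np.asarray(signal.loadings).tolist(),
        mean_row=np.asarray(signal.mean_row).tolist(),
        median_value=np.asarray(signal.median_value).tolist(),
        explained_variance_ratio=np.asarray(signal.explained_variance_ratio).tolist(),
        sign_flips=np.asarray(signal.sign_flips).tolist(),
        control_point_mask=np.asarray(signal.meta["control_point_mask"]).astype(int).tolist()
        if "control_point_mask" in signal.meta
        else None,
    )
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def save_motion(motion: GroundTruthMotion, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = dict(
        mode=motion.mode, spacing=motion.spacing.tolist(), origin=motion.origin.tolist(),
        shape=list(motion.shape), pad=motion.pad, max_displacement_mm=motion.max_displacement_mm,
    )
    if motion.mode == "svf":
        p = motion.pad
        org = motion.origin - p * motion.spacing
        nifti.write_dvf(motion.v_A, motion.spacing, org, out / "velocity_a.nii.gz", "svf-A")
        nifti.write_dvf(motion.v_B, motion.spacing, org, out / "velocity_b.nii.gz", "svf-B")
    else:
        for name, grid in (("span_a", motion.W_A), ("span_b", motion.W_B)):
            nifti.write_dvf(grid.displacements, grid.spacing, grid.origin,
                            out / f"{name}.nii.gz", name)
        meta["control_spacing"] = motion.W_A.spacing.tolist()
    (out / "motion.json").write_text(json.dumps(meta, indent=1))


def load_motion(in_dir) -> GroundTruthMotion:
    src = Path(in_dir)
    meta = json.loads((src / "motion.json").read_text())
    kw = dict(
        mode=meta["mode"], spacing=np.asarray(meta["spacing"]), origin=np.asarray(meta["origin"]),
        shape=tuple(meta["shape"]), pad=meta["pad"], max_displacement_mm=meta["max_displacement_mm"],
    )
    if meta["mode"] == "svf":
        vA, *_ = nifti.read_dvf(src / "velocity_a.nii.gz")
        vB, *_ = nifti.read_dvf(src / "velocity_b.nii.gz")
        return GroundTruthMotion(v_A=vA, v_B=vB, **kw)
    WA = FFDGrid(spacing=np.asarray(meta["control_spacing"]),
                 origin=nifti.read_dvf(src / "span_a.nii.gz")[2],
                 displacements=nifti.read_dvf(src / "span_a.nii.gz")[0])
    WB = FFDGrid(spacing=np.asarray(meta["control_spacing"]),
                 origin=nifti.read_dvf(src / "span_b.nii.gz")[2],
                 displacements=nifti.read_dvf(src / "span_b.nii.gz")[0])
    return GroundTruthMotion(W_A=WA, W_B=WB, **kw)


# ---------------------------------------------------------------------------
# application phase
# ---------------------------------------------------------------------------
def apply_model(
    model: MotionModel,
    signal: SurrogateSignal,
    reference_slice: DynamicSlice,
    new_slice: DynamicSlice,
    mcsri: VolumeImage,
    reg_params: RegistrationParams | None = None,
):
    """Estimate the motion state for one new surrogate slice.

    Returns (signal vector, DVF t->r on the MCSRI lattice, deformed image).
    """
    known = np.where(np.asarray(signal.t_indices) == new_slice.t_index)[0]
    if known.size:
        # slice was part of the surrogate stream: its signal is already
        # computed (and exactly zero at the vector-median reference t_r)
        s_t = np.asarray(signal.values[int(known[0])], dtype=np.float64)
    else:
        if new_slice.t_index == signal.reference_t_index:
            row = np.zeros(np.asarray(signal.mean_row).shape[0])
        else:
            res = register_2d(reference_slice, new_slice, reg_params)
            flat = res.params_flat
            mask = signal.meta.get("control_point_mask")
            if mask is not None:
                flat = flat[np.repeat(np.asarray(mask, dtype=bool).ravel(), 2)]
            row = flat
        score = (row - np.asarray(signal.mean_row)) @ np.asarray(signal.loadings).T
        s_t = score - np.asarray(signal.median_value)
    grid = model.params_at(s_t)
    dvf = grid.dvf(mcsri, direction="t->r")
    deformed = warp_pull(mcsri, grid)
    return s_t, dvf, deformed


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------
def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def run_pipeline(config: dict | None = None, out_dir="pipeline_out", log=print) -> dict:
    """simulate -> signals -> fit -> evaluate, with provenance hashes."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    provenance: dict = dict(config=cfg)

    try:
        stage = "simulate"
        phantom, masks = generate_phantom(PhantomSpec(seed=seed, **cfg["phantom"]))
        motion = build_motion(phantom, **cfg["motion"])
        lo, hi = phantom.fov_bounds()
        tum = np.argwhere(masks["tumour"])
        cx = float(phantom.origin[0] + tum[:, 0].mean() * phantom.spacing[0])
        bidx = np.argwhere(masks["body"])
        extent = (phantom.origin + bidx.min(0) * phantom.spacing,
                  phantom.origin + bidx.max(0) * phantom.spacing)
        sched = build_schedule(
            lo, hi, cx, in_plane_spacing=float(phantom.spacing[0]),
            motion_extent=extent, **cfg["schedule"],
        )
        trace = generate_trace(TraceConfig(), len(sched.entries),
                               sched.params["frame_interval"], seed=seed + 1)
        ds = simulate_acquisition(
            phantom, masks, motion, trace, sched,
            noise_sigma_rel=float(cfg["noise_sigma_rel"]), seed=seed + 2,
            building_repetitions=tuple(cfg["building_repetitions"]),
            evaluation_repetitions=tuple(cfg["evaluation_repetitions"]),
        )
        ds.save(out / "dataset")
        save_motion(motion, out / "dataset" / "motion")
        log(f"[simulate] {len(ds.slices)} slices")

        stage = "signals"
        signal = generate_signals(ds)
        save_signals(signal, out / "signals.csv")
        provenance["signals_hash"] = _array_hash(signal.values)
        log(f"[signals] t_r={signal.t_r} "
            f"explained_variance={np.round(signal.explained_variance_ratio, 3).tolist()}")

        stage = "fit"
        fit_cfg = FitConfig(
            control_spacings=tuple(cfg["fit"]["control_spacings"]),
            lambda_be=float(cfg["fit"]["lambda_be"]),
            max_iter_per_level=int(cfg["fit"]["max_iter_per_level"]),
        )
        recon_cfg = ReconConfig(
            n_ibp_iterations=int(cfg["recon"]["n_ibp_iterations"]),
            n_alternations=int(cfg["recon"]["n_alternations"]),
        )
        model, mcsri, alt_log = alternate_fit_reconstruct(ds, fit_cfg, recon_cfg)
        save_model(model, out / "model")
        nifti.write_volume(mcsri, out / "mcsri.nii.gz", description="MCSRI reference image")
        rows = []
        for e in alt_log.entries:
            rows.append(dict(stage=e["stage"], objective=e.get("objective"),
                             final_fidelity=e["fidelity"][-1] if e.get("fidelity") else None))
        pd.DataFrame(rows).to_csv(out / "convergence.csv", index=False)
        # full per-iteration fit objective
        fit_rows = []
        for li, level in enumerate(model.provenance["levels"]):
            for it, obj in enumerate(level["objective"]):
                fit_rows.append(dict(level=li, spacing=level["spacing"], iteration=it,
                                     objective=obj))
        pd.DataFrame(fit_rows).to_csv(out / "fit_log.csv", index=False)
        provenance["model_hash"] = _array_hash(*[c.displacements for c in model.components])
        provenance["mcsri_hash"] = _array_hash(mcsri.values)
        log(f"[fit] components={model.n_signals} lattice={model.lattice.n_points}")

        stage = "evaluate"
        results = {}
        body = masks["body"]
        a_r = ds.trace.state(signal.t_r)
        gt_ref = warp_pull(phantom, motion.dvf(*a_r, direction="backward"))
        slices_b = ds.motion_slices(ds.building_repetitions)
        cache: dict = {}
        avgi = reconstruct_average(slices_b, None, ds.ref_geometry, op_cache=cache)
        sri = reconstruct_ibp(slices_b, None, ds.ref_geometry, cfg=recon_cfg, op_cache=cache)
        results["mae_avgi"] = mae(avgi, gt_ref, body)
        results["mae_sri"] = mae(sri, gt_ref, body)
        results["mae_mcsri"] = mae(mcsri, gt_ref, body)
        eval_reps = ds.evaluation_repetitions or ds.building_repetitions
        per_frame, summary, dfe_map = dfe_analysis(ds, model, eval_reps)
        _, summary_zero, _ = dfe_analysis(ds, None, eval_reps)
        summary.to_csv(out / "dfe_model.csv", index=False)
        summary_zero.to_csv(out / "dfe_zero_model.csv", index=False)
        nifti.write_volume(ds.ref_geometry.copy_with(dfe_map), out / "dfe_mean_map.nii.gz",
                           description="temporal-mean DFE map (mm)")
        res_table, _ = residual_error_registration(ds, model, mcsri, eval_reps, body=body,
                                                   op_cache=cache)
        res_table.to_csv(out / "residual_error.csv", index=False)
        results["dfe_body_model_mm"] = float(summary[summary.roi == "body"]["mean"].iloc[0])
        results["dfe_body_zero_mm"] = float(summary_zero[summary_zero.roi == "body"]["mean"].iloc[0])
        provenance["results"] = results
        log(f"[evaluate] {results}")
    except Exception as err:  # machine-readable failure report
        report = StageError(stage, err).report
        (out / "error.json").write_text(json.dumps(report, indent=1))
        raise

    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))
    return provenance
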