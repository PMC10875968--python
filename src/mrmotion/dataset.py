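"""Dataset container: time-ordered slices, schedule, signals, ground truth.

On disk a dataset is a directory with a ``manifest.csv`` (one row per slice:
path, role, timing, repetition, geometry parameters), uncompressed-geometry
NIfTI slice files, an optional ``trace.csv`` and phantom/mask volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nifti
from .acquisition import SliceSchedule
from .geometry import DynamicSlice, ROIMaskSet, VolumeImage


@dataclass
class SliceDataset:
    slices: list[DynamicSlice]
    schedule: SliceSchedule | None
    ref_geometry: VolumeImage
    trace: object | None = None
    motion: object | None = None
    phantom: VolumeImage | None = None
    masks: ROIMaskSet | None = None
    signals: object | None = None  # SurrogateSignal, attached by the surrogate pipeline
    building_repetitions: tuple[int, ...] = (1, 2, 3)
    evaluation_repetitions: tuple[int, ...] = (4, 5)
    seed: int | None = None
    noise_sigma_rel: float | None = None

    def by_role(self, role: str, repetitions=None) -> list[DynamicSlice]:
        out = []
        for s in self.slices:
            if s.role != role:
                continue
            if repetitions is not None and s.meta.get("repetition") not in repetitions:
                continue
            out.append(s)
        return out

    def motion_slices(self, repetitions=None):
        return self.by_role("motion", repetitions)

    def surrogate_slices(self, repetitions=None):
        return self.by_role("surrogate", repetitions)

    def slice_at(self, t_index: int) -> DynamicSlice:
        for s in self.slices:
            if s.t_index == t_index:
                return s
        raise KeyError(f"no slice with t_index {t_index}")

    # -- persistence ---------------------------------------------------
    def save(self, out_dir):
        out = Path(out_dir)
        (out / "slices").mkdir(parents=True, exist_ok=True)
        rows = []
        for s in self.slices:
            rel = f"slices/t{s.t_index:05d}.nii.gz"
            nifti.write_slice(s, out / rel)
            rows.append(
                dict(
                    path=rel,
                    role=s.role,
                    t_index=s.t_index,
                    t_seconds=s.t_seconds,
                    thickness=s.geometry.thickness,
                    repetition=s.meta.get("repetition"),
                    shift_mm=s.meta.get("shift_mm"),
                    orientation=s.meta.get("orientation"),
                    station=s.meta.get("station"),
                    a1=s.meta.get("a1"),
                    a2=s.meta.get("a2"),
                )
            )
        pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
        nifti.write_volume(self.ref_geometry, out / "ref_geometry.nii.gz")
        if self.phantom is not None:
            nifti.write_volume(self.phantom, out / "phantom.nii.gz")
        if self.masks is not None:
            for name, m in self.masks.masks.items():
                nifti.write_volume(
                    self.ref_geometry.copy_with(m.astype(np.float64)), out / f"mask_{name}.nii.gz"
                )
        if self.trace is not None:
            pd.DataFrame(
                dict(t_seconds=self.trace.t_seconds, a1=self.trace.a1, a2=self.trace.a2)
            ).to_csv(out / "trace.csv", index=False)
        meta = dict(
            building_repetitions=list(self.building_repetitions),
            evaluation_repetitions=list(self.evaluation_repetitions),
            seed=self.seed,
            noise_sigma_rel=self.noise_sigma_rel,
        )
        import json

        (out / "dataset.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, in_dir) -> "SliceDataset":
        import json

        src = Path(in_dir)
        manifest = pd.read_csv(src / "manifest.csv")
        slices = []
        for _, row in manifest.iterrows():
            s = nifti.read_slice(
                src / row["path"],
                t_index=int(row["t_index"]),
                t_seconds=float(row["t_seconds"]),
                role=str(row["role"]),
                thickness=float(row["thickness"]),
            )
            s.meta.update(
                {
                    k: row[k]
                    for k in ("repetition", "shift_mm", "orientation", "station", "a1", "a2")
                    if k in row and not pd.isna(row[k])
                }
            )
            if "repetition" in s.meta:
                s.meta["repetition"] = int(s.meta["repetition"])
            slices.append(s)
        ref = nifti.read_volume(src / "ref_geometry.nii.gz")
        phantom = None
        if (src / "phantom.nii.gz").exists():
            phantom = nifti.read_volume(src / "phantom.nii.gz")
        masks = None
        mask_files = sorted(src.glob("mask_*.nii.gz"))
        if mask_files and phantom is not None:
            masks = ROIMaskSet(
                masks={
                    p.name[len("mask_"):-len(".nii.gz")]: nifti.read_volume(p).values > 0.5
                    for p in mask_files
                },
                reference=phantom,
            )
        meta = json.loads((src / "dataset.json").read_text()) if (src / "dataset.json").exists() else {}
        ds = cls(
            slices=slices,
            schedule=None,
            ref_geometry=ref,
            phantom=phantom,
            masks=masks,
            building_repetitions=tuple(meta.get("building_repetitions", (1, 2, 3))),
            evaluation_repetitions=tuple(meta.get("evaluation_repetitions", (4, 5))),
            seed=meta.get("seed"),
            noise_sigma_rel=meta.get("noise_sigma_rel"),
        )
        if (src / "trace.csv").exists():
            from .simulator import BreathingTrace, TraceConfig

            tr = pd.read_csv(src / "trace.csv")
            dt = float(tr["t_seconds"].iloc[1] - tr["t_seconds"].iloc[0]) if len(tr) > 1 else 0.35
            ds.trace = BreathingTrace(
                a1=tr["a1"].to_numpy(),
                a2=tr["a2"].to_numpy(),
                t_seconds=tr["t_seconds"].to_numpy(),
                frame_interval=dt,
                config=TraceConfig(),
                seed=meta.get("seed", 0) or 0,
            )
        return ds
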