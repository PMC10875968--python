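import numpy as np
import pytest

import mrmotion as mm


@pytest.fixture(scope="session")
def coarse_phantom():
    """Torso phantom at 4 mm (32^3): cheap enough for unit tests."""
    return mm.generate_phantom(mm.PhantomSpec(spacing_mm=4.0, seed=11))


@pytest.fixture(scope="session")
def coarse_dataset(coarse_phantom):
    """Small simulated dataset (one building + one evaluation repetition,
    span-mode motion, noise-free) reused across fitting/reconstruction tests."""
    vol, masks = coarse_phantom
    lo, hi = vol.fov_bounds()
    motion = mm.build_motion(vol, peak_si_mm=10.0, mode="span")
    tum = np.argwhere(masks["tumour"])
    cx = float(vol.origin[0] + tum[:, 0].mean() * vol.spacing[0])
    bidx = np.argwhere(masks["body"])
    extent = (vol.origin + bidx.min(0) * vol.spacing, vol.origin + bidx.max(0) * vol.spacing)
    sched = mm.build_schedule(
        lo, hi, cx, thickness=10.0, in_plane_spacing=4.0, n_repetitions=2,
        motion_extent=extent,
    )
    trace = mm.generate_trace(
        mm.TraceConfig(), len(sched.entries), sched.params["frame_interval"], seed=13
    )
    ds = mm.simulate_acquisition(
        vol, masks, motion, trace, sched, noise_sigma_rel=0.0, seed=13,
        building_repetitions=(1,), evaluation_repetitions=(2,),
    )
    # attach *ground-truth* surrogate signals (median-referenced) so that
    # fitting/reconstruction tests are independent of the surrogate stage
    from scipy.spatial.distance import cdist
    from mrmotion.surrogate import SurrogateSignal

    surr = ds.surrogate_slices()
    bsur = [s for s in surr if s.meta["repetition"] == 1]
    A = np.array([(s.meta["a1"], s.meta["a2"]) for s in bsur])
    i = int(np.argmin(cdist(A, A).sum(1)))
    a_r = A[i]
    t_r = bsur[i].t_index
    for s in ds.motion_slices():
        s.meta["signal"] = np.array([s.meta["a1"] - a_r[0], s.meta["a2"] - a_r[1]])
    ds.signals = SurrogateSignal(
        t_indices=np.array([s.t_index for s in surr]),
        t_seconds=np.array([s.t_seconds for s in surr]),
        values=np.array([(s.meta["a1"] - a_r[0], s.meta["a2"] - a_r[1]) for s in surr]),
        building=np.array([s.meta["repetition"] == 1 for s in surr]),
        reference_t_index=t_r, t_r=t_r, normalised=True,
    )
    return ds


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
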