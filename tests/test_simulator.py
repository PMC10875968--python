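import numpy as np
import pytest

import mrmotion as mm
from mrmotion.simulator import (
    SOFT_TISSUE_INTENSITY,
    SpecError,
    compose_displacement,
    rician,
)


class TestPhantom:
    def test_deterministic(self):
        a, _ = mm.generate_phantom(mm.PhantomSpec(spacing_mm=4.0, seed=5))
        b, _ = mm.generate_phantom(mm.PhantomSpec(spacing_mm=4.0, seed=5))
        assert np.array_equal(a.values, b.values)

    def test_zero_tumour_radius_warns(self):
        with pytest.warns(UserWarning):
            _, masks = mm.generate_phantom(mm.PhantomSpec(spacing_mm=4.0, tumour_radius=0.0))
        assert masks["tumour"].sum() == 0

    def test_tumour_outside_lung_rejected(self):
        with pytest.raises(SpecError):
            mm.generate_phantom(mm.PhantomSpec(spacing_mm=4.0, tumour_centre=(10.0, 10.0, 10.0)))

    def test_mask_nesting(self, coarse_phantom):
        _, masks = coarse_phantom
        assert np.all(masks["tumour"] <= masks["lungs"])
        assert np.all(masks["lungs"] <= masks["body"])
        for a, b in (("lungs", "liver"), ("lungs", "heart"), ("liver", "heart")):
            assert not np.any(masks[a] & masks[b])


class TestTrace:
    def test_zero_jitter_is_periodic(self):
        cfg = mm.TraceConfig(period_jitter_s=0.0, amplitude_jitter=0.0, centre_median=False)
        tr = mm.generate_trace(cfg, 400, 0.25, seed=1)
        period_frames = int(round(4.0 / 0.25))
        assert np.allclose(tr.a1[:-period_frames], tr.a1[period_frames:], atol=1e-12)
        # a2 is the scaled derivative: in quadrature with a1
        assert abs(np.corrcoef(tr.a1, tr.a2)[0, 1]) < 0.2

    def test_seed_reproducible(self):
        a = mm.generate_trace(mm.TraceConfig(), 200, 0.35, seed=9)
        b = mm.generate_trace(mm.TraceConfig(), 200, 0.35, seed=9)
        assert np.array_equal(a.a1, b.a1) and np.array_equal(a.a2, b.a2)

    def test_mean_cycle_period(self):
        """Monte-Carlo over ~100 cycles: the mean period tracks 4 s."""
        tr = mm.generate_trace(mm.TraceConfig(), 1300, 0.35, seed=3)  # ~455 s ~ 110 cycles
        a1 = tr.a1
        # count end-exhale troughs as cycle markers
        troughs = np.where((a1[1:-1] < a1[:-2]) & (a1[1:-1] <= a1[2:])
                           & (a1[1:-1] < np.median(a1)))[0]
        gaps = np.diff(tr.t_seconds[troughs + 1])
        gaps = gaps[gaps > 2.0]
        assert 3.8 <= gaps.mean() <= 4.2

    def test_vector_median_centred(self):
        """The trace's vector-median state (minimal summed distance to all
        states) sits exactly at the origin after centring."""
        from scipy.spatial.distance import cdist

        tr = mm.generate_trace(mm.TraceConfig(), 500, 0.35, seed=4)
        pts = np.column_stack([tr.a1, tr.a2])
        k = int(np.argmin(cdist(pts, pts).sum(axis=1)))
        assert np.linalg.norm(pts[k]) < 1e-12
        # and the scalar median of a1 stays near zero too
        assert abs(np.median(tr.a1)) < 0.2


class TestGroundTruthMotion:
    def test_zero_state_identity(self, coarse_phantom):
        vol, _ = coarse_phantom
        mot = mm.build_motion(vol, 10.0, mode="svf")
        assert np.all(mot.backward_field(0.0, 0.0) == 0.0)

    def test_constant_velocity_is_translation(self):
        vol = mm.VolumeImage(values=np.zeros((16, 16, 16)), spacing=(2, 2, 2), origin=(0, 0, 0))
        mot = mm.build_motion(vol, 10.0, mode="svf")
        c = np.array([3.0, -1.0, 2.0])
        mot.v_A = np.broadcast_to(c, mot.v_A.shape).copy()
        mot.v_B[:] = 0.0
        u = mot.forward_field(1.0, 0.0)
        assert np.allclose(u, c, atol=1e-9)

    def test_invertibility(self, coarse_phantom):
        vol, masks = coarse_phantom
        mot = mm.build_motion(vol, 12.0, mode="svf")
        res = mot.invertibility_residual(0.8, 0.3)
        vox = float(vol.spacing.min())
        body = masks["body"]
        assert (res[body] / vox).mean() < 0.05
        assert (res[body] / vox).max() < 0.25

    def test_compose_identity_and_zero(self, coarse_phantom):
        vol, masks = coarse_phantom
        mot = mm.build_motion(vol, 10.0, mode="svf")
        state = (0.5, 0.1)
        u_same = mot.between_field(state, state)
        body = masks["body"]
        assert np.linalg.norm(u_same, axis=-1)[body].mean() < 0.1
        u_from0 = mot.between_field((0.0, 0.0), state)
        assert np.allclose(u_from0, mot.forward_field(*state), atol=1e-9)

    def test_span_mode_matches_svf_shape(self, coarse_phantom):
        """span and svf describe the same breathing pattern: the span-mode
        field is the B-spline (16 mm lattice) rendition of the analytic
        field the svf mode integrates, so at small amplitude (exp(v) ~ v)
        the two agree in shape and overall magnitude."""
        vol, masks = coarse_phantom
        span = mm.build_motion(vol, 10.0, mode="span")
        svf = mm.build_motion(vol, 10.0, mode="svf")
        a = (0.05, 0.02)
        u1 = span.backward_field(*a)
        u2 = svf.backward_field(*a)
        body = masks["body"]
        v1 = u1[body].ravel()
        v2 = u2[body].ravel()
        cos = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        assert cos > 0.95
        ratio = float(np.linalg.norm(v1) / np.linalg.norm(v2))
        assert 0.6 < ratio < 1.3

    def test_range_error(self, coarse_phantom):
        vol, _ = coarse_phantom
        mot = mm.build_motion(vol, 10.0, mode="svf", max_displacement_mm=12.0)
        with pytest.raises(mm.simulator.RangeError):
            mot.backward_field(5.0, 0.0)

    def test_hysteresis_loop_area(self, coarse_phantom):
        """A probe point traces a loop with nonzero area when a2 is active."""
        vol, masks = coarse_phantom
        mot = mm.build_motion(vol, 10.0, mode="span")
        cfg = mm.TraceConfig(period_jitter_s=0.0, amplitude_jitter=0.0, centre_median=False)
        tr = mm.generate_trace(cfg, 16, 0.25, seed=0)
        tum = np.argwhere(masks["tumour"])
        probe = vol.origin + tum.mean(0) * vol.spacing

        def loop_area(a2_scale):
            pts = []
            for a1, a2 in zip(tr.a1, tr.a2 * a2_scale):
                u = mot.backward_grid(a1, a2).displacement(probe[None])[0]
                pts.append((u[1], u[2]))  # AP-SI plane
            pts = np.asarray(pts)
            x, y = pts[:, 0], pts[:, 1]
            return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

        assert loop_area(0.0) < 1e-9
        assert loop_area(1.0) > 0.05


class TestSimulateAcquisition:
    def test_noise_free_static_matches_acquire(self, coarse_phantom):
        vol, masks = coarse_phantom
        lo, hi = vol.fov_bounds()
        sched = mm.build_schedule(lo, hi, 60.0, in_plane_spacing=4.0, n_repetitions=1)
        mot = mm.build_motion(vol, 10.0, mode="span")
        tr = mm.generate_trace(mm.TraceConfig(), len(sched.entries), 0.35, seed=2)
        tr.a1[:] = 0.0
        tr.a2[:] = 0.0
        ds = mm.simulate_acquisition(vol, masks, mot, tr, sched, noise_sigma_rel=0.0, seed=2)
        for s in ds.slices[:6]:
            direct = mm.acquire_slice(vol, s.geometry)
            assert np.allclose(s.values, direct.values)

    def test_rician_background_mean(self, rng):
        sigma = 5.0
        bg = rician(np.zeros(200_000), sigma, rng)
        assert np.isclose(bg.mean(), sigma * np.sqrt(np.pi / 2.0), rtol=0.01)

    def test_same_seed_bit_identical(self, coarse_phantom):
        vol, masks = coarse_phantom
        lo, hi = vol.fov_bounds()
        sched = mm.build_schedule(lo, hi, 60.0, in_plane_spacing=4.0, n_repetitions=1)
        mot = mm.build_motion(vol, 10.0, mode="span")
        tr = mm.generate_trace(mm.TraceConfig(), len(sched.entries), 0.35, seed=2)
        d1 = mm.simulate_acquisition(vol, masks, mot, tr, sched, noise_sigma_rel=0.05, seed=7)
        d2 = mm.simulate_acquisition(vol, masks, mot, tr, sched, noise_sigma_rel=0.05, seed=7)
        for a, b in zip(d1.slices, d2.slices):
            assert np.array_equal(a.values, b.values)

    def test_noise_level_scales_with_soft_tissue(self, coarse_phantom, rng):
        """noise_sigma_rel is interpreted relative to soft-tissue intensity."""
        sigma = 0.05 * SOFT_TISSUE_INTENSITY
        bg = rician(np.zeros(100_000), sigma, rng)
        assert np.isclose(bg.std(), sigma * np.sqrt(2 - np.pi / 2), rtol=0.02)


def test_compose_displacement_translation():
    u1 = np.zeros((8, 8, 8, 3))
    u1[..., 0] = 2.0
    u2 = np.zeros((8, 8, 8, 3))
    u2[..., 2] = 4.0
    out = compose_displacement(u1, u2, (2.0, 2.0, 2.0))
    inner = out[:6]  # displaced samples stay on the lattice here
    assert np.allclose(inner[..., 0], 2.0) and np.allclose(inner[..., 2], 4.0)
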