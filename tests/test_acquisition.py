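import numpy as np
import pytest

import mrmotion as mm
from mrmotion.acquisition import FWHM_TO_SIGMA, OverlapViolationError


@pytest.fixture()
def small_vol(rng):
    return mm.VolumeImage(values=rng.standard_normal((24, 24, 24)), spacing=(2, 2, 2),
                          origin=(0, 0, 0))


def sagittal_geom(lr=10.0, shape=(20, 20), thickness=10.0):
    return mm.SliceGeometry(
        origin=(lr, 1.0, 2.0),
        in_plane_axes=np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]),
        normal=np.array([1.0, 0.0, 0.0]),
        in_plane_spacing=(2.0, 2.0),
        shape=shape,
        thickness=thickness,
    )


class TestSchedule:
    def test_shift_offsets(self):
        sched = mm.build_schedule((0, 0, 0), (100, 100, 100), 50.0, n_repetitions=1)
        shifts = sorted({e.shift_mm for e in sched.entries})
        assert shifts == [0.0, 2.0, 4.0, 6.0, 8.0]

    def test_counts_and_alternation(self):
        sched = mm.build_schedule((0, 0, 0), (100, 100, 100), 50.0, n_repetitions=1)
        per_shift = [e for e in sched.entries if e.shift_mm == 0.0 and e.repetition == 1]
        n_motion = sum(1 for e in per_shift if e.role == "motion")
        n_surr = sum(1 for e in per_shift if e.role == "surrogate")
        assert n_motion == n_surr
        roles = [e.role for e in sched.entries]
        assert roles[::2] == ["surrogate"] * (len(roles) // 2)
        assert roles[1::2] == ["motion"] * (len(roles) // 2)
        t = [e.t_index for e in sched.entries]
        assert t == sorted(t) and len(set(t)) == len(t)

    def test_repetition_geometry_closure(self):
        sched = mm.build_schedule((0, 0, 0), (80, 80, 80), 40.0, n_repetitions=2)
        rep1 = [e for e in sched.entries if e.repetition == 1]
        rep2 = [e for e in sched.entries if e.repetition == 2]
        assert len(rep1) == len(rep2)
        for a, b in zip(rep1, rep2):
            assert np.allclose(a.geometry.origin, b.geometry.origin)
            assert a.role == b.role and a.shift_mm == b.shift_mm

    def test_overlap_violation(self):
        with pytest.raises(OverlapViolationError):
            mm.build_schedule((0, 0, 0), (80, 80, 80), 40.0, shift_step_mm=3.0, n_shifts=5,
                              thickness=10.0)

    def test_orientation_order(self):
        sched = mm.build_schedule((0, 0, 0), (80, 80, 80), 40.0, n_repetitions=1)
        motion = [e for e in sched.entries if e.role == "motion" and e.shift_mm == 0.0]
        orientations = [e.orientation for e in motion]
        k = orientations.index("axial")
        assert all(o == "sagittal" for o in orientations[:k])
        assert all(o == "axial" for o in orientations[k:])


class TestAcquireSlice:
    def test_sigma_from_fwhm(self, small_vol):
        op = mm.SliceOperator(sagittal_geom(thickness=10.0), small_vol)
        assert np.isclose(op.sigma, 10.0 / FWHM_TO_SIGMA)
        assert np.isclose(op.sigma, 4.2466, atol=1e-4)

    def test_constant_volume(self, small_vol):
        vol = small_vol.copy_with(np.full(small_vol.shape, 7.0))
        s = mm.acquire_slice(vol, sagittal_geom())
        assert np.allclose(s.values[s.valid], 7.0)

    def test_linear_ramp_along_normal(self, small_vol):
        """A symmetric profile averages a linear ramp to its centre value."""
        X = small_vol.axis_coords(0)
        vol = small_vol.copy_with(np.broadcast_to(X[:, None, None] * 0.5 + 2.0,
                                                  small_vol.shape).copy())
        geom = sagittal_geom(lr=23.0)
        s = mm.acquire_slice(vol, geom)
        # interior pixels where the full quadrature support is inside the FOV
        op = mm.SliceOperator(geom, vol)
        full = op.static_valid.all(axis=2)
        assert full.any()
        assert np.allclose(s.values[full], 23.0 * 0.5 + 2.0, atol=1e-9)

    def test_quadrature_truncation(self, small_vol):
        from mrmotion.acquisition import QUADRATURE_PITCH_FACTOR

        op = mm.SliceOperator(sagittal_geom(thickness=10.0), small_vol)
        assert np.abs(op.offsets).max() <= 1.5 * 10.0
        assert np.isclose(op.offsets[1] - op.offsets[0], QUADRATURE_PITCH_FACTOR * 2.0)

    def test_plane_outside_fov(self, small_vol):
        with pytest.raises(Exception):
            mm.acquire_slice(small_vol, sagittal_geom(lr=200.0))


class TestAdjoint:
    @pytest.mark.parametrize("case", range(5))
    def test_adjoint_identity_random_geometry(self, case, rng):
        n = int(rng.integers(16, 28))
        vol = mm.VolumeImage(values=rng.standard_normal((n, n, n)),
                             spacing=rng.uniform(1.5, 3, 3), origin=rng.uniform(-4, 4, 3))
        lo, hi = vol.fov_bounds()
        axis = case % 3
        ip = [a for a in range(3) if a != axis]
        axes = np.zeros((2, 3))
        axes[0, ip[0]] = 1
        axes[1, ip[1]] = 1
        normal = np.zeros(3)
        normal[axis] = 1
        origin = np.zeros(3)
        origin[ip[0]], origin[ip[1]] = lo[ip[0]], lo[ip[1]]
        origin[axis] = rng.uniform(lo[axis], hi[axis])
        geom = mm.SliceGeometry(origin=origin, in_plane_axes=axes, normal=normal,
                                in_plane_spacing=(2, 2), shape=(15, 17), thickness=8.0)
        op = mm.SliceOperator(geom, vol)
        x = rng.standard_normal(vol.shape)
        y = rng.standard_normal(geom.shape)
        ax_, _ = op.forward(x)
        ay, _ = op.adjoint(y)
        lhs = float(np.sum(ax_ * y))
        assert abs(lhs - float(np.sum(x * ay))) <= 1e-6 * max(abs(lhs), 1e-9)

    def test_all_ones_slice_weights_equal_accumulation(self, small_vol):
        op = mm.SliceOperator(sagittal_geom(), small_vol)
        acc, wts = op.adjoint(np.ones(op.geom.shape))
        assert np.allclose(acc, wts)

    def test_slice_outside_fov_zero(self, small_vol):
        slc = mm.DynamicSlice(geometry=sagittal_geom(lr=500.0),
                              values=np.ones((20, 20)), t_index=0, t_seconds=0.0, role="motion")
        acc, wts = mm.adjoint_slice(slc, small_vol)
        assert np.all(acc.values == 0.0) and np.all(wts.values == 0.0)

    def test_schedule_order_invariance(self, small_vol):
        """A on a motion-free volume is independent of acquisition order."""
        sched = mm.build_schedule((0, 0, 0), (46, 46, 46), 23.0, in_plane_spacing=2.0,
                                  n_repetitions=1)
        vals = {}
        for e in sched.entries[:20]:
            s = mm.acquire_slice(small_vol, e.geometry, t_index=e.t_index)
            key = (tuple(e.geometry.origin), tuple(e.geometry.normal))
            if key in vals:
                assert np.array_equal(vals[key], s.values)
            vals[key] = s.values

    def test_schedule_covers_body(self, coarse_phantom):
        """Union of motion-slice supports covers every body voxel."""
        vol, masks = coarse_phantom
        lo, hi = vol.fov_bounds()
        bidx = np.argwhere(masks["body"])
        extent = (vol.origin + bidx.min(0) * vol.spacing, vol.origin + bidx.max(0) * vol.spacing)
        sched = mm.build_schedule(lo, hi, 60.0, in_plane_spacing=4.0, n_repetitions=1,
                                  motion_extent=extent)
        total = np.zeros(vol.shape)
        for e in sched.entries:
            if e.role != "motion":
                continue
            op = mm.SliceOperator(e.geometry, vol)
            _, w = op.adjoint(np.ones(e.geometry.shape))
            total += w
        assert np.all(total[masks["body"]] > 0)
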