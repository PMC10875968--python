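import numpy as np
import pytest

import mrmotion as mm
from mrmotion.surrogate import (
    InsufficientDataError,
    RankError,
    RegistrationParams,
    compute_signals,
    interpolate_to_times,
    normalise_vector_median,
    select_reference_slice,
)


def make_slice(values, t_index, t_seconds=None, role="surrogate"):
    p0, p1 = values.shape
    geom = mm.SliceGeometry(
        origin=(0.0, 0.0, 0.0),
        in_plane_axes=np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]),
        normal=np.array([1.0, 0.0, 0.0]),
        in_plane_spacing=(2.0, 2.0),
        shape=(p0, p1),
        thickness=10.0,
    )
    return mm.DynamicSlice(geometry=geom, values=values, t_index=t_index,
                           t_seconds=t_index * 0.35 if t_seconds is None else t_seconds, role=role)


class TestReferenceSelection:
    def test_majority_image_wins(self, rng):
        I = rng.random((8, 8))
        J = I + 5.0
        cands = [make_slice(I, 0), make_slice(I, 1), make_slice(J, 2)]
        assert select_reference_slice(cands) == 0

    def test_tie_breaks_earliest(self, rng):
        I = rng.random((8, 8))
        cands = [make_slice(I, 4), make_slice(I, 7), make_slice(I, 9)]
        assert select_reference_slice(cands) == 4

    def test_sinusoidal_translation_picks_mid_position(self):
        """A pattern translating sinusoidally: the selected slice is near
        the mid position (phase ~ 0)."""
        x = np.arange(32) * 2.0
        phases = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        cands = []
        for t, ph in enumerate(phases):
            shift = 8.0 * np.sin(ph)
            img = np.exp(-((x[:, None] - 32 - shift) ** 2 + (x[None, :] - 32) ** 2) / 100.0)
            cands.append(make_slice(img, t))
        t_sel = select_reference_slice(cands)
        shift_sel = abs(8.0 * np.sin(phases[t_sel]))
        assert shift_sel < 2.5  # close to the median (zero-shift) position

    def test_too_few_candidates(self, rng):
        with pytest.raises(InsufficientDataError):
            select_reference_slice([make_slice(rng.random((4, 4)), 0)])


class TestRegister2D:
    def test_identity_registration(self, coarse_dataset):
        ref = coarse_dataset.surrogate_slices()[0]
        res = mm.register_2d(ref, ref)
        assert np.abs(res.params_flat).max() < 1e-3

    def test_known_translation_recovered(self, coarse_phantom):
        vol, masks = coarse_phantom
        lo, hi = vol.fov_bounds()
        sched = mm.build_schedule(lo, hi, 60.0, in_plane_spacing=4.0, n_repetitions=1)
        geom = sched.entries[0].geometry
        ref = mm.acquire_slice(vol, geom, role="surrogate")
        # translate the anatomy 4 mm superiorly and re-acquire: aligning the
        # moving slice back onto the reference needs u_SI = +4 mm
        shifted = vol.copy_with(np.roll(vol.values, 1, axis=2))  # 4 mm voxel, SI axis
        mov = mm.acquire_slice(shifted, geom, t_index=1, role="surrogate")
        res = mm.register_2d(ref, mov,
                             RegistrationParams(displacement_weight=0.05, anchor_air_only=True))
        mask = ref.values > 0.2 * np.percentile(ref.values, 99)
        sp = geom.in_plane_spacing
        pix = [np.arange(geom.shape[0]) * sp[0], np.arange(geom.shape[1]) * sp[1]]
        u = res.grid.displacement_on_lattice(pix)
        si = u[..., 1][mask]
        assert abs(si.mean() - 4.0) < 0.5
        assert res.ssd_final < 0.1 * res.ssd_initial

    def test_in_plane_warp_recovered(self, coarse_dataset, rng):
        """A pair related by a known smooth in-plane deformation: the
        registration recovers it, reducing SSD by at least 90%."""
        from mrmotion import interp

        ref = coarse_dataset.surrogate_slices()[0]
        sp = ref.geometry.in_plane_spacing
        extent = ((ref.geometry.shape[0] - 1) * sp[0], (ref.geometry.shape[1] - 1) * sp[1])
        g = mm.FFDGrid.for_fov((0.0, 0.0), extent, 20.0)
        g = g.with_displacements(rng.standard_normal(g.displacements.shape) * 2.0)
        base = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in ref.geometry.shape],
                                    indexing="ij"), axis=-1)
        pix = [np.arange(ref.geometry.shape[a]) * sp[a] for a in range(2)]
        u = g.displacement_on_lattice(pix)
        # moving image such that mov(x + u(x)) == ref(x): pull ref through
        # the inverse mapping is hard, so instead warp ref forward to build
        # mov and register mov back onto the warped image's source
        vals, valid = interp.gather(ref.values, base + u / sp)
        mov = mm.DynamicSlice(geometry=ref.geometry, values=ref.values, t_index=1,
                              t_seconds=0.35, role="surrogate")
        warped_ref = mm.DynamicSlice(geometry=ref.geometry, values=vals, t_index=0,
                                     t_seconds=0.0, role="surrogate", valid=valid)
        res = mm.register_2d(warped_ref, mov,
                             RegistrationParams(displacement_weight=0.05, anchor_air_only=True))
        assert res.ssd_final <= 0.1 * res.ssd_initial

    def test_ssd_reduction_on_breathing_pair(self, coarse_dataset):
        """Thick-slice breathing pair: most of the SSD is explained by the
        in-plane model; through-plane content change leaves a floor."""
        surr = coarse_dataset.surrogate_slices()
        ref = surr[0]
        a_ref = ref.meta["a1"]
        mov = max(surr[:40], key=lambda s: abs(s.meta["a1"] - a_ref))
        res = mm.register_2d(ref, mov,
                             RegistrationParams(displacement_weight=0.05, anchor_air_only=True))
        assert res.ssd_final <= 0.5 * res.ssd_initial


class TestPCASignals:
    def _rows(self, scores, direction, n=60, m=40, noise=0.0, rng=None):
        rows = np.outer(scores, direction)
        if noise:
            rows = rows + rng.normal(0, noise, rows.shape)
        return rows

    def test_line_explains_all_variance(self, rng):
        """Rows on a line through the mean: PC1 carries (essentially) all
        variance; exactly rank-1 data is rejected with a rank error."""
        s = rng.standard_normal(50)
        rows = self._rows(s, rng.standard_normal(40), noise=1e-9, rng=rng)
        sig = compute_signals(rows, np.arange(50), np.arange(50) * 0.35,
                              np.ones(50, bool), mean_si=s.copy(), n_components=2)
        assert sig.explained_variance_ratio[0] > 1.0 - 1e-9
        assert np.abs(sig.values[:, 1]).max() < 1e-6 * np.abs(sig.values[:, 0]).max()
        with pytest.raises(RankError):
            compute_signals(self._rows(s, rng.standard_normal(40)), np.arange(50),
                            np.arange(50) * 0.35, np.ones(50, bool),
                            mean_si=s.copy(), n_components=2)

    def test_pc1_tracks_generating_signal(self, rng):
        s = np.sin(np.linspace(0, 12, 80))
        rows = self._rows(s, rng.standard_normal(50), noise=0.01 * s.std(), rng=rng)
        sig = compute_signals(rows, np.arange(80), np.arange(80) * 0.35,
                              np.ones(80, bool), mean_si=s.copy(), n_components=2)
        assert abs(np.corrcoef(sig.values[:, 0], s)[0, 1]) > 0.99
        # sign convention: positive correlation with the mean SI displacement
        assert np.corrcoef(sig.values[:, 0], s)[0, 1] > 0

    def test_duplicated_rows_invariant(self, rng):
        s = rng.standard_normal(40)
        w = rng.standard_normal((2, 30))
        rows = s[:, None] * w[0] + np.cos(s)[:, None] * w[1]
        sig1 = compute_signals(rows, np.arange(40), np.arange(40.0),
                               np.ones(40, bool), mean_si=s.copy(), n_components=2)
        dup = np.repeat(rows, 2, axis=0)
        sig2 = compute_signals(dup, np.arange(80), np.arange(80.0),
                               np.ones(80, bool), mean_si=np.repeat(s, 2), n_components=2)
        assert np.allclose(sig1.values, sig2.values[::2], atol=1e-8)

    def test_rank_deficiency_raises(self):
        rows = np.ones((10, 6))
        with pytest.raises(RankError):
            compute_signals(rows, np.arange(10), np.arange(10.0), np.ones(10, bool),
                            mean_si=np.ones(10), n_components=2)


class TestVectorMedian:
    def _signal(self, values, building=None):
        n = len(values)
        from mrmotion.surrogate import SurrogateSignal

        return SurrogateSignal(
            t_indices=np.arange(n), t_seconds=np.arange(n) * 0.35,
            values=np.asarray(values, dtype=float),
            building=np.ones(n, bool) if building is None else np.asarray(building),
            reference_t_index=0,
        )

    def test_exhaustive_example(self):
        # sums of distances: (0,0)->10.07, (1,0)->9.64, (0,2)->10.07, (5,5)->19.31
        sig = normalise_vector_median(self._signal([(0, 0), (1, 0), (0, 2), (5, 5)]))
        assert sig.t_r == 1
        assert np.allclose(sig.median_value, (1, 0))
        assert np.allclose(sig.values[1], (0, 0))

    def test_single_element(self):
        sig = normalise_vector_median(self._signal([(3.0, 4.0)]))
        assert sig.t_r == 0 and np.allclose(sig.values, 0.0)

    def test_idempotent(self, rng):
        sig = normalise_vector_median(self._signal(rng.standard_normal((20, 2))))
        again = normalise_vector_median(sig)
        assert np.allclose(sig.values, again.values)
        assert again.t_r == sig.t_r

    def test_zero_at_reference_exact(self, rng):
        sig = normalise_vector_median(self._signal(rng.standard_normal((15, 2))))
        i = int(np.where(sig.t_indices == sig.t_r)[0][0])
        assert np.all(sig.values[i] == 0.0)


class TestInterpolation:
    def _signal(self, t_seconds, values):
        from mrmotion.surrogate import SurrogateSignal

        values = np.asarray(values, dtype=float)
        return SurrogateSignal(
            t_indices=np.arange(len(t_seconds)), t_seconds=np.asarray(t_seconds, float),
            values=values, building=np.ones(len(t_seconds), bool), reference_t_index=0,
        )

    def test_linear_midpoint(self):
        sig = self._signal([0.0, 2.0], [[0.0, 1.0], [4.0, 3.0]])
        out = interpolate_to_times(sig, [1.0])
        assert np.allclose(out, [[2.0, 2.0]])

    def test_coincident_and_boundary(self):
        sig = self._signal([1.0, 2.0, 3.0], [[1, 0], [2, 0], [3, 0]])
        out = interpolate_to_times(sig, [2.0, 0.0, 9.0])
        assert np.allclose(out[:, 0], [2.0, 1.0, 3.0])

    def test_constant_signal(self):
        sig = self._signal([0.0, 1.0, 2.0], [[5, -1]] * 3)
        out = interpolate_to_times(sig, np.linspace(0, 2, 7))
        assert np.allclose(out, [[5, -1]] * 7)
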