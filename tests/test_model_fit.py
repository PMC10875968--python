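import numpy as np
import pytest

import mrmotion as mm
from mrmotion.model import FitConfig, FitProblem, MotionModel, fit, model_lattice_for


@pytest.fixture(scope="module")
def toy_problem():
    """Five motion slices of the static coarse phantom with random signals."""
    vol, _ = mm.generate_phantom(mm.PhantomSpec(fov_mm=(64, 64, 64), spacing_mm=4.0, seed=21))
    lo, hi = vol.fov_bounds()
    sched = mm.build_schedule(lo, hi, float((lo[0] + hi[0]) / 2), in_plane_spacing=4.0,
                              n_repetitions=1)
    rng = np.random.default_rng(5)
    slices = []
    for e in [e for e in sched.entries if e.role == "motion"][:5]:
        s = mm.acquire_slice(vol, e.geometry, t_index=e.t_index)
        s.meta["signal"] = rng.uniform(-1, 1, 2)
        slices.append(s)
    lattice = model_lattice_for(vol, 10.0, 32.0)
    return vol, slices, lattice


class TestModelParams:
    def _model(self, lattice, rng):
        comps = [lattice.with_displacements(rng.standard_normal(lattice.displacements.shape))
                 for _ in range(2)]
        return MotionModel(components=comps)

    def test_zero_signal_zero_motion(self, toy_problem, rng):
        _, _, lattice = toy_problem
        m = self._model(lattice, rng)
        assert np.all(m.params_at((0.0, 0.0)).displacements == 0.0)

    def test_unit_signal_selects_component(self, toy_problem, rng):
        _, _, lattice = toy_problem
        m = self._model(lattice, rng)
        assert np.array_equal(m.params_at((1.0, 0.0)).displacements,
                              m.components[0].displacements)

    def test_linearity(self, toy_problem, rng):
        _, _, lattice = toy_problem
        m = self._model(lattice, rng)
        expect = 2 * m.components[0].displacements + 3 * m.components[1].displacements
        assert np.allclose(m.params_at((2.0, 3.0)).displacements, expect)

    def test_signal_length_mismatch(self, toy_problem, rng):
        _, _, lattice = toy_problem
        m = self._model(lattice, rng)
        with pytest.raises(ValueError):
            m.params_at((1.0, 2.0, 3.0))

    def test_mismatched_lattices_rejected(self, toy_problem, rng):
        _, _, lattice = toy_problem
        with pytest.raises(ValueError):
            MotionModel(components=[lattice.zeros_like(), lattice.refine().zeros_like()])


class TestObjective:
    def test_self_consistent_data_zero_similarity(self, toy_problem):
        vol, slices, lattice = toy_problem
        prob = FitProblem(slices, vol, lattice, lambda_be=0.0)
        f, g = prob(np.zeros(int(np.prod(prob.shape))))
        # slices were acquired from vol with zero motion -> exact match
        assert f < 1e-20
        assert np.abs(g).max() < 1e-10

    def test_noise_floor_equals_variance(self, toy_problem, rng):
        """Adding noise of sd sigma to self-consistent slices puts the
        similarity term near sigma^2 per slice."""
        vol, slices, lattice = toy_problem
        noisy = []
        sigma = 3.0
        for s in slices:
            import copy

            s2 = copy.deepcopy(s)
            s2.values = s2.values + rng.normal(0, sigma, s2.values.shape)
            noisy.append(s2)
        prob = FitProblem(noisy, vol, lattice, lambda_be=0.0, lambda_disp=0.0)
        f, _ = prob(np.zeros(int(np.prod(prob.shape))))
        # similarity is computed on p99-normalised intensities
        assert np.isclose(f / len(slices), (sigma / prob.scale) ** 2, rtol=0.1)

    def test_gradient_matches_finite_differences(self, toy_problem, rng):
        vol, slices, lattice = toy_problem
        prob = FitProblem(slices, vol, lattice, lambda_be=0.01)
        x0 = rng.standard_normal(int(np.prod(prob.shape))) * 0.5
        f0, g0 = prob(x0)
        scale = float(np.abs(g0).max())
        eps = 1e-5
        for idx in rng.integers(0, x0.size, 10):
            xp = x0.copy()
            xp[idx] += eps
            fp, _ = prob(xp)
            xp[idx] -= 2 * eps
            fm, _ = prob(xp)
            fd = (fp - fm) / (2 * eps)
            assert abs(fd - g0[idx]) <= 1e-3 * scale

    def test_signal_scaling_chain_rule(self, toy_problem, rng):
        """Scaling all signals by 2 scales the per-component gradient
        consistently with the chain rule at the zero model."""
        vol, slices, lattice = toy_problem
        import copy

        doubled = []
        for s in slices:
            s2 = copy.deepcopy(s)
            s2.meta["signal"] = 2.0 * np.asarray(s.meta["signal"])
            doubled.append(s2)
        x = rng.standard_normal(int(np.prod((2,) + lattice.displacements.shape))) * 0.1
        p1 = FitProblem(slices, vol, lattice, lambda_be=0.0)
        p2 = FitProblem(doubled, vol, lattice, lambda_be=0.0)
        # at the zero model the data residual is signal-independent, so
        # dC/dR_i doubles with the signals
        _, g1 = p1(np.zeros_like(x))
        _, g2 = p2(np.zeros_like(x))
        assert np.allclose(g2, 2.0 * g1, atol=1e-12)

    def test_shuffled_slice_order_same_objective(self, toy_problem, rng):
        vol, slices, lattice = toy_problem
        x = rng.standard_normal(int(np.prod((2,) + lattice.displacements.shape))) * 0.3
        f1, g1 = FitProblem(slices, vol, lattice, lambda_be=0.01)(x)
        order = rng.permutation(len(slices))
        f2, g2 = FitProblem([slices[i] for i in order], vol, lattice, lambda_be=0.01)(x)
        assert np.isclose(f1, f2, rtol=1e-12)
        assert np.allclose(g1, g2)

    def test_missing_signal_rejected(self, toy_problem):
        vol, slices, lattice = toy_problem
        import copy

        bad = copy.deepcopy(slices)
        del bad[0].meta["signal"]
        with pytest.raises(ValueError):
            FitProblem(bad, vol, lattice, lambda_be=0.0)


class TestFit:
    def test_zero_motion_data_stays_zero(self, toy_problem):
        vol, slices, _ = toy_problem
        cfg = FitConfig(control_spacings=(32.0,), lambda_be=0.01, max_iter_per_level=10)
        model = fit(slices, vol, cfg)
        assert float(np.linalg.norm(model.components[0].displacements, axis=-1).max()) < 0.1
        assert float(np.linalg.norm(model.components[1].displacements, axis=-1).max()) < 0.1

    def test_objective_non_increasing(self, coarse_dataset):
        """The Armijo line search only accepts decreasing steps, so the CG
        path's objective history is non-increasing by construction."""
        ds = coarse_dataset
        cfg = FitConfig(control_spacings=(32.0, 16.0), max_iter_per_level=8, optimizer="cg")
        model = fit(ds.motion_slices(ds.building_repetitions), ds.phantom, cfg)
        for level in model.provenance["levels"]:
            hist = level["objective"]
            assert all(b <= a * (1 + 1e-12) for a, b in zip(hist, hist[1:]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FitConfig(control_spacings=(16.0, 32.0))
        with pytest.raises(ValueError):
            FitConfig(lambda_be=-1.0)
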