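import numpy as np
import pytest

import mrmotion as mm
from mrmotion import bspline
from mrmotion.bspline import SupportError


@pytest.fixture()
def random_grid(rng):
    g = mm.FFDGrid.for_fov((0, 0, 0), (48, 48, 48), 12.0)
    return g.with_displacements(rng.standard_normal(g.displacements.shape) * 2.0)


class TestDisplacement:
    def test_partition_of_unity(self, rng):
        g = mm.FFDGrid.for_fov((0, 0, 0), (40, 40, 40), 10.0)
        c = np.array([3.0, -1.0, 2.0])
        g = g.with_displacements(np.broadcast_to(c, g.displacements.shape).copy())
        pts = rng.uniform(0, 40, (200, 3))
        assert np.allclose(g.displacement(pts), c, atol=1e-12)

    def test_zero_grid(self, rng):
        g = mm.FFDGrid.for_fov((0, 0, 0), (40, 40, 40), 10.0)
        assert np.all(g.displacement(rng.uniform(0, 40, (50, 3))) == 0.0)

    def test_single_kernel_matches_1d_basis_product(self):
        """A unit displacement at one control point reproduces the separable
        cubic B-spline kernel."""
        g = mm.FFDGrid.for_fov((0, 0, 0), (40, 40, 40), 10.0)
        d = np.zeros(g.displacements.shape)
        i, j, k = 4, 4, 4
        d[i, j, k, 0] = 1.0
        g = g.with_displacements(d)
        for off in [(0.0, 0.0, 0.0), (3.0, -4.0, 7.0), (12.5, 5.0, -2.5)]:
            p = g.origin + np.array([i, j, k]) * g.spacing + np.array(off)
            expected = np.prod([float(bspline.bspline3(o / 10.0)) for o in off])
            u = g.displacement(p[None])[0]
            assert np.isclose(u[0], expected, atol=1e-12)
            assert np.allclose(u[1:], 0.0)

    def test_unsupported_point_raises(self, random_grid):
        far = random_grid.origin - 5 * random_grid.spacing
        with pytest.raises(SupportError):
            random_grid.displacement(far[None])


class TestWarpAndSplat:
    def test_identity_transform(self, rng):
        vol = mm.VolumeImage(values=rng.standard_normal((12, 12, 12)), spacing=(2, 2, 2),
                             origin=(0, 0, 0))
        g = mm.FFDGrid.for_fov((0, 0, 0), (22, 22, 22), 8.0)
        out = mm.warp_pull(vol, g)
        assert np.array_equal(out.values, vol.values)

    def test_integer_voxel_shift(self, rng):
        vol = mm.VolumeImage(values=rng.standard_normal((12, 12, 12)), spacing=(2, 2, 2),
                             origin=(0, 0, 0))
        g = mm.FFDGrid.for_fov((0, 0, 0), (22, 22, 22), 8.0)
        g = g.with_displacements(
            np.broadcast_to(np.array([2.0, 0.0, 0.0]), g.displacements.shape).copy()
        )
        out = mm.warp_pull(vol, g)
        assert np.allclose(out.values[:-1][out.valid[:-1]], vol.values[1:][out.valid[:-1]])
        assert not out.valid[-1].any()  # reads past the last LR plane

    def test_linear_ramp_exact(self, rng):
        """Linear interpolation is exact on linear intensity functions."""
        vol = mm.VolumeImage(values=np.zeros((16, 16, 16)), spacing=(2, 2, 2), origin=(0, 0, 0))
        coef = np.array([0.7, -0.3, 1.1])
        X = np.stack(np.meshgrid(*[vol.axis_coords(a) for a in range(3)], indexing="ij"), axis=-1)
        vol = vol.copy_with(X @ coef + 5.0)
        g = mm.FFDGrid.for_fov((0, 0, 0), (30, 30, 30), 10.0)
        g = g.with_displacements(rng.standard_normal(g.displacements.shape) * 1.5)
        out = mm.warp_pull(vol, g)
        u = g.displacement_on_lattice([vol.axis_coords(a) for a in range(3)])
        expected = (X + u) @ coef + 5.0
        assert np.allclose(out.values[out.valid], expected[out.valid], atol=1e-6)

    def test_adjoint_identity(self, rng):
        vol = mm.VolumeImage(values=rng.standard_normal((24, 24, 24)), spacing=(2, 2, 2),
                             origin=(0, 0, 0))
        g = mm.FFDGrid.for_fov((-10, -10, -10), (56, 56, 56), 14.0)
        g = g.with_displacements(rng.standard_normal(g.displacements.shape) * 3)
        y = mm.VolumeImage(values=rng.standard_normal((24, 24, 24)), spacing=(2, 2, 2),
                           origin=(0, 0, 0))
        w = mm.warp_pull(vol, g)
        acc, wts = mm.splat_push(y, g, target_geometry=vol)
        lhs = float(np.sum(w.values * y.values))
        rhs = float(np.sum(vol.values * acc.values))
        assert abs(lhs - rhs) <= 1e-6 * abs(lhs)

    def test_splat_zero_grid_mass(self, rng):
        y = mm.VolumeImage(values=rng.random((10, 10, 10)), spacing=(2, 2, 2), origin=(0, 0, 0))
        g = mm.FFDGrid.for_fov((0, 0, 0), (18, 18, 18), 9.0)
        acc, wts = mm.splat_push(y, g)
        assert np.allclose(acc.values, y.values)
        assert np.allclose(wts.values, 1.0)


class TestBendingEnergy:
    def test_zero_and_affine_fields(self, rng):
        g = mm.FFDGrid.for_fov((0, 0, 0), (40, 40, 40), 10.0)
        be, grad = g.bending_energy((0, 0, 0), (40, 40, 40))
        assert be == 0.0 and np.all(grad == 0.0)
        cp = np.stack(
            np.meshgrid(*[g.origin[a] + np.arange(g.n_points[a]) * g.spacing[a] for a in range(3)],
                        indexing="ij"), axis=-1)
        A = rng.standard_normal((3, 3)) * 0.1
        aff = g.with_displacements(cp @ A.T + rng.standard_normal(3))
        be, _ = aff.bending_energy((0, 0, 0), (40, 40, 40))
        assert be < 1e-25

    def test_nonnegative(self, random_grid):
        be, _ = random_grid.bending_energy()
        assert be > 0.0

    def test_gradient_matches_finite_differences(self, rng):
        g = mm.FFDGrid.for_fov((0, 0, 0), (30, 30, 30), 10.0)
        g = g.with_displacements(rng.standard_normal(g.displacements.shape))
        be0, grad = g.bending_energy((0, 0, 0), (30, 30, 30))
        eps = 1e-5
        for idx in rng.integers(0, grad.size, 15):
            d = g.displacements.ravel().copy()
            d[idx] += eps
            bp, _ = g.with_displacements(d.reshape(grad.shape)).bending_energy((0, 0, 0), (30, 30, 30))
            d[idx] -= 2 * eps
            bm, _ = g.with_displacements(d.reshape(grad.shape)).bending_energy((0, 0, 0), (30, 30, 30))
            fd = (bp - bm) / (2 * eps)
            assert abs(fd - grad.ravel()[idx]) <= 1e-4 * max(abs(fd), np.abs(grad).max())


class TestRefinement:
    def test_zero_and_uniform_preserved(self):
        g = mm.FFDGrid.for_fov((0, 0, 0), (40, 40, 40), 10.0)
        assert np.all(g.refine().displacements == 0.0)
        c = np.array([1.5, -2.0, 0.5])
        gu = g.with_displacements(np.broadcast_to(c, g.displacements.shape).copy())
        fine = gu.refine()
        # uniform away from the lattice boundary (zero-padding affects the rim)
        inner = fine.displacements[3:-3, 3:-3, 3:-3]
        assert np.allclose(inner, c, atol=1e-12)

    def test_field_preserved_at_random_points(self, random_grid, rng):
        fine = random_grid.refine()
        pts = rng.uniform(0, 48, (1000, 3))
        assert np.abs(random_grid.displacement(pts) - fine.displacement(pts)).max() <= 1e-9

    def test_2d_grid_refinement(self, rng):
        g = mm.FFDGrid.for_fov((0, 0), (60, 60), 20.0)
        g = g.with_displacements(rng.standard_normal(g.displacements.shape))
        fine = g.refine()
        pts = rng.uniform(0, 60, (300, 2))
        assert np.abs(g.displacement(pts) - fine.displacement(pts)).max() <= 1e-9
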