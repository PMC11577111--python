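"""Transform-algebra oracles: warping, composition, inversion, velocity
integration, Jacobians, pyramids."""

import numpy as np
import pytest
from scipy.linalg import expm

from bodyatlas.containers import AffineTransform, DisplacementField, Grid, Volume
from bodyatlas.transforms import (
    NonConvergenceError,
    apply_affine_as_field,
    compose,
    downsample,
    integrate_velocity,
    invert,
    jacobian_determinant,
    upsample_field,
    warp_volume,
)

from conftest import smooth_random_field


def constant_field(grid, t):
    return DisplacementField(np.broadcast_to(np.asarray(t, float), grid.shape + (3,)).copy(), grid)


class TestWarpVolume:
    def test_zero_field_is_identity(self, rng):
        grid = Grid((8, 8, 8), (1.0, 1.0, 1.0))
        vol = Volume(rng.random(grid.shape), grid)
        out = warp_volume(vol, DisplacementField.zeros(grid))
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_constant_volume_invariant_inside_domain(self, small_grid):
        vol = Volume(np.full(small_grid.shape, 3.5), small_grid)
        f = smooth_random_field(small_grid, 1.5, seed=1)
        out = warp_volume(vol, f)
        inner = out.data[2:-2, 2:-2, 2:-2]
        np.testing.assert_allclose(inner, 3.5, atol=1e-9)

    def test_one_voxel_translation_matches_index_shift(self):
        # ramp volume shifted by exactly one voxel: index-shift oracle
        grid = Grid((8, 8, 8), (2.0, 2.0, 2.0))
        data = np.arange(512, dtype=float).reshape(8, 8, 8)
        vol = Volume(data, grid)
        f = constant_field(grid, (2.0, 0.0, 0.0))  # +1 voxel along axis 0
        out = warp_volume(vol, f)
        np.testing.assert_allclose(out.data[:-1], data[1:], atol=1e-12)

    def test_grid_mismatch_raises(self, small_grid):
        vol = Volume(np.zeros((4, 4, 4)), Grid((4, 4, 4), (1, 1, 1)))
        bad = np.zeros(small_grid.shape + (2,))
        with pytest.raises(ValueError):
            DisplacementField(bad, small_grid)
        # interpolation name is validated
        with pytest.raises(ValueError):
            warp_volume(vol, DisplacementField.zeros(vol.grid), interpolation="cubic")


class TestCompose:
    def test_zero_is_identity_element(self, small_grid):
        f = smooth_random_field(small_grid, 2.0, seed=2)
        z = DisplacementField.zeros(small_grid)
        np.testing.assert_allclose(compose(f, z).data, f.data, atol=1e-9)
        np.testing.assert_allclose(compose(z, f).data, f.data, atol=1e-9)

    def test_translations_add(self, small_grid):
        t1, t2 = (1.0, -2.0, 0.5), (0.25, 0.5, -1.0)
        c = compose(constant_field(small_grid, t1), constant_field(small_grid, t2))
        np.testing.assert_allclose(c.data, np.broadcast_to(np.add(t1, t2), c.data.shape), atol=1e-9)

    def test_matches_two_step_resampling_oracle(self, small_grid, rng):
        """warp(warp(m, outer), inner) == warp(m, compose(outer, inner))."""
        outer = smooth_random_field(small_grid, 1.2, seed=3)
        inner = smooth_random_field(small_grid, 1.2, seed=4)
        data = np.zeros(small_grid.shape)
        data[4:12, 4:12, 4:12] = rng.random((8, 8, 8))
        from scipy import ndimage

        vol = Volume(ndimage.gaussian_filter(data, 1.5), small_grid)
        two_step = warp_volume(warp_volume(vol, outer), inner)
        one_step = warp_volume(vol, compose(outer, inner))
        inner_region = (slice(3, -3),) * 3
        assert np.abs(two_step.data - one_step.data)[inner_region].max() < 2e-2

    def test_associative_to_interpolation_tolerance(self, small_grid):
        a = smooth_random_field(small_grid, 0.8, seed=5)
        b = smooth_random_field(small_grid, 0.8, seed=6)
        c = smooth_random_field(small_grid, 0.8, seed=7)
        left = compose(compose(a, b), c)
        right = compose(a, compose(b, c))
        inner = (slice(3, -3),) * 3
        assert np.abs(left.data - right.data)[inner].max() < 5e-2


class TestInvert:
    def test_zero_field_self_inverse(self, small_grid):
        inv = invert(DisplacementField.zeros(small_grid))
        np.testing.assert_allclose(inv.data, 0.0, atol=1e-12)

    def test_translation_inverts_exactly(self, small_grid):
        t = (1.5, -0.75, 2.0)
        inv = invert(constant_field(small_grid, t))
        np.testing.assert_allclose(inv.data, np.broadcast_to(np.negative(t), inv.data.shape), atol=1e-9)

    def test_integrated_velocity_roundtrip_below_tenth_voxel(self, small_grid):
        vel = smooth_random_field(small_grid, 3.0, seed=8)
        phi = integrate_velocity(vel, 6)
        phi_inv = invert(phi, tol=0.005, max_iter=100)
        round_trip = compose(phi, phi_inv)
        err = np.sqrt((round_trip.data**2).sum(axis=-1))
        interior = err[3:-3, 3:-3, 3:-3]
        assert interior.max() < 0.1 * min(small_grid.spacing)

    def test_nonconvergence_raises(self, small_grid):
        f = constant_field(small_grid, (5.0, 0.0, 0.0))
        with pytest.raises(NonConvergenceError):
            invert(f, tol=1e-12, max_iter=1)

    def test_negated_velocity_approximates_inverse(self, small_grid):
        vel = smooth_random_field(small_grid, 2.0, seed=9)
        phi_inv = invert(integrate_velocity(vel, 6), tol=0.005, max_iter=100)
        neg = integrate_velocity(vel.with_data(-vel.data), 6)
        err = np.sqrt(((phi_inv.data - neg.data) ** 2).sum(axis=-1))
        assert err[3:-3, 3:-3, 3:-3].max() < 0.1 * min(small_grid.spacing)


class TestIntegrateVelocity:
    def test_zero_velocity_is_identity(self, small_grid):
        out = integrate_velocity(DisplacementField.zeros(small_grid), 6)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_constant_velocity_flows_to_translation(self, small_grid):
        v0 = (1.0, 2.0, -1.5)
        out = integrate_velocity(constant_field(small_grid, v0), 6)
        np.testing.assert_allclose(out.data, np.broadcast_to(v0, out.data.shape), atol=1e-9)

    def test_linear_velocity_matches_matrix_exponential(self):
        # v(x) = B(x - c) flows to (expm(B) - I)(x - c)
        grid = Grid((16, 16, 16), (2.0, 2.0, 2.0), (-15.0, -15.0, -15.0))
        B = np.array([[0.0, 0.05, 0.0], [-0.05, 0.02, 0.0], [0.0, 0.0, -0.03]])
        pts = grid.coordinates()
        vel = DisplacementField(pts @ B.T, grid)
        out = integrate_velocity(vel, 8)
        expected = pts @ (expm(B) - np.eye(3)).T
        err = np.sqrt(((out.data - expected) ** 2).sum(axis=-1))
        scale = np.sqrt((pts**2).sum(axis=-1)) + 1e-9
        interior = (slice(3, -3),) * 3
        assert (err / scale)[interior].max() < 1e-3

    def test_folding_free_for_bounded_velocities(self, small_grid):
        from bodyatlas.evaluation import folding_ratio

        for seed in range(5):
            amp = 0.4 * min(small_grid.spacing) * 2**6 * 0.5
            vel = smooth_random_field(small_grid, min(amp, 6.0), seed=100 + seed)
            assert folding_ratio(integrate_velocity(vel, 6)) == 0.0


class TestJacobianDeterminant:
    def test_zero_field_gives_one(self, small_grid):
        det = jacobian_determinant(DisplacementField.zeros(small_grid))
        np.testing.assert_allclose(det.data, 1.0, atol=1e-12)

    def test_linear_displacement_closed_form(self, small_grid):
        A = np.array([[0.1, 0.02, 0.0], [0.0, -0.05, 0.03], [0.01, 0.0, 0.08]])
        pts = small_grid.coordinates()
        f = DisplacementField(pts @ A.T, small_grid)
        det = jacobian_determinant(f)
        expected = np.linalg.det(np.eye(3) + A)
        inner = det.data[1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(inner, expected, atol=1e-9)

    def test_matches_bruteforce_stencil_oracle(self, small_grid):
        f = smooth_random_field(small_grid, 2.0, seed=11)
        det = jacobian_determinant(f).data
        sp = small_grid.spacing
        # independent per-voxel central-difference stencil in the interior
        u = f.data
        for idx in [(4, 5, 6), (8, 8, 8), (2, 10, 12)]:
            i, j, k = idx
            J = np.eye(3)
            for comp in range(3):
                J[comp, 0] += (u[i + 1, j, k, comp] - u[i - 1, j, k, comp]) / (2 * sp[0])
                J[comp, 1] += (u[i, j + 1, k, comp] - u[i, j - 1, k, comp]) / (2 * sp[1])
                J[comp, 2] += (u[i, j, k + 1, comp] - u[i, j, k - 1, comp]) / (2 * sp[2])
            assert abs(det[idx] - np.linalg.det(J)) < 1e-10

    def test_degenerate_grid_rejected(self):
        g = Grid((2, 5, 5), (1, 1, 1))
        with pytest.raises(ValueError):
            jacobian_determinant(DisplacementField.zeros(g))


class TestPyramid:
    def test_factor_one_unchanged(self, small_grid, rng):
        vol = Volume(rng.random(small_grid.shape), small_grid)
        out = downsample(vol, 1)
        np.testing.assert_allclose(out.data, vol.data)

    def test_constant_volume_preserved(self):
        grid = Grid((16, 16, 16), (1.0, 1.0, 1.0))
        out = downsample(Volume(np.full(grid.shape, 2.5), grid), 2)
        assert out.grid.shape == (8, 8, 8)
        assert out.grid.spacing == (2.0, 2.0, 2.0)
        np.testing.assert_allclose(out.data, 2.5, atol=1e-9)

    def test_ramp_resampled_at_new_centres(self):
        grid = Grid((16, 16, 16), (1.0, 1.0, 1.0))
        pts = grid.coordinates()
        vol = Volume(pts[..., 0].copy(), grid)  # ramp along axis 0
        out = downsample(vol, 2)
        expected = out.grid.coordinates()[..., 0]
        inner = (slice(1, -1),) * 3
        np.testing.assert_allclose(out.data[inner], expected[inner], atol=1e-6)

    def test_factor_exceeding_grid_raises(self, small_grid):
        with pytest.raises(ValueError):
            downsample(Volume(np.zeros(small_grid.shape), small_grid), 20)

    def test_field_upsampling_preserves_mm(self, small_grid):
        f = constant_field(Grid((8, 8, 8), (4.0, 4.0, 4.0)), (1.0, -2.0, 0.5))
        up = upsample_field(f, small_grid)
        np.testing.assert_allclose(up.data, np.broadcast_to((1.0, -2.0, 0.5), up.data.shape), atol=1e-9)


class TestAffineAsField:
    def test_identity_gives_zero_field(self, small_grid):
        f = apply_affine_as_field(AffineTransform.identity(), small_grid)
        np.testing.assert_allclose(f.data, 0.0, atol=1e-12)

    def test_pure_translation_gives_constant_field(self, small_grid):
        t = (3.0, -1.0, 0.5)
        f = apply_affine_as_field(AffineTransform.translation_only(t), small_grid)
        np.testing.assert_allclose(f.data, np.broadcast_to(t, f.data.shape), atol=1e-12)

    def test_right_angle_rotation_permutes_bar(self):
        # 90 deg rotation about z maps an x-aligned bar onto a y-aligned bar
        grid = Grid((9, 9, 9), (1.0, 1.0, 1.0), (-4.0, -4.0, -4.0))
        data = np.zeros(grid.shape)
        data[2:7, 4, 4] = 1.0
        vol = Volume(data, grid)
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        f = apply_affine_as_field(AffineTransform(R, np.zeros(3)), grid)
        out = warp_volume(vol, f, "nearest")
        expected = np.zeros(grid.shape)
        # pull-back: output voxel x takes value of moving at Rx
        for i in range(9):
            for j in range(9):
                for k in range(9):
                    x = np.array([i - 4, j - 4, k - 4], float)
                    y = R @ x
                    yi = np.round(y + 4).astype(int)
                    if np.all((0 <= yi) & (yi < 9)):
                        expected[i, j, k] = data[tuple(yi)]
        np.testing.assert_array_equal(out.data, expected)

    def test_singular_linear_part_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform(np.zeros((3, 3)), np.zeros(3))
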