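"""Forward slice sampling, the z* closed form, irregular splines and
prediction-weighted column resampling."""

import numpy as np
import pytest

from s2v.geometry import RigidParams, make_rigid_matrix, voxel_world_maps
from s2v.resampling import (
    DegenerateGeometryError,
    IrregularColumn,
    bspline_basis,
    build_columns,
    evaluate_on_grid,
    fast_linear_resample,
    fit_irregular_spline,
    forward_model_volume,
    predict_observed_slice,
    prediction_weights,
    reconstruct_volume,
    resample_column_with_predictions,
    resample_volume_rigid,
    solve_zstar,
)
from s2v.temporal import DCTMovementModel, SliceTiming


def _voxel_matrix(r: RigidParams, shape, voxel_size):
    v2w, w2v = voxel_world_maps(shape, voxel_size)
    return w2v @ make_rigid_matrix(r) @ v2w


class TestBsplineBasis:
    def test_tabulated_values(self):
        assert np.isclose(bspline_basis(0.0), 2.0 / 3.0)
        assert np.isclose(bspline_basis(1.0), 1.0 / 6.0)
        assert bspline_basis(2.1) == 0.0
        assert bspline_basis(-2.0) == 0.0

    def test_symmetry(self, rng):
        x = rng.uniform(-3, 3, 50)
        assert np.allclose(bspline_basis(x), bspline_basis(-x))

    def test_partition_of_unity(self, rng):
        for x in rng.uniform(-10, 10, 100):
            j = np.arange(np.floor(x) - 3, np.ceil(x) + 4)
            assert np.isclose(np.sum(bspline_basis(x - j)), 1.0, atol=1e-12)


class TestSolveZstar:
    shape = (16, 16, 10)

    def test_identity_transform(self):
        Rinv = np.eye(4)
        xp, yp, z = solve_zstar(3.0, 5.0, 4, Rinv)
        assert (xp, yp, z) == (3.0, 5.0, 4.0)

    def test_pure_z_translation_matches_linear_solve(self):
        r = RigidParams(dz=1.7)
        M = _voxel_matrix(r, self.shape, 1.0)
        Rinv = np.linalg.inv(M)
        x, y, s = 2.0, 3.0, 5
        xp, yp, z = solve_zstar(x, y, s, Rinv)
        # oracle: dense linear solve of Rinv [x, y, z*, 1] = [x', y', s, 1]
        # with unknowns u = (x', y', z*)
        A = np.array(
            [
                [1.0, 0.0, -Rinv[0, 2]],
                [0.0, 1.0, -Rinv[1, 2]],
                [0.0, 0.0, -Rinv[2, 2]],
            ]
        )
        b = np.array(
            [
                Rinv[0, 0] * x + Rinv[0, 1] * y + Rinv[0, 3],
                Rinv[1, 0] * x + Rinv[1, 1] * y + Rinv[1, 3],
                Rinv[2, 0] * x + Rinv[2, 1] * y + Rinv[2, 3] - s,
            ]
        )
        sol = np.linalg.solve(A, b)
        assert np.allclose([xp, yp, z], sol, atol=1e-10)
        # documented sign convention: +dz movement samples deeper slices
        assert np.isclose(z, 5 + 1.7)

    def test_random_rotation_satisfies_plane_equation(self, rng):
        """The closed form solves the slice-plane equation to 1e-10."""
        for _ in range(200):
            r = RigidParams(*rng.normal(scale=[1, 1, 1, 0.05, 0.05, 0.05]))
            M = _voxel_matrix(r, self.shape, 2.5)
            Rinv = np.linalg.inv(M)
            x, y = rng.uniform(0, 15, 2)
            s = int(rng.integers(0, 10))
            xp, yp, z = solve_zstar(x, y, s, Rinv)
            lhs = Rinv @ np.array([x, y, z, 1.0])
            assert np.allclose(lhs, [xp, yp, s, 1.0], atol=1e-10)

    def test_degenerate_geometry_error(self):
        Rinv = np.eye(4)
        Rinv[2, 2] = 1e-8
        with pytest.raises(DegenerateGeometryError):
            solve_zstar(0.0, 0.0, 0, Rinv)


class TestForwardModel:
    def test_zero_movement_reproduces_slice(self, small_phantom, small_timing):
        vol = small_phantom.truth[0]
        model = DCTMovementModel.zeros(0, small_timing.n_times)
        for s in (0, 5, 11):
            sl, inside = predict_observed_slice(
                vol, model, small_timing, s, voxel_size=2.5
            )
            assert np.allclose(sl, vol[:, :, s], atol=1e-6 * vol.max())
            assert inside.all()

    def test_constant_movement_equals_volumetric_resampling(
        self, small_phantom, small_timing
    ):
        """Stacked forward slices with M=0 movement == rigid volume resample."""
        vol = small_phantom.truth[0]
        r = RigidParams(1.2, -0.8, 0.9, 0.03, -0.02, 0.04)
        model = DCTMovementModel.constant(r, small_timing.n_times)
        fwd, _ = forward_model_volume(vol, model, small_timing, voxel_size=2.5)
        oracle = resample_volume_rigid(vol, r, voxel_size=2.5)
        assert np.max(np.abs(fwd - oracle)) < 1e-5 * np.ptp(vol)

    def test_integer_z_translation_shifts_slices(self, small_phantom, small_timing):
        vol = small_phantom.truth[0]
        model = DCTMovementModel.constant(
            RigidParams(dz=2.5), small_timing.n_times  # exactly one voxel
        )
        sl, _ = predict_observed_slice(vol, model, small_timing, 4, voxel_size=2.5)
        assert np.allclose(sl, vol[:, :, 5], atol=1e-9 * vol.max())


class TestBuildColumns:
    def test_zero_movement_columns_are_input(self, small_phantom, small_timing):
        vol = small_phantom.truth[0]
        model = DCTMovementModel.zeros(0, small_timing.n_times)
        cs = build_columns(vol, model, small_timing, voxel_size=2.5)
        col = cs.column(10, 12)
        assert np.allclose(col.zstar, np.arange(small_timing.n_slices))
        assert np.allclose(col.g, vol[10, 12, :], atol=1e-8 * vol.max())

    def test_mb_group_zstar_coplanar(self, small_phantom):
        """Slices of one MB group share a transform, so their z* values are
        parallel-plane offsets: z*(s) - s is the same function of (x, y)."""
        timing = SliceTiming.interleaved(12, mb_factor=3)
        vol = small_phantom.truth[0]
        trace = np.zeros((timing.n_times, 6))
        trace[:, 3] = np.linspace(0, 0.05, timing.n_times)  # growing x-rotation
        cs = build_columns(vol, trace, timing, voxel_size=2.5)
        g0 = timing.groups[2]  # one MB group
        # shared transform -> the z* planes of the group's slices are
        # parallel: their difference is constant over (x, y)
        offsets = [cs.zstar[s] - s for s in g0]
        assert np.ptp(offsets[0] - offsets[1]) < 1e-9
        assert np.ptp(offsets[0] - offsets[2]) < 1e-9

    def test_looking_up_rotation_creates_duplicates_and_gaps(self, small_phantom):
        """A mid-volume pitch rotation duplicates z* coverage on one side of
        the head and leaves a gap on the other (deck-of-cards geometry)."""
        timing = SliceTiming.sequential(12)
        vol = small_phantom.truth[0]
        trace = np.zeros((timing.n_times, 6))
        trace[6:, 3] = 0.12  # ~7 deg pitch from slice 6 on
        cs = build_columns(vol, trace, timing, voxel_size=2.5)
        nx, ny, nz = vol.shape
        # per documented geometry, z* of rotated slices moves oppositely at
        # the front and back of the in-plane y axis
        front, back = 3, ny - 4
        z_front = np.sort(cs.zstar[:, nx // 2, front])
        z_back = np.sort(cs.zstar[:, nx // 2, back])
        gap_front = np.max(np.diff(z_front))
        gap_back = np.max(np.diff(z_back))
        # one side has a widened gap, the other compressed/duplicated coverage
        assert max(gap_front, gap_back) > 1.5
        assert min(np.min(np.diff(z_front)), np.min(np.diff(z_back))) < 0.7


class TestIrregularSpline:
    def test_interpolates_at_integer_samples(self, rng):
        n = 12
        g = rng.normal(size=n)
        c = fit_irregular_spline((np.arange(n, dtype=float), g), n, lam=1e-12)
        y = evaluate_on_grid(c, n)
        assert np.allclose(y, g, atol=1e-8)

    def test_constant_column_reproduced(self):
        z = np.array([0.3, 1.7, 2.2, 4.9, 6.5, 8.0])
        g = np.full_like(z, 3.5)
        c = fit_irregular_spline((z, g), 9, lam=0.5)
        assert np.allclose(evaluate_on_grid(c, 9), 3.5, atol=1e-9)

    def test_noisy_sine_reconstruction_below_noise(self, rng):
        """Irregularly sampled noisy sine: reconstruction RMSE to the true
        curve stays below the sample noise SD."""
        n_grid = 20
        z = np.sort(rng.uniform(0, n_grid - 1, 60))
        true = np.sin(2 * np.pi * z / 19)
        noise_sd = 0.15
        g = true + rng.normal(scale=noise_sd, size=z.size)
        c = fit_irregular_spline((z, g), n_grid, lam=1.0)
        y = evaluate_on_grid(c, n_grid)
        truth_grid = np.sin(2 * np.pi * np.arange(n_grid) / 19)
        rmse = np.sqrt(np.mean((y - truth_grid) ** 2))
        assert rmse < noise_sd

    def test_evaluate_zero_coefficients(self):
        assert np.allclose(evaluate_on_grid(np.zeros(12), 10), 0.0)

    def test_single_unit_coefficient_gives_basis_column(self):
        n = 10
        c = np.zeros(n + 2)
        c[4] = 1.0  # basis function centred at grid point 3
        y = evaluate_on_grid(c, n)
        assert np.allclose(y, bspline_basis(np.arange(n) - 3.0))

    def test_matches_direct_spline_summation(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 16))
            c = rng.normal(size=n + 2)
            y = evaluate_on_grid(c, n)
            i = np.arange(n)[:, None]
            j = np.arange(n + 2)[None, :] - 1
            direct = (bspline_basis(i - j) * c[None, :]).sum(axis=1)
            assert np.allclose(y, direct, atol=1e-12)

    def test_large_lam_tends_to_straight_line(self, rng):
        z = np.sort(rng.uniform(0, 11, 30))
        g = 2.0 + 0.5 * z + rng.normal(scale=0.3, size=30)
        c = fit_irregular_spline((z, g), 12, lam=1e8)
        y = evaluate_on_grid(c, 12)
        # residual from the best-fitting straight line is tiny
        A = np.column_stack([np.ones(12), np.arange(12.0)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.max(np.abs(y - A @ coef)) < 1e-4


class TestPredictionWeights:
    def test_close_bracket_gives_zero(self):
        # brackets narrower than one grid step never admit predictions
        w = prediction_weights(np.array([-0.1, 0.9, 1.1, 1.9, 2.1, 2.9]), 3)
        assert np.allclose(w, 0.0)

    def test_single_bracketed_point(self):
        # dz = 1.1 bracketing exactly grid point 1: w = dz - 1
        w = prediction_weights(np.array([0.7, 1.8]), 3)
        assert np.isclose(w[1], 0.1)
        assert np.isclose(w[2], 1.0)  # outside the last observation

    def test_two_bracketed_points_distance_rule(self):
        w = prediction_weights(np.array([0.75, 2.25]), 4)
        assert np.isclose(w[1], 0.25)
        assert np.isclose(w[2], 0.25)
        assert np.isclose(w[1] + w[2], 0.5)

    def test_two_bracketed_points_asymmetric(self):
        w = prediction_weights(np.array([0.9, 2.5]), 4)
        assert np.isclose(w[1], 0.1)
        assert np.isclose(w[2], 0.5)

    def test_three_plus_bracketed_points_middle_capped(self):
        w = prediction_weights(np.array([0.8, 4.3]), 6)
        assert np.isclose(w[2], 1.0)  # interior points capped at 1
        assert np.isclose(w[3], 1.0)
        assert np.isclose(w[1], 0.2)  # distance to nearest observation
        assert np.isclose(w[4], 0.3)
        # bracket total: dz - 1
        assert np.isclose(w[1:5].sum(), 3.5 - 1.0)

    def test_bracket_total_rule(self, rng):
        """Total prediction weight in any bracket of width 1 < dz <= 3 is
        dz - 1 (the consistent reading of the printed heuristic)."""
        for _ in range(200):
            lo = rng.uniform(0, 3)
            dz = rng.uniform(1.0 + 1e-6, 3.0)
            zs = np.array([lo, lo + dz])
            n_grid = 8
            w = prediction_weights(zs, n_grid)
            inside = [
                i
                for i in range(n_grid)
                if lo + 1e-9 < i < lo + dz - 1e-9
            ]
            if not inside:
                continue
            assert np.isclose(w[inside].sum(), dz - 1.0, atol=1e-9)

    def test_exact_tie_counts_as_observation(self):
        w = prediction_weights(np.array([0.0, 2.0, 4.0]), 5)
        assert w[0] == 0.0 and w[2] == 0.0 and w[4] == 0.0
        # grid points 1 and 3 lie in dz = 2 brackets: w = dz - 1 = 1
        assert np.isclose(w[1], 1.0)
        assert np.isclose(w[3], 1.0)

    def test_outside_points_pure_prediction(self):
        w = prediction_weights(np.array([3.4, 4.6]), 9)
        assert np.allclose(w[:3], 1.0)
        assert np.allclose(w[6:], 1.0)


class TestWeightedResampling:
    def test_zero_weights_match_plain_spline(self, rng):
        n = 10
        z = np.sort(rng.uniform(0, n - 1, 25))
        g = np.cos(z)
        p = rng.normal(size=n)  # irrelevant
        y_w = resample_column_with_predictions((z, g), p, np.zeros(n), lam=0.01)
        c = fit_irregular_spline((z, g), n, lam=0.01)
        y = evaluate_on_grid(c, n)
        assert np.allclose(y_w, y, atol=1e-10)

    def test_gap_filled_toward_truth_predictions(self):
        """A three-slice gap with weight-1 truth predictions lands within 2%
        of the truth on a smooth profile."""
        n = 12
        grid = np.arange(n, dtype=float)
        truth = 50 + 40 * np.sin(grid / 3.0)
        z = np.concatenate([grid[:4], grid[8:]]) + 0.01
        g = 50 + 40 * np.sin(z / 3.0)
        w = prediction_weights(z, n)
        y = resample_column_with_predictions((z, g), truth, w, lam=0.01)
        gap = slice(4, 8)
        assert np.max(np.abs(y[gap] - truth[gap])) < 0.02 * np.ptp(truth)

    def test_matches_dense_weighted_normal_equations(self, rng):
        from s2v.resampling import _design_irregular, _design_regular, _penalty_D

        n = 8
        z = np.sort(rng.uniform(0, n - 1, 14))
        g = rng.normal(size=14)
        p = rng.normal(size=n)
        w = rng.uniform(0, 1, n)
        lam = 0.05
        y = resample_column_with_predictions((z, g), p, w, lam=lam)
        Wi = _design_irregular(z, n)
        Wr = _design_regular(n)
        A = np.vstack([Wi, np.diag(w) @ Wr])
        b = np.concatenate([g, w * p])
        c = np.linalg.solve(A.T @ A + lam * _penalty_D(n), A.T @ b)
        assert np.allclose(y, Wr @ c, atol=1e-8)


class TestFastLinear:
    def test_exact_at_integer_nodes(self, rng):
        g = rng.normal(size=7)
        col = IrregularColumn(g, np.arange(7.0), np.arange(7))
        assert np.allclose(fast_linear_resample(col, 7), g)

    def test_midpoint_interpolation(self):
        col = IrregularColumn([0.0, 2.0], [0.0, 2.0], [0, 1])
        y = fast_linear_resample(col, 3)
        assert np.isclose(y[1], 1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fast_linear_resample(IrregularColumn([1.0], [0.5], [0]), 4)

    def test_close_to_spline_on_smooth_column(self, small_phantom):
        vol = small_phantom.truth[0]
        g = vol[12, 12, :]
        z = np.arange(g.size, dtype=float)
        col = IrregularColumn(g, z, np.arange(g.size))
        y_lin = fast_linear_resample(col, g.size)
        c = fit_irregular_spline(col, g.size, lam=1e-10)
        y_spl = evaluate_on_grid(c, g.size)
        assert np.max(np.abs(y_lin - y_spl)) < 0.05 * np.ptp(g)


class TestReconstructVolume:
    def test_zero_movement_identity(self, small_phantom, small_timing):
        vol = small_phantom.truth[0]
        model = DCTMovementModel.zeros(0, small_timing.n_times)
        out, dens = reconstruct_volume(
            vol, model, small_timing, mode="spline", voxel_size=2.5, lam=1e-8
        )
        interior = np.zeros(vol.shape, bool)
        interior[1:-1, 1:-1, 1:-1] = True
        assert np.max(np.abs(out - vol)[interior]) < 1e-6 * vol.max()
        assert np.allclose(dens[interior], 0.0)  # samples sit on the grid

    def test_forward_inverse_roundtrip_correlation(self, small_phantom, small_timing, rng):
        """Forward-then-inverse with smooth movement: correlation > 0.99 in
        fully observed regions."""
        vol = small_phantom.truth[0]
        b = np.zeros((3, 6))
        b[0] = [0.5, -0.5, 0.8, 0.01, -0.01, 0.015]
        b[1] = [0.6, 0.4, -0.7, 0.02, 0.015, -0.01]
        b[2] = [-0.2, 0.3, 0.3, -0.008, 0.01, 0.006]
        model = DCTMovementModel(b, small_timing.n_times)
        obs, _ = forward_model_volume(vol, model, small_timing, voxel_size=2.5)
        rec, dens = reconstruct_volume(
            obs, model, small_timing, mode="spline", voxel_size=2.5, lam=1e-4
        )
        interior = np.zeros(vol.shape, bool)
        interior[2:-2, 2:-2, 2:-2] = True
        observed_ok = interior & (dens < 1.1)
        c = np.corrcoef(rec[observed_ok], vol[observed_ok])[0, 1]
        assert c > 0.99

    def test_gap_filled_toward_predictions_or_smoothness(self, small_phantom):
        """Mid-volume pitch rotation leaves unobserved z-ranges; with truth
        predictions the fill lands near truth, without them it is the
        smoothest-curve fill and deviates more."""
        timing = SliceTiming.sequential(12)
        vol = small_phantom.truth[0]
        trace = np.zeros((timing.n_times, 6))
        trace[6:, 3] = 0.25  # ~14 deg pitch halfway through
        obs, _ = forward_model_volume(vol, trace, timing, voxel_size=2.5)
        rec_p, dens = reconstruct_volume(
            obs, trace, timing, prediction=vol, mode="spline", voxel_size=2.5
        )
        rec_s, _ = reconstruct_volume(
            obs, trace, timing, mode="spline", voxel_size=2.5
        )
        gap = np.isinf(dens) | (dens > 2.0)
        gap &= vol > 0.3 * vol.max()
        assert gap.sum() > 10
        err_p = np.abs(rec_p[gap] - vol[gap]).mean()
        err_s = np.abs(rec_s[gap] - vol[gap]).mean()
        assert err_p < err_s
        assert err_p < 0.1 * vol.max()


class TestDisplacementFields:
    def test_constant_pe_field_equals_translation(self, small_phantom, small_timing):
        """A spatially constant phase-encode displacement field acts exactly
        like the corresponding in-plane translation in the forward model,
        and the inverse model undoes it when given the same field."""
        from s2v.resampling import DisplacementField

        vol = small_phantom.truth[0]
        N = small_timing.n_times
        d = DisplacementField(np.full(vol.shape, 3.0), "susceptibility", axis=1)
        m0 = DCTMovementModel.zeros(0, N)
        fwd_f, _ = forward_model_volume(
            vol, m0, small_timing, voxel_size=2.5, fields=[d]
        )
        m_t = DCTMovementModel.constant(RigidParams(dy=3.0), N)
        fwd_t, _ = forward_model_volume(vol, m_t, small_timing, voxel_size=2.5)
        assert np.allclose(fwd_f, fwd_t, atol=1e-9 * vol.max())

        cs = build_columns(fwd_f, m0, small_timing, voxel_size=2.5, fields=[d])
        interior = slice(4, -4)
        x = 12
        for y in range(6, 18):
            col = cs.column(x, y)
            keep = (col.slices >= 4) & (col.slices < small_timing.n_slices - 4)
            assert np.allclose(
                col.g[keep], vol[x, y, col.slices[keep]],
                atol=2e-2 * vol.max(),
            )

    def test_mismatched_field_grid_rejected(self, small_phantom, small_timing):
        from s2v.resampling import DisplacementField

        vol = small_phantom.truth[0]
        bad = DisplacementField(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="grid"):
            forward_model_volume(
                vol, DCTMovementModel.zeros(0, small_timing.n_times),
                small_timing, voxel_size=2.5, fields=[bad],
            )
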