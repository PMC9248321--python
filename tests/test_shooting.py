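import numpy as np
import pytest

from lgrbsn.fields import Grid
from lgrbsn.shooting import (
    KernelSpec,
    LandmarkCorrespondence,
    hamiltonian,
    kernel_matrix,
    optimize_momentum,
    rasterize_field,
    register_region,
    shoot,
)
from lgrbsn.shooting import _objective_and_grad


class TestKernelMatrix:
    def test_reference_values(self):
        k = KernelSpec(1.0)
        assert kernel_matrix([[0, 0]], [[0, 0]], k)[0, 0] == 1.0
        assert kernel_matrix([[0, 0]], [[1, 0]], k)[0, 0] == pytest.approx(
            np.exp(-0.5), abs=1e-12
        )
        assert kernel_matrix([[0, 0]], [[10, 0]], k)[0, 0] < 1e-21

    def test_symmetric_unit_diagonal(self, rng):
        pts = rng.normal(size=(7, 3))
        K = kernel_matrix(pts, pts, KernelSpec(2.0))
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), 1.0)

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            KernelSpec(0.0)


class TestShoot:
    def test_single_landmark_travels_straight(self):
        # gradient of K vanishes at zero separation: unit-speed straight geodesic
        st = shoot([[0.0, 0.0]], [[1.0, 0.0]], KernelSpec(1.0), steps=20)
        assert np.allclose(st.q[-1], [[1.0, 0.0]], atol=1e-12)
        assert np.allclose(st.p, st.p[0])

    def test_zero_momentum_is_stationary(self, rng):
        q0 = rng.normal(size=(4, 2))
        st = shoot(q0, np.zeros_like(q0), KernelSpec(1.0), steps=5)
        assert np.allclose(st.q, q0)
        assert hamiltonian(st.q[-1], st.p[-1], st.kernel) == 0.0

    def test_distant_landmarks_decouple(self):
        k = KernelSpec(1.0)
        q0 = np.array([[0.0, 0.0], [10.0, 0.0]])  # 10 sigma apart
        p0 = np.array([[0.6, 0.2], [-0.5, 0.1]])
        st = shoot(q0, p0, k, steps=40)
        for i in range(2):
            solo = shoot(q0[i : i + 1], p0[i : i + 1], k, steps=40)
            assert np.abs(st.q[-1, i] - solo.q[-1, 0]).max() < 1e-6

    @pytest.mark.parametrize("n_landmarks", [1, 10])
    def test_hamiltonian_conserved_at_20_steps(self, n_landmarks, rng):
        q0 = rng.normal(scale=2.0, size=(n_landmarks, 2))
        p0 = rng.normal(size=(n_landmarks, 2))
        drift20 = shoot(q0, p0, KernelSpec(1.0), steps=20).hamiltonian_drift()
        assert drift20 < 0.01
        drift40 = shoot(q0, p0, KernelSpec(1.0), steps=40).hamiltonian_drift()
        assert drift40 <= drift20 + 1e-14

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            shoot([[np.nan, 0.0]], [[1.0, 0.0]], KernelSpec(1.0))
        with pytest.raises(ValueError):
            shoot([[0.0, 0.0]], [[1.0, 0.0]], KernelSpec(1.0), steps=0)


class TestAdjointGradient:
    def test_matches_finite_differences(self, rng):
        kernel = KernelSpec(1.5)
        q0 = rng.normal(size=(5, 2))
        corr = LandmarkCorrespondence(q0, q0 + rng.normal(scale=0.7, size=(5, 2)), 0.1)
        p0 = rng.normal(size=(5, 2)) * 0.5
        _, grad, _ = _objective_and_grad(p0, corr, kernel, steps=8)
        eps = 1e-6
        for i in range(5):
            for d in range(2):
                dp = np.zeros_like(p0)
                dp[i, d] = eps
                jp = _objective_and_grad(p0 + dp, corr, kernel, 8)[0]
                jm = _objective_and_grad(p0 - dp, corr, kernel, 8)[0]
                assert grad[i, d] == pytest.approx((jp - jm) / (2 * eps), rel=1e-5, abs=1e-7)


class TestOptimizeMomentum:
    def test_already_matched_needs_no_momentum(self, rng):
        pts = rng.normal(size=(4, 2))
        res = optimize_momentum(LandmarkCorrespondence(pts, pts, 0.25), KernelSpec(1.0))
        assert np.allclose(res.initial_momentum, 0.0)
        assert res.objective_trace[-1] == 0.0

    def test_single_pair_recovers_unit_translation(self):
        corr = LandmarkCorrespondence([[0.0, 0.0]], [[1.0, 0.0]], 1e-4)
        res = optimize_momentum(corr, KernelSpec(1.0), steps=20)
        assert np.linalg.norm(res.state.q[-1] - [[1.0, 0.0]]) < 0.01
        assert res.initial_momentum[0] == pytest.approx([1.0, 0.0], rel=0.02, abs=0.02)

    def test_rigid_translation_with_wide_kernel(self):
        moving = np.array([[0.0, 0.0], [1.0, 0.0]])
        corr = LandmarkCorrespondence(moving, moving + [1.0, 0.0], 1e-4)
        res = optimize_momentum(corr, KernelSpec(10.0), steps=20, max_iter=500)
        err = np.linalg.norm(res.state.q[-1] - (moving + [1.0, 0.0]), axis=1)
        assert err.max() < 0.01
        p = res.initial_momentum
        assert np.linalg.norm(p[0] - p[1]) < 0.01 * np.linalg.norm(p[0])

    def test_trace_non_increasing_under_backtracking(self, rng):
        q0 = rng.normal(size=(6, 2))
        corr = LandmarkCorrespondence(q0, q0 + rng.normal(scale=0.5, size=(6, 2)), 0.01)
        res = optimize_momentum(corr, KernelSpec(1.0), steps=10, max_iter=50)
        assert np.all(np.diff(res.objective_trace) <= 1e-12)

    def test_exact_matching_limit(self):
        # matching error decreases monotonically as the covariance tightens
        errs = []
        for cov in (1.0, 0.1, 0.01, 1e-4):
            corr = LandmarkCorrespondence([[0.0, 0.0]], [[1.0, 0.0]], cov)
            res = optimize_momentum(corr, KernelSpec(1.0), steps=20, max_iter=500)
            errs.append(np.linalg.norm(res.state.q[-1] - [[1.0, 0.0]]))
        assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))

    def test_lbfgs_agrees_with_gd(self):
        corr = LandmarkCorrespondence([[0.0, 0.0]], [[1.0, 0.0]], 1e-4)
        res = optimize_momentum(corr, KernelSpec(1.0), steps=20, method="lbfgs")
        assert np.linalg.norm(res.state.q[-1] - [[1.0, 0.0]]) < 0.01


class TestRasterize:
    def test_zero_momentum_gives_zero_field(self):
        st = shoot([[3.0, 3.0]], [[0.0, 0.0]], KernelSpec(1.0), steps=5)
        f = rasterize_field(st, Grid((8, 8)), "forward")
        assert np.allclose(f.values, 0.0)

    def test_single_landmark_field_values(self):
        sigma = 1.0
        st = shoot([[8.0, 8.0]], [[1.0, 0.0]], KernelSpec(sigma), steps=40)
        grid = Grid((32, 32), spacing=(0.5, 0.5))
        f = rasterize_field(st, grid, "forward")
        # at the landmark the field reproduces its displacement
        assert np.allclose(f.values[16, 16], [1.0, 0.0], atol=5e-3)
        # ten kernel widths away the Gaussian velocity is negligible
        assert np.linalg.norm(f.values[0, 0]) < 1e-6

    def test_forward_reverse_inverse_consistency(self):
        kernel = KernelSpec(3.0)
        moving = np.array([[10.0, 10.0], [14.0, 12.0]])
        fixed = np.array([[12.0, 11.0], [15.0, 14.0]])
        res = optimize_momentum(
            LandmarkCorrespondence(moving, fixed, 1e-4), kernel, steps=40, max_iter=300
        )
        grid = Grid((24, 24))
        fwd = rasterize_field(res.state, grid, "forward")
        rev = rasterize_field(res.state, grid, "reverse")
        from lgrbsn.fields import compose_field_with_map

        r = fwd.values + compose_field_with_map(rev, fwd.as_map()).values
        err = np.linalg.norm(r, axis=-1)
        assert np.quantile(err, 0.99) < 0.1  # 0.1 * spacing for 99% of grid points


class TestRegisterRegion:
    def test_identity_correspondence_gives_zero_fields(self, rng):
        pts = rng.uniform(4, 12, size=(5, 2))
        grid = Grid((16, 16))
        fwd, rev, match = register_region(
            LandmarkCorrespondence(pts, pts, 0.25), KernelSpec(2.0), grid, grid
        )
        assert np.abs(fwd.values).max() < 1e-9
        assert np.abs(rev.values).max() < 1e-9

    def test_swapping_roles_swaps_fields(self):
        kernel = KernelSpec(3.0)
        grid = Grid((24, 24))
        moving = np.array([[10.0, 10.0], [14.0, 12.0]])
        fixed = np.array([[12.0, 11.0], [15.0, 14.0]])
        f_ab, r_ab, _ = register_region(
            LandmarkCorrespondence(moving, fixed, 1e-4), kernel, grid, grid,
            steps=40, max_iter=300,
        )
        f_ba, r_ba, _ = register_region(
            LandmarkCorrespondence(fixed, moving, 1e-4), kernel, grid, grid,
            steps=40, max_iter=300,
        )
        # forward of one direction approximates the reverse of the other
        diff = np.linalg.norm(f_ab.values - r_ba.values, axis=-1)
        assert np.quantile(diff, 0.99) < 0.1

    def test_regional_fields_are_diffeomorphic(self):
        from lgrbsn.fields import count_nonpositive_jacobian

        kernel = KernelSpec(3.0)
        grid = Grid((24, 24))
        moving = np.array([[10.0, 10.0], [14.0, 12.0], [8.0, 15.0]])
        fixed = moving + np.array([[2.0, 1.0], [1.0, 2.0], [-1.0, 1.0]])
        fwd, rev, _ = register_region(
            LandmarkCorrespondence(moving, fixed, 1e-4), kernel, grid, grid,
            steps=40, max_iter=300,
        )
        assert count_nonpositive_jacobian(fwd.as_map()) == 0
        assert count_nonpositive_jacobian(rev.as_map()) == 0

    def test_landmark_interpolation_property(self):
        # the rasterized forward field reproduces each landmark's endpoint
        kernel = KernelSpec(3.0)
        grid = Grid((24, 24))
        moving = np.array([[10.0, 10.0], [14.0, 12.0]])
        fixed = np.array([[12.0, 11.0], [15.0, 14.0]])
        match = optimize_momentum(
            LandmarkCorrespondence(moving, fixed, 1e-4), kernel, steps=40, max_iter=300
        )
        fwd = rasterize_field(match.state, grid, "forward")
        from lgrbsn.fields import sample_field

        endpoints = moving + sample_field(fwd, moving)
        assert np.abs(endpoints - match.state.q[-1]).max() < 0.02


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_divergence_raises_actionable_error():
    # a denormal covariance overflows the matching gradient immediately
    corr = LandmarkCorrespondence([[0.0, 0.0]], [[1e3, 0.0]], 1e-305)
    with pytest.raises(FloatingPointError, match="step_size|covariance"):
        optimize_momentum(corr, KernelSpec(1.0), steps=5, max_iter=3)
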