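"""Unit tests for the clustering level-set core."""

import numpy as np
import pytest

from conftest import random_image, random_state
from oracles import (
    double_loop_energy,
    minimize_bias_pixel,
    minimize_center,
)

from lgcw.core import (
    EnergyParams,
    Image2D,
    LevelSetState,
    compute_energy,
    data_force,
    evolve_level_set,
    gaussian_kernel,
    initialize_level_set,
    segment_lgscm,
    smoothed_delta,
    smoothed_heaviside,
    update_bias_field,
    update_cluster_centers,
)
from lgcw.errors import (
    DegenerateRegionError,
    InitializationError,
    InvalidParameterError,
    ShapeError,
)


class TestGaussianKernel:
    def test_normalized_and_symmetric(self):
        k = gaussian_kernel(1.0, 3)
        assert k.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(k.weights, np.rot90(k.weights, 2))

    def test_center_weight_matches_direct_formula(self):
        k = gaussian_kernel(0.5, 1)
        ax = np.arange(-1, 2, dtype=float)
        xx, yy = np.meshgrid(ax, ax, indexing="ij")
        ref = np.exp(-(xx**2 + yy**2) / (2 * 0.25))
        ref /= ref.sum()
        assert k.weights[1, 1] == pytest.approx(ref[1, 1], rel=1e-12)

    def test_default_radius_rule(self):
        assert gaussian_kernel(4.0).radius == 8

    def test_rejects_bad_parameters(self):
        with pytest.raises(InvalidParameterError):
            gaussian_kernel(0.0)
        with pytest.raises(InvalidParameterError):
            gaussian_kernel(1.0, 0)


class TestSmoothedHeaviside:
    def test_half_at_zero_and_limits(self):
        assert smoothed_heaviside(0.0, 1.0) == pytest.approx(0.5)
        assert smoothed_heaviside(1e9, 1.0) == pytest.approx(1.0, abs=1e-6)
        assert smoothed_heaviside(-1e9, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_value_at_epsilon(self):
        # H(eps) = 0.5 + atan(1)/pi = 0.75 for the arctan profile
        assert smoothed_heaviside(1.0, 1.0) == pytest.approx(0.75)

    def test_monotone_and_bounded(self):
        x = np.linspace(-50, 50, 1001)
        h = smoothed_heaviside(x, 2.0)
        assert np.all(np.diff(h) > 0)
        assert h.min() >= 0 and h.max() <= 1

    def test_delta_is_derivative(self):
        x = np.linspace(-5, 5, 11)
        eps = 1.3
        fd = (smoothed_heaviside(x + 1e-6, eps) - smoothed_heaviside(x - 1e-6, eps)) / 2e-6
        assert np.allclose(fd, smoothed_delta(x, eps), atol=1e-6)


class TestClusterCenters:
    def test_constant_image_gives_constant_centers(self, small_kernel, rng):
        img = Image2D(np.full((8, 8), 42.0))
        state = random_state(rng)
        state.bias = np.ones((8, 8))
        t1, t2 = update_cluster_centers(img, state, small_kernel)
        assert t1 == pytest.approx(42.0)
        assert t2 == pytest.approx(42.0)

    def test_crisp_two_region_image_recovers_region_means(self, small_kernel):
        P = np.full((8, 8), 10.0)
        P[:, 4:] = 200.0
        phi = np.full((8, 8), 1e12)  # |phi| huge: memberships crisp to ~1e-12
        phi[:, 4:] = -1e12  # interior (cluster 1) = right half
        state = LevelSetState(phi=phi, epsilon=1.0, bias=np.ones((8, 8)), centers=(0.0, 0.0))
        t1, t2 = update_cluster_centers(Image2D(P), state, small_kernel)
        assert t1 == pytest.approx(200.0, abs=1e-6)
        assert t2 == pytest.approx(10.0, abs=1e-6)

    def test_empty_region_is_degenerate(self, small_kernel):
        P = Image2D(np.full((8, 8), 5.0))
        state = LevelSetState(
            phi=np.full((8, 8), 1e12),  # interior membership ~ 0
            epsilon=1e-8,
            bias=np.ones((8, 8)),
            centers=(0.0, 0.0),
        )
        with pytest.raises(DegenerateRegionError):
            update_cluster_centers(P, state, small_kernel)

    def test_matches_numerical_minimizer_and_does_not_increase_energy(
        self, small_kernel, rng
    ):
        params = EnergyParams(length_weight=0, distreg_weight=0)
        for _ in range(5):
            img = random_image(rng)
            state = random_state(rng)
            before = compute_energy(img, state, small_kernel, params).data
            t1, t2 = update_cluster_centers(img, state, small_kernel)
            ref1 = minimize_center(
                img.pixels, state.phi, 1.0, state.bias, state.centers[1], 1,
                small_kernel.weights, small_kernel.radius,
            )
            ref2 = minimize_center(
                img.pixels, state.phi, 1.0, state.bias, state.centers[0], 2,
                small_kernel.weights, small_kernel.radius,
            )
            assert t1 == pytest.approx(ref1, abs=1e-6)
            assert t2 == pytest.approx(ref2, abs=1e-6)
            state.centers = (t1, t2)
            after = compute_energy(img, state, small_kernel, params).data
            assert after <= before + 1e-9 * abs(before)


class TestBiasField:
    def test_perfect_fit_gives_unit_bias(self, small_kernel):
        img = Image2D(np.full((8, 8), 42.0))
        state = LevelSetState(
            phi=np.zeros((8, 8)), epsilon=1.0, bias=np.ones((8, 8)), centers=(42.0, 42.0)
        )
        e = update_bias_field(img, state, small_kernel)
        assert np.allclose(e, 1.0, atol=1e-12)

    def test_scaled_image_gives_scaled_bias(self, small_kernel):
        P = np.full((8, 8), 10.0)
        P[:, 4:] = 100.0
        phi = np.where(np.arange(8)[None, :] >= 4, -1e12, 1e12) * np.ones((8, 1))
        state = LevelSetState(
            phi=phi, epsilon=1.0, bias=np.ones((8, 8)), centers=(100.0, 10.0)
        )
        e = update_bias_field(Image2D(2 * P), state, small_kernel)
        assert np.allclose(e, 2.0, atol=1e-9)

    def test_matches_per_pixel_numerical_minimizer(self, small_kernel, rng):
        img = random_image(rng)
        state = random_state(rng)
        e = update_bias_field(img, state, small_kernel)
        for n in [(0, 0), (3, 4), (7, 7), (5, 1)]:
            ref = minimize_bias_pixel(
                img.pixels, state.phi, 1.0, *state.centers, n,
                small_kernel.weights, small_kernel.radius,
            )
            assert e[n] == pytest.approx(ref, abs=1e-6)

    def test_update_does_not_increase_energy(self, small_kernel, rng):
        params = EnergyParams(length_weight=0, distreg_weight=0)
        img = random_image(rng)
        state = random_state(rng)
        before = compute_energy(img, state, small_kernel, params).data
        state.bias = update_bias_field(img, state, small_kernel)
        after = compute_energy(img, state, small_kernel, params).data
        assert after <= before + 1e-9 * abs(before)


class TestEnergy:
    def test_perfect_fit_has_zero_data_term(self, small_kernel):
        # P = e * t1 everywhere and t2 = t1, so residuals vanish for both
        # clusters regardless of the membership split
        img = Image2D(np.full((8, 8), 100.0))
        state = LevelSetState(
            phi=np.full((8, 8), -2.0), epsilon=1.0, bias=np.ones((8, 8)),
            centers=(100.0, 100.0),
        )
        e = compute_energy(img, state, small_kernel, EnergyParams(length_weight=0, distreg_weight=0))
        assert e.data == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_scaling_of_residuals(self, small_kernel, rng):
        img = random_image(rng)
        state = random_state(rng, centers=(0.0, 0.0))  # residual = P itself
        params = EnergyParams(length_weight=0, distreg_weight=0)
        e1 = compute_energy(img, state, small_kernel, params).data
        img2 = Image2D(2.0 * img.pixels)
        e2 = compute_energy(img2, state, small_kernel, params).data
        assert e2 == pytest.approx(4.0 * e1, rel=1e-12)

    def test_matches_double_loop_oracle(self, small_kernel, rng):
        params = EnergyParams(length_weight=0, distreg_weight=0)
        for _ in range(3):
            img = random_image(rng, shape=(6, 6))
            state = random_state(rng, shape=(6, 6))
            mine = compute_energy(img, state, small_kernel, params).data
            ref = double_loop_energy(
                img.pixels, state.phi, 1.0, state.bias, *state.centers,
                small_kernel.weights, small_kernel.radius,
            )
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_shape_mismatch_raises(self, small_kernel, rng):
        img = random_image(rng, shape=(8, 8))
        state = random_state(rng, shape=(6, 6))
        with pytest.raises(ShapeError):
            compute_energy(img, state, small_kernel, EnergyParams())


class TestEvolveLevelSet:
    def test_null_step_leaves_phi_unchanged(self, small_kernel, rng):
        img = random_image(rng)
        state = random_state(rng)
        params = EnergyParams(time_step=0.0, length_weight=0, distreg_weight=0)
        out = evolve_level_set(img, state, small_kernel, params)
        assert np.array_equal(out.phi, state.phi)

    def test_zero_force_at_perfect_fit(self, small_kernel):
        img = Image2D(np.full((8, 8), 100.0))
        state = LevelSetState(
            phi=np.full((8, 8), -5.0), epsilon=1.0, bias=np.ones((8, 8)),
            centers=(100.0, 100.0),
        )
        force = data_force(img, state, small_kernel)
        assert np.max(np.abs(force)) < 1e-12

    def test_force_sign_matches_finite_difference_gradient(self, small_kernel, rng):
        img = random_image(rng)
        state = random_state(rng)
        params = EnergyParams(length_weight=0, distreg_weight=0)
        force = data_force(img, state, small_kernel)
        h = 1e-5
        for i in range(0, 8, 2):
            for j in range(0, 8, 3):
                up = state.phi.copy()
                up[i, j] += h
                down = state.phi.copy()
                down[i, j] -= h
                e_up = compute_energy(
                    img, LevelSetState(up, 1.0, state.bias, state.centers),
                    small_kernel, params,
                ).data
                e_dn = compute_energy(
                    img, LevelSetState(down, 1.0, state.bias, state.centers),
                    small_kernel, params,
                ).data
                grad = (e_up - e_dn) / (2 * h)
                if abs(grad) > 1e-8:
                    assert np.sign(force[i, j]) == np.sign(-grad)

    def test_outer_iteration_never_increases_total_energy(self, small_kernel, rng):
        img = random_image(rng, shape=(16, 16))
        state = random_state(rng, shape=(16, 16))
        params = EnergyParams()
        e0 = compute_energy(img, state, small_kernel, params).total
        for _ in range(5):
            state = evolve_level_set(img, state, small_kernel, params)
            assert state.energy <= e0 + 1e-6 * abs(e0)
            e0 = state.energy


class TestInitialization:
    def test_centered_circle_area(self):
        img = Image2D(np.zeros((64, 64)))
        state = initialize_level_set(img, "centered-circle", radius=20)
        area = state.interior_mask().sum()
        assert abs(area - np.pi * 400) / (np.pi * 400) < 0.05

    def test_user_roi_rectangle_is_exact(self):
        img = Image2D(np.zeros((32, 32)))
        state = initialize_level_set(img, "user-roi", roi=(5, 8, 15, 20))
        inside = state.interior_mask()
        expected = np.zeros((32, 32), bool)
        expected[5:15, 8:20] = True
        assert np.array_equal(inside, expected)

    def test_threshold_mode_selects_brighter_level(self):
        P = np.full((32, 32), 20.0)
        P[10:20, 10:20] = 200.0
        state = initialize_level_set(Image2D(P), "threshold")
        assert np.array_equal(state.interior_mask(), P > 100)

    def test_empty_region_raises(self):
        img = Image2D(np.zeros((16, 16)))
        with pytest.raises(InitializationError):
            initialize_level_set(img, "user-roi", roi=(5, 5, 5, 5))

    def test_bias_starts_at_one_and_centers_are_region_means(self):
        P = np.full((16, 16), 10.0)
        P[4:12, 4:12] = 90.0
        state = initialize_level_set(Image2D(P), "user-roi", roi=(4, 4, 12, 12))
        assert np.all(state.bias == 1.0)
        assert state.centers[0] == pytest.approx(90.0)
        assert state.centers[1] == pytest.approx(10.0)


class TestSegmentLgscm:
    def test_constant_image_warns_and_converges_immediately(self):
        img = Image2D(np.full((16, 16), 37.0))
        with pytest.warns(UserWarning, match="constant image"):
            mask, state, log = segment_lgscm(img, EnergyParams(max_outer_iters=5))
        assert state.centers[0] == state.centers[1] == pytest.approx(37.0)
        assert len(log) == 1

    def test_too_small_image_rejected(self):
        with pytest.raises(ShapeError):
            segment_lgscm(Image2D(np.zeros((4, 4))))

    def test_clean_two_region_image_segments_exactly(self):
        P = np.full((48, 48), 20.0)
        rr, cc = np.meshgrid(np.arange(48), np.arange(48), indexing="ij")
        disc = (rr - 24) ** 2 + (cc - 24) ** 2 <= 12**2
        P[disc] = 200.0
        params = EnergyParams(max_outer_iters=60)
        mask, state, log = segment_lgscm(Image2D(P), params)
        from lgcw.metrics import dice

        assert dice(disc, mask) >= 0.98
        energies = [rec.e_total for rec in log]
        assert all(
            b <= a + 1e-6 * abs(a) for a, b in zip(energies, energies[1:])
        )
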