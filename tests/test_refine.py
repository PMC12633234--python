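"""Cross-correlation loss, gradients, AdaBelief refinement, FSC, mismatch."""

import numpy as np
import pytest

from cryosim import (
    ImageConfig,
    ImageStack,
    RealVoxelVolume,
    RefinementProblem,
    cross_correlation_loss,
    fourier_shell_correlation,
    loss_gradient_wrt_centers,
    make_refinement_fixture,
    mismatch_score,
    rasterize_gmm,
    refine_centers,
    simulate_image,
)


@pytest.fixture(scope="module")
def small_problem():
    """4 noiseless images of a 10-atom mixture; model starts displaced."""
    truth, start, stack = make_refinement_fixture(
        n_atoms=10, n_images=4, snr=1e9, perturbation_scale=2.0, seed=17
    )
    cfg = ImageConfig((64, 64), 1.0)
    return truth, start, stack, cfg


class TestCrossCorrelationLoss:
    def test_identical_images_give_minus_one(self, rng):
        img = rng.normal(size=(32, 32))
        assert cross_correlation_loss(img, img) == pytest.approx(-1.0, abs=1e-12)

    def test_negated_image_gives_plus_one(self, rng):
        img = rng.normal(size=(32, 32))
        assert cross_correlation_loss(img, -img) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        img = rng.normal(size=(32, 32))
        assert cross_correlation_loss(img, 3.0 * img + 7.0) == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_correlation_loss(np.zeros((8, 8)), rng.normal(size=(8, 8)))


class TestGradient:
    def test_matches_central_finite_differences(self, small_problem, rng):
        truth, start, stack, cfg = small_problem
        prob = RefinementProblem(stack, start, cfg)
        c0 = start.centers.copy()
        _, grad = loss_gradient_wrt_centers(prob, c0)
        h = 1e-3
        for _ in range(8):
            i, j = rng.integers(0, c0.shape[0]), rng.integers(0, 3)
            cp, cm = c0.copy(), c0.copy()
            cp[i, j] += h
            cm[i, j] -= h
            lp, _ = loss_gradient_wrt_centers(prob, cp)
            lm, _ = loss_gradient_wrt_centers(prob, cm)
            fd = (lp - lm) / (2 * h)
            assert grad[i, j] == pytest.approx(fd, rel=1e-4)

    def test_stationary_at_ground_truth_on_noiseless_images(self, small_problem):
        truth, _, stack, cfg = small_problem
        clean = np.stack(
            [
                simulate_image(truth, stack.poses[i], stack.ctfs[i], cfg).pixels
                for i in range(len(stack))
            ]
        )
        clean_stack = ImageStack(clean, 1.0, stack.poses, stack.ctfs)
        prob = RefinementProblem(clean_stack, truth, cfg)
        loss, grad = loss_gradient_wrt_centers(prob, truth.centers)
        assert loss == pytest.approx(-len(stack), abs=1e-9)
        assert np.linalg.norm(grad) < 1e-6

    def test_displaced_center_gradient_points_back_to_truth(self):
        truth, _, stack = make_refinement_fixture(
            n_atoms=1, n_images=1, snr=1e9, perturbation_scale=0.0, seed=3
        )
        cfg = ImageConfig((64, 64), 1.0)
        prob = RefinementProblem(stack, truth, cfg)
        displaced = truth.centers + np.array([[2.0, 0.0, 0.0]])
        _, grad = loss_gradient_wrt_centers(prob, displaced)
        # minimizing the loss must push x back toward the truth
        assert grad[0, 0] > 0

    def test_stack_gradient_is_sum_of_per_image_gradients(self, small_problem):
        truth, start, stack, cfg = small_problem
        total = np.zeros_like(start.centers)
        for i in range(len(stack)):
            sub = ImageStack(
                stack.images[i : i + 1], 1.0, [stack.poses[i]], [stack.ctfs[i]]
            )
            _, g = loss_gradient_wrt_centers(
                RefinementProblem(sub, start, cfg), start.centers
            )
            total += g
        _, full = loss_gradient_wrt_centers(
            RefinementProblem(stack, start, cfg), start.centers
        )
        np.testing.assert_allclose(full, total, atol=1e-9)


class TestRefineCenters:
    def test_zero_steps_rejected(self, small_problem):
        _, start, stack, cfg = small_problem
        with pytest.raises(ValueError):
            refine_centers(RefinementProblem(stack, start, cfg), 0)

    def test_single_step_at_optimum_barely_moves_loss(self, small_problem):
        truth, _, stack, cfg = small_problem
        clean = np.stack(
            [
                simulate_image(truth, stack.poses[i], stack.ctfs[i], cfg).pixels
                for i in range(len(stack))
            ]
        )
        clean_stack = ImageStack(clean, 1.0, stack.poses, stack.ctfs)
        prob = RefinementProblem(clean_stack, truth, cfg)
        trace = refine_centers(prob, 2, learning_rate=1e-2)
        assert abs(trace.losses[1] - trace.losses[0]) < 1e-9

    def test_recovery_reduces_loss_and_distance(self):
        truth, start, stack = make_refinement_fixture(
            n_atoms=10, n_images=8, snr=0.1, perturbation_scale=3.0, seed=23
        )
        cfg = ImageConfig((64, 64), 1.0)
        prob = RefinementProblem(stack, start, cfg)
        trace = refine_centers(prob, 40, learning_rate=0.1)
        assert trace.losses[-1] < trace.losses[0]
        d_start = np.linalg.norm(start.centers - truth.centers, axis=1).mean()
        d_final = np.linalg.norm(trace.final_centers - truth.centers, axis=1).mean()
        assert d_final < d_start

    def test_identical_settings_give_bitwise_identical_traces(self, small_problem):
        _, start, stack, cfg = small_problem
        prob = RefinementProblem(stack, start, cfg)
        a = refine_centers(prob, 5, learning_rate=0.05, seed=1)
        b = refine_centers(prob, 5, learning_rate=0.05, seed=1)
        np.testing.assert_array_equal(a.losses, b.losses)
        np.testing.assert_array_equal(a.final_centers, b.final_centers)


class TestFSC:
    def test_self_correlation_is_one_in_every_shell(self, rng):
        vol = RealVoxelVolume(rng.normal(size=(32, 32, 32)), 1.0)
        curve = fourier_shell_correlation(vol, vol)
        good = ~np.isnan(curve.correlation)
        np.testing.assert_allclose(curve.correlation[good], 1.0, atol=1e-9)

    def test_scale_invariance(self, rng):
        a = RealVoxelVolume(rng.normal(size=(32, 32, 32)), 1.0)
        b = RealVoxelVolume(2.0 * a.grid, 1.0)
        curve = fourier_shell_correlation(a, b)
        good = ~np.isnan(curve.correlation)
        np.testing.assert_allclose(curve.correlation[good], 1.0, atol=1e-9)

    def test_independent_noise_volumes_decorrelate(self, rng):
        a = RealVoxelVolume(rng.normal(size=(64, 64, 64)), 1.0)
        b = RealVoxelVolume(rng.normal(size=(64, 64, 64)), 1.0)
        curve = fourier_shell_correlation(a, b)
        big = curve.shell_counts >= 100
        assert np.nanmean(np.abs(curve.correlation[big])) < 0.1

    def test_shape_mismatch_rejected(self, rng):
        a = RealVoxelVolume(rng.normal(size=(16, 16, 16)), 1.0)
        b = RealVoxelVolume(rng.normal(size=(32, 32, 32)), 1.0)
        with pytest.raises(ValueError):
            fourier_shell_correlation(a, b)


class TestMismatchScore:
    def _vol(self, values):
        return RealVoxelVolume(values, 1.0)

    def test_equal_volumes_score_zero(self):
        u0 = self._vol(np.full((8, 8, 8), 2.0))
        s, n_masked = mismatch_score(u0, u0)
        assert n_masked == 0
        np.testing.assert_allclose(s.grid, 0.0, atol=1e-12)

    def test_missing_density_scores_plus_one(self):
        u0 = self._vol(np.full((8, 8, 8), 2.0))
        u = self._vol(np.zeros((8, 8, 8)))
        s, _ = mismatch_score(u0, u)
        np.testing.assert_allclose(s.grid, 1.0, atol=1e-12)

    def test_spurious_density_scores_minus_one(self):
        u0 = self._vol(np.zeros((8, 8, 8)))
        u = self._vol(np.full((8, 8, 8), 2.0))
        u0.grid[0, 0, 0] = 1.0  # max(u0) must be positive for the threshold
        s, _ = mismatch_score(u0, u)
        assert s.grid[4, 4, 4] == pytest.approx(-1.0, abs=1e-12)

    def test_empty_space_masked_and_counted(self):
        u0 = np.zeros((8, 8, 8))
        u0[4, 4, 4] = 1.0
        s, n_masked = mismatch_score(self._vol(u0), self._vol(np.zeros((8, 8, 8))))
        assert np.isnan(s.grid[0, 0, 0])
        assert n_masked == 8**3 - 1
        assert s.grid[4, 4, 4] == pytest.approx(1.0)


class TestFixture:
    def test_zero_perturbation_start_equals_truth(self):
        truth, start, _ = make_refinement_fixture(5, 2, 1.0, 0.0, seed=9)
        np.testing.assert_array_equal(truth.centers, start.centers)

    def test_same_seed_reproduces_everything(self):
        a = make_refinement_fixture(5, 3, 0.5, 1.0, seed=4)
        b = make_refinement_fixture(5, 3, 0.5, 1.0, seed=4)
        np.testing.assert_array_equal(a[0].centers, b[0].centers)
        np.testing.assert_array_equal(a[1].centers, b[1].centers)
        np.testing.assert_array_equal(a[2].images, b[2].images)

    def test_realized_snr_matches_request(self):
        snr = 0.1
        truth, _, stack = make_refinement_fixture(8, 10, snr, 0.0, seed=13)
        cfg = ImageConfig((64, 64), 1.0)
        clean = np.stack(
            [
                simulate_image(truth, stack.poses[i], stack.ctfs[i], cfg).pixels
                for i in range(len(stack))
            ]
        )
        noise = stack.images - clean
        pooled = clean.var(axis=(1, 2)).sum() / noise.var(axis=(1, 2)).sum()
        assert pooled == pytest.approx(snr, rel=0.1)
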