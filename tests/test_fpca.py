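"""Sparse FPCA engine: smoothers, eigendecomposition, PACE scores, prediction."""

import json
import warnings

import numpy as np
import pytest

from helpers import default_truth, sparse_sample, truth_fpca_model
from vfcast.errors import ConfigError, DataError
from vfcast.fpca import (
    FPCAModel,
    FPCAOptions,
    TrajectoryPrediction,
    _trapz_weights,
    compute_scores_pace,
    eigendecompose,
    estimate_covariance,
    estimate_mean,
    fit_fpca,
    interpolate_md,
    predict_trajectory,
)


def _quiet_fit(sample, options):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_fpca(sample, options)


class TestMeanSmoother:
    def test_exact_on_linear_data(self, rng):
        # local-linear smoothing reproduces a linear function exactly
        sample = []
        for _ in range(20):
            t = np.sort(rng.uniform(0, 3650, size=5))
            sample.append((t, -5.0 - t / 365.0))
        grid, mu, _ = estimate_mean(sample, FPCAOptions(bandwidth_mean=800.0))
        np.testing.assert_allclose(mu, -5.0 - grid / 365.0, atol=1e-8)

    def test_constant_subject_gives_constant_mean(self):
        sample = [(np.array([0.0, 1000.0, 3650.0]), np.array([-3.0, -3.0, -3.0]))]
        _, mu, _ = estimate_mean(sample, FPCAOptions(bandwidth_mean=2000.0))
        np.testing.assert_allclose(mu, -3.0, atol=1e-8)

    def test_quadratic_recovered_with_small_bandwidth(self, rng):
        f = lambda t: -4.0 - 2.0 * (t / 3650.0) ** 2
        sample = []
        for _ in range(300):
            t = np.sort(rng.uniform(0, 3650, size=20))
            sample.append((t, f(t)))
        _, mu, _ = estimate_mean(sample, FPCAOptions(bandwidth_mean=200.0))
        grid = np.linspace(0, 3650, 100)
        assert np.max(np.abs(mu - f(grid))) < 0.05

    def test_empty_sample_errors(self):
        with pytest.raises(DataError):
            estimate_mean([], FPCAOptions())


class TestCovarianceSurface:
    def test_dense_noiseless_rank_one(self, rng):
        grid = np.linspace(0, 3650, 51)
        T = 3650.0
        phi = np.sqrt(2.0 / T) * np.cos(2 * np.pi * grid / T)
        lam = 5000.0
        xi = rng.normal(0, np.sqrt(lam), size=150)
        sample = [(grid, x * phi) for x in xi]
        lam_emp = xi.var()  # oracle: biased sample variance on the dense grid
        opts = FPCAOptions(bandwidth_cov=60.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cg, G, sigma2, _ = estimate_covariance(sample, lambda t: np.zeros_like(t), opts)
        expected = lam_emp * np.outer(phi, phi)
        mask = np.abs(np.subtract.outer(cg, cg)) > 200  # off-diagonal band
        peak = lam_emp * 2.0 / T  # surface magnitude of the rank-1 component
        assert np.max(np.abs((G - expected)[mask])) < 0.02 * peak
        assert sigma2 < 0.02 * peak

    def test_pure_noise_gives_flat_surface_and_sigma2_one(self, rng):
        sample = []
        for _ in range(500):
            t = np.sort(rng.uniform(0, 3650, size=4))
            sample.append((t, rng.normal(0, 1.0, size=4)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, G, sigma2, _ = estimate_covariance(
                sample, lambda t: np.zeros_like(t), FPCAOptions(bandwidth_cov=900.0)
            )
        assert np.max(np.abs(G)) < 0.3  # off-diagonal covariance near zero
        assert sigma2 == pytest.approx(1.0, rel=0.10)

    def test_surface_is_symmetric(self, rng):
        truth = default_truth()
        sample, _ = sparse_sample(truth, "slow", 80, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, G, _, _ = estimate_covariance(
                sample,
                lambda t: truth.mu("slow", t),
                FPCAOptions(bandwidth_cov=900.0),
            )
        assert np.max(np.abs(G - G.T)) == 0.0

    def test_no_repeated_observations_errors(self):
        sample = [(np.array([100.0]), np.array([-5.0]))]
        with pytest.raises(Exception):
            estimate_covariance(sample, lambda t: np.zeros_like(t), FPCAOptions())


class TestEigendecomposition:
    def test_constant_surface_analytic_solution(self):
        # G(s,t) = c has the single eigenpair (c*T, 1/sqrt(T))
        grid = np.linspace(0, 3650, 51)
        c = 7.0
        phi, lam, fve = eigendecompose(np.full((51, 51), c), grid, K=1)
        assert lam[0] == pytest.approx(c * 3650.0, rel=1e-9)
        np.testing.assert_allclose(phi[0], 1.0 / np.sqrt(3650.0), rtol=1e-9)
        assert fve[0] == pytest.approx(1.0)

    def test_exact_rank_one_recovery(self):
        grid = np.linspace(0, 3650, 51)
        w = _trapz_weights(grid)
        raw = np.cos(2 * np.pi * grid / 3650.0)
        f = raw / np.sqrt(np.sum(w * raw**2))
        G = 123.0 * np.outer(f, f)
        phi, lam, _ = eigendecompose(G, grid, K=1)
        assert lam[0] == pytest.approx(123.0, rel=1e-6)
        aligned = min(np.max(np.abs(phi[0] - f)), np.max(np.abs(phi[0] + f)))
        assert aligned < 1e-6

    def test_fve_based_component_selection(self):
        # eigenvalues (98, 1.9, 0.1): FVE >= 0.995 needs exactly K = 2
        grid = np.linspace(0.0, 1.0, 41)
        w = _trapz_weights(grid)
        basis = np.vstack(
            [np.ones_like(grid), np.cos(2 * np.pi * grid), np.cos(4 * np.pi * grid)]
        )
        basis = np.vstack([b / np.sqrt(np.sum(w * b**2)) for b in basis])
        G = sum(l * np.outer(b, b) for l, b in zip([98.0, 1.9, 0.1], basis))
        phi, lam, fve = eigendecompose(G, grid, K=None, fve_target=0.995)
        assert phi.shape[0] == 2
        np.testing.assert_allclose(lam, [98.0, 1.9], rtol=1e-8)

    def test_k_beyond_positive_eigenvalues_errors(self):
        grid = np.linspace(0, 10, 11)
        G = np.outer(np.ones(11), np.ones(11))
        with pytest.raises(Exception):
            eigendecompose(G, grid, K=5)

    def test_sign_convention_nonnegative_integral(self):
        grid = np.linspace(0, 3650, 51)
        G = np.full((51, 51), 3.0)
        phi, _, _ = eigendecompose(G, grid, K=1)
        assert np.sum(_trapz_weights(grid) * phi[0]) > 0


class TestPaceScores:
    def test_scores_zero_when_subject_equals_mean(self):
        model = truth_fpca_model(default_truth(), "slow")
        t = np.array([0.0, 500.0, 1200.0])
        scores = compute_scores_pace((t, np.interp(t, model.grid, model.mu)), model)
        np.testing.assert_allclose(scores.xi, 0.0, atol=1e-9)

    def test_single_observation_closed_form(self):
        # K=1, lambda=2, phi(t1)=1, sigma2=1, y-mu=3 -> xi = 2*3/(2+1) = 2.0
        grid = np.linspace(0.0, 10.0, 11)
        model = FPCAModel(
            grid=grid,
            mu=np.zeros(11),
            phi=np.ones((1, 11)),
            lam=np.array([2.0]),
            sigma2=1.0,
            fve=np.array([1.0]),
        )
        scores = compute_scores_pace((np.array([4.0]), np.array([3.0])), model)
        assert scores.xi[0] == pytest.approx(2.0, abs=1e-10)

    def test_noiseless_full_grid_scores_equal_quadrature_projection(self):
        truth = default_truth(sigma2=0.0)
        model = truth_fpca_model(truth, "slow")
        model.sigma2 = 0.0
        y = model.mu + 3.0 * model.phi[0]
        scores = compute_scores_pace((model.grid, y), model)
        # oracle: quadrature projection of (y - mu) on each eigenfunction
        w = _trapz_weights(model.grid)
        proj = [(w * (y - model.mu) * model.phi[k]).sum() for k in range(2)]
        np.testing.assert_allclose(proj, [3.0, 0.0], atol=1e-8)
        np.testing.assert_allclose(scores.xi, [3.0, 0.0], atol=1e-6)

    def test_observation_outside_domain_errors(self):
        model = truth_fpca_model(default_truth(), "slow")
        with pytest.raises(DataError):
            compute_scores_pace((np.array([3651.0]), np.array([-5.0])), model)

    def test_shrinkage_monotone_in_noise_variance(self):
        truth = default_truth()
        model = truth_fpca_model(truth, "slow")
        t = np.array([0.0, 400.0])
        y = np.interp(t, model.grid, model.mu) + np.array([4.0, 5.0])
        norms = []
        for s2 in [0.5, 2.0, 8.0, 32.0, 128.0]:
            model.sigma2 = s2
            norms.append(np.linalg.norm(compute_scores_pace((t, y), model).xi))
        assert all(a > b for a, b in zip(norms, norms[1:]))


class TestTrajectoryPrediction:
    def test_zero_scores_reproduce_mean(self):
        model = truth_fpca_model(default_truth(), "fast")
        pred = predict_trajectory(np.zeros(2), model)
        np.testing.assert_allclose(pred.values, model.mu)

    def test_pointwise_identity(self):
        model = truth_fpca_model(default_truth(), "slow")
        pred = predict_trajectory(np.array([1.7, -2.2]), model)
        expected = model.mu + 1.7 * model.phi[0] - 2.2 * model.phi[1]
        assert np.max(np.abs(pred.values - expected)) < 1e-10

    def test_grid_is_100_equispaced_points(self):
        model = truth_fpca_model(default_truth(), "slow")
        assert len(model.grid) == 100
        steps = np.diff(model.grid)
        np.testing.assert_allclose(steps, steps[0], rtol=1e-9)

    def test_score_length_mismatch_errors(self):
        model = truth_fpca_model(default_truth(), "slow")
        with pytest.raises(DataError):
            predict_trajectory(np.zeros(3), model)

    def test_interpolation_contract(self):
        pred = TrajectoryPrediction(
            grid=np.array([0.0, 10.0, 20.0]), values=np.array([1.0, 2.0, 4.0])
        )
        assert interpolate_md(pred, 10.0) == pytest.approx(2.0)
        assert interpolate_md(pred, 15.0) == pytest.approx(3.0)
        with pytest.raises(DataError):
            interpolate_md(pred, 21.0)

    def test_no_extrapolation_past_ten_years(self):
        model = truth_fpca_model(default_truth(), "slow")
        pred = predict_trajectory(np.zeros(2), model)
        with pytest.raises(DataError):
            interpolate_md(pred, 3651.0)


class TestFitOrchestration:
    def test_model_invariants_and_order_invariance(self, rng):
        truth = default_truth()
        sample, _ = sparse_sample(truth, "slow", 120, rng)
        opts = FPCAOptions(bandwidth_mean=1200.0, bandwidth_cov=1200.0, em_iterations=40)
        m1 = _quiet_fit(sample, opts)
        m1.validate()
        perm = list(np.random.default_rng(1).permutation(len(sample)))
        m2 = _quiet_fit([sample[i] for i in perm], opts)
        np.testing.assert_allclose(m1.mu, m2.mu, atol=1e-8)
        np.testing.assert_allclose(m1.lam, m2.lam, rtol=1e-7)

    def test_two_component_truth_reaches_high_fve(self, rng):
        truth = default_truth()
        sample, _ = sparse_sample(truth, "slow", 300, rng)
        model = _quiet_fit(sample, FPCAOptions())
        assert model.fve[1] >= 0.95

    def test_serialization_round_trip(self, rng, tmp_path):
        truth = default_truth()
        sample, _ = sparse_sample(truth, "slow", 60, rng)
        model = _quiet_fit(
            sample, FPCAOptions(bandwidth_mean=1500.0, bandwidth_cov=1500.0, em_iterations=20)
        )
        model.save(tmp_path / "model")
        loaded = FPCAModel.load(tmp_path / "model")
        hdr_a = json.loads((tmp_path / "model.json").read_text())
        model.save(tmp_path / "model2")
        assert hdr_a == json.loads((tmp_path / "model2.json").read_text())
        np.testing.assert_allclose(loaded.mu, model.mu, atol=1e-12)
        np.testing.assert_allclose(loaded.phi, model.phi, atol=1e-12)
        np.testing.assert_allclose(loaded.lam, model.lam, atol=1e-12)
        assert loaded.sigma2 == model.sigma2

    def test_invalid_options_rejected(self):
        with pytest.raises(ConfigError):
            FPCAOptions(n_grid_out=1).validate()
        with pytest.raises(ConfigError):
            FPCAOptions(K=None, fve_target=None).validate()
        with pytest.raises(ConfigError):
            FPCAOptions(domain=(100.0, 100.0)).validate()


class TestMoreDataHelps:
    def test_year_one_mse_non_increasing_with_baseline_observations(self):
        # PACE mechanics under the true model: predictions at year 1 improve
        # (in MSE over eyes) when the baseline window holds 3 tests instead of 1
        truth = default_truth()
        model = truth_fpca_model(truth, "slow")
        rng = np.random.default_rng(17)
        t1 = np.array([0.0])
        t3 = np.array([0.0, 180.0, 365.0])
        target_day = 730.0
        errs = {1: [], 3: []}
        for _ in range(600):
            xi = (
                rng.normal(0, np.sqrt(truth.lam1)),
                rng.normal(0, np.sqrt(truth.lam2)),
            )
            latent_at = lambda tt: truth.latent_curve("slow", xi[0], xi[1], tt)
            for nb, tb in ((1, t1), (3, t3)):
                y = latent_at(tb) + rng.normal(0, 1.0, size=len(tb))
                scores = compute_scores_pace((tb, y), model)
                pred = predict_trajectory(scores, model)
                errs[nb].append(
                    (interpolate_md(pred, target_day) - latent_at(np.array([target_day]))[0]) ** 2
                )
        assert np.mean(errs[3]) <= np.mean(errs[1])
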