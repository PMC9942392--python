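"""Sparse FPCA: smoothers, eigenanalysis, AIC order selection and BLUP
scores against generating-process oracles."""

import json

import numpy as np
import pytest

from trajsurv.fpca import (
    FpcaModel,
    GridFunction,
    eigendecompose,
    estimate_covariance,
    estimate_mean,
    estimate_scores,
    fit_fpca,
    fit_trajectory,
    make_grid,
    select_K,
    trapezoid_weights,
)
from trajsurv.simulate import orthonormal_poly_basis

GRID = make_grid()
W = trapezoid_weights(GRID)
BASIS = orthonormal_poly_basis(GRID, 3)


def synthetic_model(lam=(2.0,), sigma2=0.0, mu=None):
    lam = np.asarray(lam, dtype=float)
    phi = BASIS[:len(lam)]
    mu = np.zeros_like(GRID) if mu is None else mu
    return FpcaModel("CEA", GRID, mu, phi, lam, sigma2, 1.0, 1.0)


def rank1_series(rng, n, sigma=0.5, times=None, var=1.0):
    phi = BASIS[0]
    out = []
    scores = rng.normal(0, np.sqrt(var), n)
    for a in scores:
        t = times if times is not None else np.sort(rng.uniform(-1, 12, 6))
        y = a * np.interp(t, GRID, phi) + rng.normal(0, sigma, len(t))
        out.append((t, y))
    return out, scores


class TestQuadrature:
    def test_weights_positive_and_sum_to_interval_length(self):
        assert np.all(W > 0)
        assert W.sum() == pytest.approx(13.0)

    def test_grid_function_validates(self):
        with pytest.raises(ValueError):
            GridFunction(np.array([0.0, 0.0, 1.0]), np.zeros(3))
        with pytest.raises(ValueError):
            GridFunction(GRID, np.zeros(5))


class TestMean:
    def test_constant_data_give_constant_mean(self):
        rng = np.random.default_rng(0)
        series = [(np.sort(rng.uniform(-1, 12, 5)), np.full(5, 3.7))
                  for _ in range(40)]
        mu, _ = estimate_mean(series, GRID, bandwidth=2.0)
        np.testing.assert_allclose(mu.values, 3.7, atol=1e-8)

    def test_linear_mean_recovered_from_dense_noise_free_data(self):
        times = np.linspace(-1, 12, 60)
        series = [(times, 2.0 - 0.1 * times)] * 30
        mu, _ = estimate_mean(series, GRID, bandwidth="auto")
        assert np.max(np.abs(mu.values - (2.0 - 0.1 * GRID))) < 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_mean([], GRID)
        with pytest.raises(ValueError):
            estimate_mean([(np.array([1.0]), np.array([2.0]))] * 5, GRID)


class TestCovariance:
    def test_error_variance_recovered_on_dense_rank1_design(self):
        rng = np.random.default_rng(1)
        times = np.linspace(-1, 12, 25)
        series, _ = rank1_series(rng, 1000, sigma=0.5, times=times)
        mu = GridFunction(GRID, np.zeros_like(GRID))
        _, sigma2, _ = estimate_covariance(series, mu)
        assert abs(sigma2 - 0.25) / 0.25 < 0.10

    def test_surface_is_symmetric_and_psd(self):
        rng = np.random.default_rng(2)
        series, _ = rank1_series(rng, 150, sigma=0.4)
        mu = GridFunction(GRID, np.zeros_like(GRID))
        surf, _, _ = estimate_covariance(series, mu)
        np.testing.assert_array_equal(surf, surf.T)
        vals = np.linalg.eigvalsh(np.sqrt(W)[:, None] * surf
                                  * np.sqrt(W)[None, :])
        assert vals.min() > -1e-10

    def test_white_noise_has_vanishing_off_diagonal(self):
        rng = np.random.default_rng(3)
        sigma = 1.0
        series = [(np.sort(rng.uniform(-1, 12, 6)),
                   rng.normal(0, sigma, 6)) for _ in range(500)]
        mu = GridFunction(GRID, np.zeros_like(GRID))
        surf, _, _ = estimate_covariance(series, mu)
        n_pairs = 500 * 6 * 5
        # each surface value averages roughly the pairs within the kernel
        # footprint (~bandwidth/range of the domain in each axis)
        se = sigma ** 2 / np.sqrt(n_pairs * (1.3 / 13.0) ** 2)
        off = surf[np.triu_indices_from(surf, k=8)]
        assert np.max(np.abs(off)) < 3 * se

    def test_needs_repeated_measurements(self):
        series = [(np.array([1.0]), np.array([0.5]))] * 10
        mu = GridFunction(GRID, np.zeros_like(GRID))
        with pytest.raises(ValueError):
            estimate_covariance(series, mu)


class TestEigendecomposition:
    def test_rank_one_identity(self):
        phi = BASIS[0]
        surf = 2.0 * np.outer(phi, phi)
        lam, phis = eigendecompose(surf, GRID)
        assert lam[0] == pytest.approx(2.0, abs=1e-8)
        assert np.max(np.abs(np.abs(phis[0]) - np.abs(phi))) < 1e-6

    def test_two_components_recovered_in_order(self):
        surf = 3.0 * np.outer(BASIS[1], BASIS[1]) \
            + 1.0 * np.outer(BASIS[0], BASIS[0])
        lam, phis = eigendecompose(surf, GRID)
        assert lam[0] == pytest.approx(3.0, abs=1e-8)
        assert lam[1] == pytest.approx(1.0, abs=1e-8)
        assert abs((phis[0] * BASIS[1] * W).sum()) == pytest.approx(1, abs=1e-6)

    def test_eigenfunctions_unit_norm_and_sign_fixed(self):
        surf = 2.0 * np.outer(BASIS[0], BASIS[0])
        _, phis = eigendecompose(surf, GRID)
        assert (phis[0] ** 2 * W).sum() == pytest.approx(1.0, abs=1e-10)
        assert (phis[0] * W).sum() >= 0


class TestScores:
    def test_zero_residual_gives_zero_scores(self):
        model = synthetic_model(lam=(2.0, 1.0), sigma2=0.1,
                                mu=1.0 + 0.2 * GRID)
        t = np.array([-0.5, 2.0, 6.0, 11.0])
        y = np.interp(t, GRID, model.mu)
        xi, post = estimate_scores(model, t, y)
        np.testing.assert_allclose(xi, 0.0, atol=1e-12)
        assert post.shape == (2, 2)

    def test_dense_noise_free_patient_recovers_generating_score(self):
        model = synthetic_model(lam=(2.0,), sigma2=0.0)
        t = np.linspace(-1, 12, 80)
        y = 1.7 * np.interp(t, GRID, BASIS[0])
        xi, _ = estimate_scores(model, t, y)
        assert abs(xi[0] - 1.7) < 0.05

    def test_single_observation_score_is_shrunk_below_naive_projection(self):
        model = synthetic_model(lam=(2.0,), sigma2=0.5)
        t = np.array([5.0])
        y = np.array([1.0])
        xi, _ = estimate_scores(model, t, y)
        naive = y[0] / np.interp(t, GRID, BASIS[0])[0]
        assert 0 < abs(xi[0]) < abs(naive)

    def test_dense_noise_free_scores_converge_to_numerical_projection(self):
        """BLUP -> direct quadrature projection of (Y - mu) on phi as the
        design densifies and the error variance vanishes."""
        model = synthetic_model(lam=(2.0, 1.0), sigma2=1e-10)
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 2)
        y_grid = a[0] * BASIS[0] + a[1] * BASIS[1]
        t = GRID.copy()
        xi, _ = estimate_scores(model, t, y_grid)
        proj = np.array([(y_grid * BASIS[k] * W).sum() for k in range(2)])
        np.testing.assert_allclose(xi, proj, atol=1e-6)
        np.testing.assert_allclose(proj, a, atol=1e-10)

    def test_no_observations_rejected(self):
        model = synthetic_model()
        with pytest.raises(ValueError):
            estimate_scores(model, np.array([]), np.array([]))


class TestSelectK:
    def test_singleton_candidate_returned(self):
        rng = np.random.default_rng(5)
        series, _ = rank1_series(rng, 60, sigma=0.3)
        model = fit_fpca(series, "CEA", select=False, max_components=4)
        assert select_K(model, series, candidates=[3]) == 3

    def test_noise_only_data_select_smallest_candidate(self):
        rng = np.random.default_rng(6)
        series = [(np.sort(rng.uniform(-1, 12, 6)), rng.normal(0, 1, 6))
                  for _ in range(200)]
        model = fit_fpca(series, "CEA", select=False, max_components=4)
        assert select_K(model, series, candidates=[1, 2, 3]) == 1

    def test_two_well_separated_components_selected(self):
        rng = np.random.default_rng(7)
        series = []
        for _ in range(400):
            a = rng.normal(0, [2.0, 1.0])
            t = np.sort(rng.uniform(-1, 12, 6))
            y = a[0] * np.interp(t, GRID, BASIS[0]) \
                + a[1] * np.interp(t, GRID, BASIS[1]) \
                + rng.normal(0, np.sqrt(0.1), 6)
            series.append((t, y))
        model = fit_fpca(series, "CEA", k_candidates=range(1, 5))
        assert model.K == 2


class TestTrajectory:
    def test_zero_scores_reproduce_mean(self):
        model = synthetic_model(lam=(2.0, 1.0), mu=1.0 - 0.1 * GRID)
        fit = fit_trajectory(model, np.zeros(2))
        np.testing.assert_array_equal(fit.values, model.mu)

    def test_reconstruction_identity_exact(self):
        model = synthetic_model(lam=(2.0, 1.0), mu=0.5 + 0.0 * GRID)
        xi = np.array([1.3, -0.4])
        fit = fit_trajectory(model, xi)
        np.testing.assert_allclose(
            fit.values, model.mu + xi @ model.phi[:2], atol=1e-14)

    def test_reconstruction_error_decreases_with_nested_K(self):
        truth = 1.1 * BASIS[0] - 0.8 * BASIS[1] + 0.5 * BASIS[2]
        model3 = synthetic_model(lam=(2.0, 1.0, 0.5))
        proj = np.array([(truth * BASIS[k] * W).sum() for k in range(3)])
        errs = []
        for K in (1, 2, 3):
            fit = fit_trajectory(model3.truncated(K), proj[:K])
            errs.append(((fit.values - truth) ** 2 * W).sum())
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-20

    def test_score_roundtrip_on_noise_free_reconstruction(self):
        model = synthetic_model(lam=(2.0, 1.0), sigma2=0.0)
        xi = np.array([0.9, -0.6])
        fit = fit_trajectory(model, xi)
        t = np.linspace(-1, 12, 50)
        xi2, _ = estimate_scores(model, t, np.interp(t, GRID, fit.values))
        np.testing.assert_allclose(xi2, xi, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        model = synthetic_model(lam=(2.0,))
        with pytest.raises(ValueError):
            fit_trajectory(model, np.zeros(3))


def test_fitted_model_invariants(clean_cohort):
    """Orthonormality under quadrature, descending eigenvalues, fixed sign
    convention — asserted on a real sparse fit."""
    from trajsurv.preprocess import build_series
    _, measurements, _ = clean_cohort
    series = build_series(measurements, "CEA")
    model = fit_fpca(series, "CEA", k_candidates=range(1, 5))
    gram = (model.phi * model.quad_weights) @ model.phi.T
    np.testing.assert_allclose(gram, np.eye(model.K), atol=1e-6)
    assert np.all(np.diff(model.lam) <= 1e-12)
    assert model.lam[-1] > 0
    assert model.sigma2 >= 0
    assert np.all(model.phi @ model.quad_weights >= -1e-9)


def test_model_json_roundtrip():
    model = synthetic_model(lam=(2.0, 1.0), sigma2=0.3)
    back = FpcaModel.from_json(model.to_json())
    np.testing.assert_allclose(back.phi, model.phi)
    np.testing.assert_allclose(back.lam, model.lam)
    assert back.sigma2 == model.sigma2
    assert json.loads(model.to_json())["marker"] == "CEA"
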