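"""Voxel population encoding model: basis, fitting, likelihood, decoding,
observed FI, cross-validation, windows, ROI selection."""

import numpy as np
import pandas as pd
import pytest

from contextfi import encoding, synthetic
from contextfi.encoding import (
    BasisSet,
    EncodingModelParams,
    VoxelDataset,
    VoxelEncodingModel,
    analytic_fi,
    basis_response,
    crossval_fit,
    decode_mle,
    fit_weights,
    log_likelihood,
    observed_fi,
    observed_fi_exact,
    roi_select,
    surround_modulation_index,
    window_average_fi,
)


class TestBasis:
    def test_peak_and_null_responses(self):
        basis = BasisSet(n_basis=8)
        phi0 = basis.preferred_orientations[0]
        resp = basis_response(phi0, basis)
        assert resp[0] == pytest.approx(1.0)
        assert basis_response(phi0 + 45.0, basis)[0] == pytest.approx(0.0)

    def test_half_width_closed_form(self):
        # cos(45 deg)^5 = 2^(-5/2)
        basis = BasisSet(n_basis=8, exponent=5)
        resp = basis_response(22.5, basis)
        assert resp[0] == pytest.approx(2.0 ** (-2.5), abs=1e-10)

    def test_circular_evaluation(self):
        basis = BasisSet(n_basis=8)
        assert np.allclose(basis.response(1.0), basis.response(181.0))

    def test_responses_bounded(self, rng):
        basis = BasisSet()
        r = basis.response(rng.uniform(0, 180, 100))
        assert np.all((r >= 0) & (r <= 1))


class TestFitWeights:
    def test_noiseless_exact_recovery(self, rng):
        basis = BasisSet()
        W = rng.standard_normal((10, 8))
        theta = rng.uniform(0, 180, 200)
        M = basis.response(theta) @ W.T
        fitted = fit_weights(VoxelDataset(M, theta), basis)
        assert np.allclose(fitted, W, atol=1e-10)

    def test_underdetermined_rejected(self, rng):
        basis = BasisSet()
        theta = rng.uniform(0, 180, 5)
        with pytest.raises(ValueError):
            fit_weights(VoxelDataset(rng.standard_normal((5, 3)), theta), basis)

    def test_matches_normal_equations_oracle(self, rng):
        basis = BasisSet()
        theta = rng.uniform(0, 180, 300)
        M = rng.standard_normal((300, 7))
        X = basis.response(theta)
        oracle = (np.linalg.pinv(X.T @ X) @ X.T @ M).T
        fitted = fit_weights(VoxelDataset(M, theta), basis)
        assert np.allclose(fitted, oracle, atol=1e-8)

    def test_ols_error_attains_theoretical_floor(self):
        """The OLS weight error should match its analytic expectation
        E||dW||_F^2 = tr((X'X)^-1) tr(Omega) — i.e. the implementation adds
        no avoidable error."""
        params = synthetic.random_encoding_params(30, seed=1, channel_sd=0.3, rho=0.1)
        errs = []
        for s in range(3):
            theta = np.random.default_rng(100 + s).uniform(0, 180, 5000)
            ds = synthetic.gen_voxel_dataset(params, theta, seed=200 + s)
            W = fit_weights(ds, params.basis)
            errs.append(np.sum((W - params.W) ** 2))
            if s == 0:
                X = params.basis.response(theta)
                floor = np.trace(np.linalg.inv(X.T @ X)) * np.trace(params.covariance())
        assert np.mean(errs) == pytest.approx(floor, rel=0.25)


class TestFitNoise:
    def test_parameter_recovery(self):
        params = synthetic.random_encoding_params(
            30, seed=1, channel_sd=0.3, tau_spread=0.0, rho=0.1
        )
        theta = np.random.default_rng(2).uniform(0, 180, 5000)
        ds = synthetic.gen_voxel_dataset(params, theta, seed=3)
        sigma, tau, rho, info = encoding.fit_noise(ds, params.W, params.basis)
        assert info["converged"]
        assert rho == pytest.approx(0.1, abs=0.03)
        assert np.median(np.abs(tau - params.tau) / params.tau) < 0.05

    def test_recovery_at_null_rho(self):
        params = synthetic.random_encoding_params(20, seed=4, channel_sd=0.2, rho=0.0)
        theta = np.random.default_rng(5).uniform(0, 180, 4000)
        ds = synthetic.gen_voxel_dataset(params, theta, seed=6)
        _, _, rho, _ = encoding.fit_noise(ds, params.W, params.basis)
        assert rho < 0.02

    def test_ml_dominates_truth_on_training_data(self):
        params = synthetic.random_encoding_params(8, seed=7, channel_sd=0.25, rho=0.15)
        theta = np.random.default_rng(8).uniform(0, 180, 1500)
        ds = synthetic.gen_voxel_dataset(params, theta, seed=9)
        sigma, tau, rho, info = encoding.fit_noise(ds, params.W, params.basis)
        fitted = EncodingModelParams(params.basis, params.W, sigma, tau, rho)
        ll_fit = sum(
            log_likelihood(m, t, fitted) for m, t in zip(ds.responses, ds.theta)
        )
        ll_true = sum(
            log_likelihood(m, t, params) for m, t in zip(ds.responses, ds.theta)
        )
        assert ll_fit >= ll_true - 1e-6


class TestLikelihood:
    def test_matches_bruteforce_gaussian(self, toy_encoding_params, rng):
        """From-definition oracle with explicit inverse and determinant."""
        params = toy_encoding_params
        omega = params.covariance()
        inv = np.linalg.inv(omega)
        _, logdet = np.linalg.slogdet(omega)
        for _ in range(5):
            m = rng.standard_normal(5)
            theta = rng.uniform(0, 180)
            diff = m - params.mu(theta)
            expected = -0.5 * (5 * np.log(2 * np.pi) + logdet + diff @ inv @ diff)
            assert log_likelihood(m, theta, params) == pytest.approx(expected, abs=1e-8)

    def test_mode_at_mean(self, toy_encoding_params, rng):
        params = toy_encoding_params
        theta = 60.0
        mu = params.mu(theta)
        ll_mu = log_likelihood(mu, theta, params)
        for _ in range(5):
            assert log_likelihood(mu + rng.standard_normal(5) * 0.1, theta, params) <= ll_mu


class TestDecoding:
    def test_noiseless_decode_recovers_theta(self, toy_encoding_params):
        params = toy_encoding_params
        for theta in (3.2, 88.0, 171.5):
            prof = decode_mle(params.mu(theta), params, grid_step=0.5)
            assert abs(prof.mle - theta) <= 0.25 + 1e-9

    def test_untuned_model_flat_likelihood_tie_rule(self):
        params = EncodingModelParams(
            BasisSet(), np.zeros((4, 8)), 0.0, np.ones(4), 0.0
        )
        prof = decode_mle(np.zeros(4), params, grid_step=1.0)
        assert np.ptp(prof.loglik) < 1e-9
        assert prof.mle == 0.0  # lowest grid index wins exact ties

    def test_moderate_noise_high_circular_correlation(self):
        params = synthetic.random_encoding_params(
            20, seed=10, channel_sd=0.1, tau_mean=0.3, weight_scale=1.5
        )
        theta = np.random.default_rng(11).uniform(0, 180, 1000)
        ds = synthetic.gen_voxel_dataset(params, theta, seed=12)
        mles = np.array([decode_mle(m, params, 1.0).mle for m in ds.responses])
        assert encoding.circular_correlation(theta, mles) > 0.9


class TestObservedFI:
    def test_noiseless_equals_analytic(self, toy_encoding_params):
        params = toy_encoding_params
        theta = 37.0
        j = observed_fi_exact(params.mu(theta), theta, params, step=0.1)
        assert j == pytest.approx(analytic_fi(params, theta), rel=1e-3)

    def test_profile_and_exact_agree(self, toy_encoding_params, rng):
        params = toy_encoding_params
        theta = 101.3
        m = params.mu(theta) + rng.standard_normal(5) * 0.3
        prof = decode_mle(m, params, grid_step=0.5)
        j_grid = observed_fi(prof, theta)
        j_exact = observed_fi_exact(m, theta, params, step=0.5)
        assert j_grid == pytest.approx(j_exact, rel=0.05, abs=1e-4)

    def test_scalar_closed_form(self):
        """One 'voxel' with sinusoidal tuning and unit noise: the observed
        FI at the mean must equal the hand-derived second derivative."""

        class _Sin:
            n_basis = 1

            def response(self, theta):
                return np.sin(2 * np.pi * np.asarray(theta, float) / 180.0)[..., None]

        params = EncodingModelParams.__new__(EncodingModelParams)
        params.basis = _Sin()
        params.W = np.array([[1.0]])
        params.channel_sd = 0.0
        params.tau = np.array([1.0])
        params.rho = 0.0
        params._chol = np.array([[1.0]])
        theta = 40.0
        m = params.mu(theta)
        j = observed_fi_exact(m, theta, params, step=0.05)
        expected = (2 * np.pi / 180.0) ** 2 * np.cos(2 * np.pi * theta / 180.0) ** 2
        assert j == pytest.approx(expected, abs=1e-4)

    def test_mean_observed_fi_matches_analytic(self, toy_encoding_params):
        params = toy_encoding_params
        theta = 57.0
        truth = analytic_fi(params, theta)
        ds = synthetic.gen_voxel_dataset(params, np.full(4000, theta), seed=13)
        js = np.array(
            [observed_fi_exact(m, theta, params, 0.5) for m in ds.responses]
        )
        se = js.std(ddof=1) / np.sqrt(js.size)
        assert abs(js.mean() - truth) < 3 * se


class TestScaleEquivariance:
    def test_decoded_orientation_and_fi_invariant(self, toy_encoding_params, rng):
        params = toy_encoding_params
        c = 3.7
        scaled = EncodingModelParams(
            params.basis, c * params.W, params.channel_sd, c * params.tau, params.rho
        )
        m = params.mu(50.0) + rng.standard_normal(5) * 0.2
        p1 = decode_mle(m, params, 0.5)
        p2 = decode_mle(c * m, scaled, 0.5)
        assert p1.mle == p2.mle
        j1 = observed_fi_exact(m, 50.0, params, 0.5)
        j2 = observed_fi_exact(c * m, 50.0, scaled, 0.5)
        assert j1 == pytest.approx(j2, rel=1e-8)


class TestCrossval:
    def test_partition_property(self):
        params = synthetic.random_encoding_params(6, seed=14)
        theta = np.random.default_rng(15).uniform(0, 180, 57)
        ds = synthetic.gen_voxel_dataset(params, theta, seed=16)
        out = crossval_fit(ds, n_folds=5, n_phase_models=1, seed=17)
        assert len(out) == 57
        assert sorted(out["trial"]) == list(range(57))
        assert out["fold"].nunique() == 5

    def test_seeded_reproducibility(self):
        params = synthetic.random_encoding_params(6, seed=18)
        theta = np.random.default_rng(19).uniform(0, 180, 40)
        ds = synthetic.gen_voxel_dataset(params, theta, seed=20)
        a = crossval_fit(ds, n_folds=4, n_phase_models=2, seed=21)
        b = crossval_fit(ds, n_folds=4, n_phase_models=2, seed=21)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_folds_rejected(self):
        params = synthetic.random_encoding_params(4, seed=22)
        ds = synthetic.gen_voxel_dataset(params, np.linspace(0, 170, 10), seed=23)
        with pytest.raises(ValueError):
            crossval_fit(ds, n_folds=50, n_phase_models=1, seed=0)


class TestWindowAverage:
    def test_constant_fi(self):
        theta = np.linspace(0, 179, 500)
        out = window_average_fi(theta, np.full(500, 2.5))
        assert np.allclose(out.fi, 2.5)
        assert np.allclose(out.sem, 0.0)

    def test_matches_analytic_windowed_mean(self):
        """Quadrature oracle: windowed mean of 1 + cos(4 pi theta/180)."""
        theta = np.arange(0, 180, 0.05)
        j = 1.0 + np.cos(np.deg2rad(4.0 * theta))
        out = window_average_fi(theta, j, window_deg=25.0, centers=np.arange(0, 180, 5.0))
        w = np.deg2rad(4.0) * 12.5
        atten = np.sin(w) / w  # mean of cos over the window
        expected = 1.0 + atten * np.cos(np.deg2rad(4.0 * out.grid))
        assert np.max(np.abs(out.fi - expected) / expected) < 0.01

    def test_window_bounds(self):
        # a window spanning 22.5..47.5 is centered at 35
        theta = np.array([22.5, 35.0, 47.5, 47.51, 22.49])
        out = window_average_fi(theta, np.arange(5.0), window_deg=25.0, centers=[35.0])
        assert out.fi[0] == pytest.approx(np.mean([0.0, 1.0, 2.0]))


class TestSurroundModulation:
    def test_doubling_is_hundred_percent(self):
        theta = np.tile(np.arange(0, 180, 1.0), 4)
        j_base = np.ones_like(theta)
        in_win = (theta >= 22.5) & (theta <= 47.5)
        j_surr = np.where(in_win, 2.0, 1.0)
        pct, t, p = surround_modulation_index(theta, j_surr, theta, j_base)
        assert pct == pytest.approx(100.0)

    def test_null_difference(self, rng):
        theta = rng.uniform(0, 180, 2000)
        j = rng.uniform(1, 2, 2000)
        pct, t, p = surround_modulation_index(theta, j, theta, j)
        assert pct == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_injected_bump_recovered(self, rng):
        theta_b = rng.uniform(0, 180, 20000)
        theta_s = rng.uniform(0, 180, 20000)
        j_b = 1.0 + 0.1 * rng.standard_normal(20000)
        bump = 0.5 * np.exp(-0.5 * ((theta_s - 35.0) / 5.0) ** 2)
        j_s = 1.0 + bump + 0.1 * rng.standard_normal(20000)
        pct, t, p = surround_modulation_index(theta_s, j_s, theta_b, j_b)
        expected = 100.0 * np.mean(
            0.5 * np.exp(-0.5 * ((np.linspace(22.5, 47.5, 2001) - 35.0) / 5.0) ** 2)
        )
        assert pct == pytest.approx(expected, abs=1.5)
        assert p < 1e-10


class TestRoiSelect:
    @pytest.mark.parametrize(
        "c,s,rule",
        [(0.5, 0.4, "center_inner"), (7.0, 1.0, "boundary"), (20.0, 2.0, "surround_outer")],
    )
    def test_rule_examples(self, c, s, rule):
        ds = VoxelDataset(
            responses=np.zeros((3, 1)),
            theta=np.zeros(3),
            prf_center=np.array([c]),
            prf_size=np.array([s]),
        )
        assert roi_select(ds, rule).n_voxels == 1

    def test_missing_prf_rejected(self):
        ds = VoxelDataset(responses=np.zeros((2, 2)), theta=np.zeros(2))
        with pytest.raises(ValueError):
            roi_select(ds, "boundary")


class TestEstimatorInterface:
    def test_sklearn_contract(self):
        model = VoxelEncodingModel(n_basis=8, grid_step=1.0)
        params = model.get_params()
        assert params["n_basis"] == 8
        model.set_params(grid_step=0.5)
        assert model.grid_step == 0.5

    def test_fit_predict_roundtrip(self):
        gen = synthetic.random_encoding_params(
            10, seed=30, channel_sd=0.1, tau_mean=0.3, weight_scale=1.5
        )
        theta = np.random.default_rng(31).uniform(0, 180, 600)
        ds = synthetic.gen_voxel_dataset(gen, theta, seed=32)
        model = VoxelEncodingModel(grid_step=1.0).fit(ds.responses, ds.theta)
        assert model.W_.shape == (10, 8)
        pred = model.predict(ds.responses[:50])
        r = encoding.circular_correlation(theta[:50], pred)
        assert r > 0.8
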