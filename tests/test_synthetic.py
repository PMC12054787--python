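"""Generators: stimuli, behavioral trials, priors, voxel datasets."""

import numpy as np
import pytest

from contextfi import synthetic
from contextfi.behavior import sliding_bias_sd
from contextfi.circstats import periodic_integral, signed_orientation_diff
from contextfi.synthetic import (
    DEFAULT_STIMULUS,
    StimulusSpec,
    gen_behavioral_trials,
    gen_prior,
    gen_stimulus_image,
    gen_voxel_dataset,
    oblique_observer,
    random_encoding_params,
)


def _eccentricity_grid(spec):
    n = spec.image_size
    c = (np.arange(n) - (n - 1) / 2.0) * spec.degrees_per_pixel
    return np.hypot(c[None, :], c[:, None])


class TestStimulus:
    def test_blank_regions_are_mid_gray(self):
        img = gen_stimulus_image(30.0, "noise", seed=0)
        r = _eccentricity_grid(DEFAULT_STIMULUS)
        assert np.all(img[r < 0.6] == 0.5)  # inside the blank central disk
        assert np.all(img[r > 13.0] == 0.5)  # outside the surround

    def test_center_contrast_is_twenty_percent(self):
        img = gen_stimulus_image(0.0, "none", seed=0, phase_center=0.0)
        r = _eccentricity_grid(DEFAULT_STIMULUS)
        center = img[(r > 2.0) & (r < 6.5)]
        # anti-aliased pixels slightly attenuate the sampled extrema
        assert center.max() == pytest.approx(0.5 + 0.5 * 0.2, abs=8e-3)
        assert center.min() == pytest.approx(0.5 - 0.5 * 0.2, abs=8e-3)
        assert center.max() <= 0.6 and center.min() >= 0.4

    def test_oriented_surround_holds_grating(self):
        img = gen_stimulus_image(0.0, "oriented", 35.0, seed=0)
        r = _eccentricity_grid(DEFAULT_STIMULUS)
        surround = img[(r > 7.5) & (r < 12.0)]
        assert surround.std() > 0.01

    def test_seed_reproducibility(self):
        a = gen_stimulus_image(10.0, "noise", seed=7)
        b = gen_stimulus_image(10.0, "noise", seed=7)
        c = gen_stimulus_image(10.0, "noise", seed=8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_mirror_symmetry(self):
        """Reflecting about the vertical axis equals negating orientations."""
        spec = StimulusSpec(image_size=255)  # odd size: exact mirror pixels
        img_pos = gen_stimulus_image(
            35.0, "oriented", 20.0, spec=spec, phase_center=0.0, phase_surround=0.0
        )
        img_neg = gen_stimulus_image(
            np.mod(-35.0, 180.0),
            "oriented",
            np.mod(-20.0, 180.0),
            spec=spec,
            phase_center=0.0,
            phase_surround=0.0,
        )
        assert np.allclose(img_pos[:, ::-1], img_neg, atol=1e-10)

    def test_png_roundtrip(self, tmp_path):
        from PIL import Image

        from contextfi.synthetic import write_image

        img = gen_stimulus_image(10.0, "oriented", 35.0, seed=0)
        path = tmp_path / "stim.png"
        write_image(img, path)
        back = np.asarray(Image.open(path)) / 255.0
        assert back.shape == img.shape
        assert np.max(np.abs(back - img)) < 1.0 / 255.0

    def test_spec_from_config(self):
        from contextfi.synthetic import spec_from_config

        spec = spec_from_config({"image_size": 128, "degrees_per_pixel": 0.2})
        assert spec.image_size == 128
        assert spec.center_outer_radius == 7.0

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(center_inner_radius=8.0)
        with pytest.raises(ValueError):
            gen_stimulus_image(10.0, "wavy")


class TestBehavioralTrials:
    def test_zero_bias_mean_error(self):
        obs = synthetic.GroundTruthObserver(
            bias_fn=lambda t: np.zeros_like(np.asarray(t, float)),
            sd_fn=lambda t: np.full_like(np.asarray(t, float), 2.0),
        )
        tr = gen_behavioral_trials(obs, 100000, seed=1)
        err = signed_orientation_diff(tr["estimate_deg"], tr["theta_deg"])
        assert abs(err.mean()) < 0.05

    def test_constant_bias_recovered_by_sliding_window(self):
        obs = synthetic.GroundTruthObserver(
            bias_fn=lambda t: np.full_like(np.asarray(t, float), 5.0),
            sd_fn=lambda t: np.full_like(np.asarray(t, float), 0.01),
        )
        tr = gen_behavioral_trials(obs, 20000, seed=2)
        prof = sliding_bias_sd(tr)
        assert np.nanmax(np.abs(prof.bias - 5.0)) < 0.1

    def test_sinusoidal_bias_recovered(self):
        obs = synthetic.GroundTruthObserver(
            bias_fn=lambda t: 3.0 * np.sin(np.deg2rad(4.0 * np.asarray(t, float))),
            sd_fn=lambda t: np.full_like(np.asarray(t, float), 2.0),
        )
        tr = gen_behavioral_trials(obs, 50000, seed=3)
        prof = sliding_bias_sd(tr)
        target = obs.bias_fn(prof.grid)
        rms = np.sqrt(np.nanmean((prof.bias - target) ** 2))
        assert rms < 0.2

    def test_errors_respect_circularity(self):
        obs = oblique_observer(sd_mean=30.0, sd_amplitude=0.0, bias_amplitude=20.0)
        tr = gen_behavioral_trials(obs, 5000, seed=4)
        assert tr["estimate_deg"].between(0, 180, inclusive="left").all()
        err = signed_orientation_diff(tr["estimate_deg"], tr["theta_deg"])
        assert np.all(np.abs(err) <= 90.0)

    def test_reproducible(self):
        obs = oblique_observer()
        a = gen_behavioral_trials(obs, 100, seed=9)
        b = gen_behavioral_trials(obs, 100, seed=9)
        assert a.equals(b)


class TestPriors:
    @pytest.mark.parametrize("family", ["uniform", "cardinal_peaked", "surround_conditioned"])
    def test_density_integrates_to_one(self, family):
        p = gen_prior(family)
        assert periodic_integral(p.density, p.step) == pytest.approx(1.0, abs=1e-6)
        assert np.all(p.density >= 0)

    def test_uniform_density_value(self):
        p = gen_prior("uniform")
        assert np.allclose(p.density, 1.0 / 180.0)

    def test_cardinal_peaks(self):
        p = gen_prior("cardinal_peaked")
        d0 = p.density_at(0.0)
        assert d0 > p.density_at(45.0)
        assert d0 == pytest.approx(p.density_at(90.0), rel=1e-9)

    def test_surround_bump_location(self):
        surr = gen_prior("surround_conditioned", surround_deg=35.0)
        base = gen_prior("cardinal_peaked")
        excess = surr.density - (1.0 - 0.15) * base.density
        assert surr.grid[np.argmax(excess)] == pytest.approx(35.0, abs=0.5)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            gen_prior("cardinal_peaked", cardinal_concentration=-1.0)


class TestVoxelGenerator:
    def test_noiseless_limit(self):
        params = random_encoding_params(6, seed=0, channel_sd=0.0, tau_mean=1e-9, tau_spread=0.0)
        theta = np.array([10.0, 77.0, 140.0])
        ds = gen_voxel_dataset(params, theta, seed=1)
        mu = params.mu(theta)
        assert np.allclose(ds.responses, mu, atol=1e-6)

    def test_rho_zero_gives_diagonal_residual_covariance(self):
        from contextfi.encoding import residual_covariance

        cov = residual_covariance(np.array([1.0, 2.0, 0.5]), 0.0)
        assert np.allclose(cov, np.diag([1.0, 4.0, 0.25]))

    def test_sample_covariance_matches_model(self, toy_encoding_params):
        """Monte-Carlo oracle: residual covariance at N=1e5 matches Omega."""
        params = toy_encoding_params
        theta = np.full(100000, 42.0)
        ds = gen_voxel_dataset(params, theta, seed=5)
        resid = ds.responses - params.mu(42.0)
        emp = np.cov(resid.T)
        omega = params.covariance()
        scale = np.sqrt(np.outer(np.diag(omega), np.diag(omega)))
        assert np.max(np.abs(emp - omega) / scale) < 0.03

    def test_non_positive_definite_rejected(self):
        from contextfi.encoding import BasisSet, EncodingModelParams

        with pytest.raises(ValueError):
            EncodingModelParams(
                basis=BasisSet(), W=np.ones((3, 8)), channel_sd=0.1,
                tau=np.array([1.0, -1.0, 1.0]), rho=0.2,
            )

    def test_hdf5_roundtrip(self, tmp_path):
        params = random_encoding_params(4, seed=3)
        ds = gen_voxel_dataset(params, np.linspace(0, 170, 20), seed=6, prf=True)
        path = tmp_path / "vox.h5"
        ds.to_hdf5(path)
        back = type(ds).from_hdf5(path)
        assert np.allclose(back.responses, ds.responses)
        assert np.allclose(back.prf_center, ds.prf_center)
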