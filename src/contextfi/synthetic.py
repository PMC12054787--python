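"""Synthetic inputs for every stage of the pipeline.

This module generates (i) center/surround grating stimuli with the
experiment's geometry, (ii) behavioral trial tables from a ground-truth
observer with known orientation-dependent bias and SD, (iii) voxel
datasets drawn from the population encoding model itself, and
(iv) parametric orientation priors (uniform, cardinal-peaked, and
surround-conditioned). All generators are deterministic given a seed.

Orientation convention: orientations are in [0, 180) degrees measured
clockwise from vertical, so 0 renders vertical stripes and +35 renders
stripes tilted 35 degrees clockwise; reflecting an image about the
vertical axis negates all orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from .circstats import signed_orientation_diff, wrap_orientation
from .encoding import BasisSet, EncodingModelParams, VoxelDataset
from .profiles import PriorProfile

__all__ = [
    "StimulusSpec",
    "DEFAULT_STIMULUS",
    "GroundTruthObserver",
    "oblique_observer",
    "observer_from_prior",
    "gen_stimulus_image",
    "gen_behavioral_trials",
    "gen_prior",
    "gen_voxel_dataset",
    "random_encoding_params",
    "write_trials",
    "read_trials",
    "write_image",
]


# ---------------------------------------------------------------------------
# stimuli


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and rendering parameters of the center/surround stimulus.

    Defaults follow the experiment: a mid-gray disk of 1.5 degrees radius
    (with a 0.35-degree fixation dot), a 1 cycle-per-degree center grating
    from 1.5 to 7 degrees, a surround annulus from 7 to 12.5 degrees, and
    20% peak contrast. The raster is 256 x 256 pixels at 0.1 degrees per
    pixel, covering +/- 12.8 degrees of eccentricity.
    """

    center_inner_radius: float = 1.5
    center_outer_radius: float = 7.0
    surround_outer_radius: float = 12.5
    spatial_frequency: float = 1.0
    peak_contrast: float = 0.2
    image_size: int = 256
    degrees_per_pixel: float = 0.1
    fixation_radius: float = 0.35
    noise_bandwidth_octaves: float = 1.0
    oversample: int = 2  # anti-aliasing: render at oversample x and box-average
    edge_taper_deg: float = 0.0  # raised-cosine contrast ramp at annulus edges

    def __post_init__(self):
        if not (
            0 < self.center_inner_radius < self.center_outer_radius < self.surround_outer_radius
        ):
            raise ValueError("radii must satisfy 0 < inner < outer < surround")
        if not (0 < self.peak_contrast <= 1):
            raise ValueError("peak_contrast must be in (0, 1]")
        if self.image_size <= 0 or self.degrees_per_pixel <= 0:
            raise ValueError("image raster must have positive size")
        if self.oversample < 1:
            raise ValueError("oversample must be at least 1")


DEFAULT_STIMULUS = StimulusSpec()


def spec_from_config(config: dict) -> StimulusSpec:
    """Build a StimulusSpec from a config mapping (e.g. parsed YAML/JSON)."""
    return StimulusSpec(**config)


def write_image(img: np.ndarray, path) -> None:
    """Write a [0, 1] float image as an 8-bit grayscale PNG."""
    from PIL import Image

    data = np.clip(np.round(np.asarray(img) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path, format="PNG")


def _grids(spec: StimulusSpec):
    n = spec.image_size * spec.oversample
    coords = (np.arange(n) - (n - 1) / 2.0) * (
        spec.degrees_per_pixel / spec.oversample
    )
    x = coords[None, :]
    y = -coords[:, None]  # row 0 is the top of the image
    return x, y, np.hypot(x, y)


def _downsample(img, oversample: int):
    """Box-average oversampled pixels back to the output raster."""
    if oversample == 1:
        return img
    n = img.shape[0] // oversample
    return img.reshape(n, oversample, n, oversample).mean(axis=(1, 3))


def _annulus_weight(r, inner, outer, taper):
    """Radial contrast window: 1 inside [inner, outer], raised-cosine ramps
    of width ``taper`` just inside both edges, 0 outside."""
    if taper <= 0:
        return ((r >= inner) & (r < outer)).astype(float)
    w = np.zeros_like(r)
    core = (r >= inner + taper) & (r <= outer - taper)
    w[core] = 1.0
    rise = (r >= inner) & (r < inner + taper)
    w[rise] = 0.5 * (1.0 - np.cos(np.pi * (r[rise] - inner) / taper))
    fall = (r > outer - taper) & (r < outer)
    w[fall] = 0.5 * (1.0 - np.cos(np.pi * (outer - r[fall]) / taper))
    return w


def _grating(x, y, orientation_deg, spatial_frequency, phase):
    """Unit-amplitude sinusoidal grating; orientation clockwise from vertical."""
    ang = np.deg2rad(orientation_deg)
    # stripes along direction (sin a, cos a); wave vector perpendicular to it
    u = x * np.cos(ang) - y * np.sin(ang)
    return np.cos(2.0 * np.pi * spatial_frequency * u + phase)


def _bandpass_noise(rng, spec: StimulusSpec, rotation_deg: float = 0.0, n_waves: int = 128):
    """Isotropic band-pass noise, unit SD, as a seeded sum of plane waves.

    Component radial frequencies are log-Gaussian around the grating
    spatial frequency (FWHM ``noise_bandwidth_octaves``), orientations and
    phases uniform, amplitudes Rayleigh — an approximately Gaussian,
    stationary, isotropic texture. Because the texture is analytic in its
    component angles, it can be rotated rigidly (``rotation_deg``) with no
    resampling: the same seed with a rotation yields the exact same
    texture turned about the image center.
    """
    x, y, _ = _grids(spec)
    sd_oct = spec.noise_bandwidth_octaves / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    freqs = spec.spatial_frequency * 2.0 ** (sd_oct * rng.standard_normal(n_waves))
    # sign matches the grating convention (clockwise from vertical)
    angles = rng.uniform(0.0, 2.0 * np.pi, n_waves) - np.deg2rad(rotation_deg)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_waves)
    amps = rng.rayleigh(1.0, n_waves)
    kx = 2.0 * np.pi * freqs * np.cos(angles)
    ky = 2.0 * np.pi * freqs * np.sin(angles)
    # field = Re sum_k c_k exp(i kx x) exp(i ky y): a rank-M outer-product
    # sum evaluated as one complex matmul over the separable exponentials
    ex = np.exp(1j * kx[:, None] * x.ravel()[None, :])  # (M, n) columns
    ey = np.exp(1j * ky[:, None] * y.ravel()[None, :])  # (M, n) rows
    c = amps * np.exp(1j * phases)
    field = ((c[:, None] * ey).T @ ex).real
    return field / field.std()


def gen_stimulus_image(
    center_orientation: float,
    surround_kind: str = "noise",
    surround_orientation: float = 0.0,
    spec: StimulusSpec = DEFAULT_STIMULUS,
    seed: int | None = 0,
    phase_center: float | None = None,
    phase_surround: float | None = None,
    noise_rotation: float = 0.0,
) -> np.ndarray:
    """Render one stimulus image as floats in [0, 1] (mid-gray = 0.5).

    ``surround_kind`` is ``"none"`` (mid-gray annulus), ``"noise"``
    (spatial-frequency-matched isotropic band-pass noise), or
    ``"oriented"`` (grating at ``surround_orientation``). Grating phases
    default to random (seed-controlled) so that phase carries no
    orientation information in expectation; pass explicit phases for
    deterministic rendering. ``noise_rotation`` turns the (seed-fixed)
    noise texture rigidly about the image center, which lets a sweep
    rotate the whole baseline stimulus rather than only its center.
    """
    if surround_kind not in ("none", "noise", "oriented"):
        raise ValueError(f"unknown surround kind {surround_kind!r}")
    rng = np.random.default_rng(seed)
    if phase_center is None:
        phase_center = rng.uniform(0.0, 2.0 * np.pi)
    if phase_surround is None:
        phase_surround = rng.uniform(0.0, 2.0 * np.pi)

    x, y, r = _grids(spec)
    n_hi = spec.image_size * spec.oversample
    img = np.full((n_hi, n_hi), 0.5)

    w_center = _annulus_weight(
        r, spec.center_inner_radius, spec.center_outer_radius, spec.edge_taper_deg
    )
    grating = _grating(
        x, y, center_orientation, spec.spatial_frequency, phase_center
    )
    img += 0.5 * spec.peak_contrast * w_center * grating

    w_surround = _annulus_weight(
        r, spec.center_outer_radius, spec.surround_outer_radius, spec.edge_taper_deg
    )
    if surround_kind == "oriented":
        sg = _grating(
            x, y, surround_orientation, spec.spatial_frequency, phase_surround
        )
        img += 0.5 * spec.peak_contrast * w_surround * sg
    elif surround_kind == "noise":
        noise = _bandpass_noise(rng, spec, rotation_deg=noise_rotation)
        # match the grating's RMS contrast; clip at peak contrast
        noise = np.clip(noise / np.sqrt(2.0), -1.0, 1.0)
        img += 0.5 * spec.peak_contrast * w_surround * noise
    return _downsample(img, spec.oversample)


# ---------------------------------------------------------------------------
# behavioral trials


@dataclass
class GroundTruthObserver:
    """Known bias and SD curves used to generate estimation trials.

    Both functions take orientation in degrees and return degrees; both
    must be 180-periodic and ``sd_fn`` strictly positive.
    """

    bias_fn: Callable[[np.ndarray], np.ndarray]
    sd_fn: Callable[[np.ndarray], np.ndarray]

    def fi(self, theta, dtheta: float = 1e-3) -> np.ndarray:
        """Analytic Fisher information implied by the bias/SD curves,
        J = (1 + b')^2 / sigma^2 (the bound assumed tight)."""
        theta = np.asarray(theta, dtype=float)
        bp = (self.bias_fn(theta + dtheta) - self.bias_fn(theta - dtheta)) / (
            2.0 * dtheta
        )
        return (1.0 + bp) ** 2 / self.sd_fn(theta) ** 2


def oblique_observer(
    bias_amplitude: float = 4.0,
    sd_mean: float = 3.5,
    sd_amplitude: float = 0.8,
) -> GroundTruthObserver:
    """Observer reproducing the oblique effect.

    Bias is repulsive away from the cardinal orientations
    (b = A sin(4 pi theta / 180)) and SD is larger at cardinals than at
    obliques, so that the implied FI peaks at 0 and 90 degrees.
    """

    def bias(theta):
        return bias_amplitude * np.sin(np.deg2rad(4.0 * np.asarray(theta, float)))

    def sd(theta):
        return sd_mean + sd_amplitude * np.cos(
            np.deg2rad(4.0 * np.asarray(theta, float))
        )

    if sd_mean <= sd_amplitude:
        raise ValueError("sd must stay positive")
    return GroundTruthObserver(bias_fn=bias, sd_fn=sd)


def observer_from_prior(
    prior: PriorProfile, total_resource: float = 60.0
) -> GroundTruthObserver:
    """Unbiased observer whose estimation SD realizes a target FI shape.

    Under efficient coding sqrt(J) is proportional to the prior density;
    with zero bias, sigma = 1/sqrt(J) = 1/(total_resource * density).
    """

    def bias(theta):
        return np.zeros_like(np.asarray(theta, dtype=float))

    def sd(theta):
        return 1.0 / (total_resource * prior.density_at(theta))

    return GroundTruthObserver(bias_fn=bias, sd_fn=sd)


def gen_behavioral_trials(
    observer: GroundTruthObserver,
    n_trials: int,
    seed: int = 0,
    condition: str = "baseline",
) -> pd.DataFrame:
    """Generate an estimation trial table from a ground-truth observer.

    Stimulus orientations are uniform on [0, 180); the reported estimate is
    theta + bias(theta) + N(0, sd(theta)^2), wrapped back into the
    orientation domain. Columns: trial_id, condition, theta_deg,
    estimate_deg.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 180.0, size=n_trials)
    noise = rng.standard_normal(n_trials) * observer.sd_fn(theta)
    estimate = wrap_orientation(theta + observer.bias_fn(theta) + noise)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "condition": condition,
            "theta_deg": theta,
            "estimate_deg": estimate,
        }
    )


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"theta_deg", "estimate_deg"} - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# priors


def gen_prior(
    family: str,
    grid_step: float = 0.5,
    cardinal_weight: float = 0.4,
    cardinal_concentration: float = 1.5,
    surround_deg: float = 35.0,
    surround_weight: float = 0.15,
    surround_concentration: float = 15.0,
    baseline: PriorProfile | None = None,
) -> PriorProfile:
    """Parametric 180-periodic orientation priors.

    ``uniform``
        flat density 1/180 per degree.
    ``cardinal_peaked``
        mixture of a uniform floor and von Mises bumps (doubled angle) at
        the cardinal orientations 0 and 90; emulates the long-term
        orientation statistics of natural scenes.
    ``surround_conditioned``
        a baseline prior (cardinal-peaked unless given) plus a localized
        von Mises bump at the surround orientation; emulates the
        distribution of center orientation conditioned on the dominant
        surround orientation.
    """
    if cardinal_concentration < 0 or surround_concentration < 0:
        raise ValueError("concentration parameters must be nonnegative")
    grid = np.arange(0.0, 180.0, grid_step)
    if family == "uniform":
        return PriorProfile(grid, np.full(grid.size, 1.0 / 180.0))
    if family == "cardinal_peaked":
        ang = np.deg2rad(2.0 * grid)  # cardinal bumps: period-90 structure
        from scipy.special import i0

        vm = np.exp(cardinal_concentration * np.cos(2.0 * ang)) / (
            2.0 * np.pi * i0(cardinal_concentration)
        )
        density = (1.0 - cardinal_weight) / 180.0 + cardinal_weight * vm * (
            2.0 * np.pi / 180.0
        )
        return PriorProfile(grid, density).normalize()
    if family == "surround_conditioned":
        base = (
            gen_prior(
                "cardinal_peaked",
                grid_step=grid_step,
                cardinal_weight=cardinal_weight,
                cardinal_concentration=cardinal_concentration,
            )
            if baseline is None
            else baseline
        )
        from scipy.special import i0

        ang = np.deg2rad(2.0 * (base.grid - surround_deg))
        bump = np.exp(surround_concentration * np.cos(ang)) / (
            2.0 * np.pi * i0(surround_concentration)
        )
        density = (1.0 - surround_weight) * base.density + surround_weight * bump * (
            2.0 * np.pi / 180.0
        )
        return PriorProfile(base.grid.copy(), density).normalize()
    raise ValueError(f"unknown prior family {family!r}")


# ---------------------------------------------------------------------------
# voxel datasets


def random_encoding_params(
    n_voxels: int = 30,
    seed: int = 0,
    basis: BasisSet | None = None,
    channel_sd: float = 0.3,
    tau_mean: float = 1.0,
    tau_spread: float = 0.2,
    rho: float = 0.05,
    weight_scale: float = 1.0,
) -> EncodingModelParams:
    """Draw a random but valid parameter set for the generative model.

    Weights are i.i.d. Gaussian scaled by ``weight_scale``; tau is
    log-normal around ``tau_mean``.
    """
    rng = np.random.default_rng(seed)
    if basis is None:
        basis = BasisSet()
    W = weight_scale * rng.standard_normal((n_voxels, basis.n_basis))
    tau = tau_mean * np.exp(tau_spread * rng.standard_normal(n_voxels))
    return EncodingModelParams(
        basis=basis, W=W, channel_sd=channel_sd, tau=tau, rho=rho
    )


def gen_voxel_dataset(
    params: EncodingModelParams,
    orientations,
    seed: int = 0,
    warp: PriorProfile | None = None,
    prf: bool = False,
    prf_range: tuple[float, float] = (0.5, 20.0),
) -> VoxelDataset:
    """Draw trial responses from the generative model p(m | theta).

    Each trial's response vector is N(mu(theta), Omega) with mu = W f(theta)
    and Omega = sigma^2 W W^T + Sigma_eta. If ``warp`` is given, the basis
    is evaluated at the efficient-coding warped orientation (the cumulative
    of the prior density mapped back to degrees), which concentrates tuning
    (and hence FI) where the prior is dense; with a uniform warp this is
    the identity. Optional pRF metadata (center eccentricity and size) is
    attached when ``prf`` is True.
    """
    rng = np.random.default_rng(seed)
    theta = wrap_orientation(np.asarray(orientations, dtype=float))
    theta_eval = theta if warp is None else _warp_orientation(theta, warp)
    mu = params.basis.response(theta_eval) @ params.W.T
    chol = params.cholesky()
    noise = rng.standard_normal((theta.size, params.n_voxels)) @ chol.T
    prf_center = prf_size = None
    if prf:
        prf_center = rng.uniform(*prf_range, size=params.n_voxels)
        prf_size = 0.1 + 0.25 * prf_center  # sizes grow with eccentricity
    return VoxelDataset(
        responses=mu + noise,
        theta=theta,
        prf_center=prf_center,
        prf_size=prf_size,
    )


def _warp_orientation(theta, prior: PriorProfile) -> np.ndarray:
    """Map orientation through the prior CDF, rescaled to [0, 180)."""
    cdf = np.cumsum(prior.density) * prior.step
    cdf = np.concatenate([[0.0], cdf])
    grid = np.concatenate([prior.grid, [prior.grid[0] + 180.0]])
    return 180.0 * np.interp(np.mod(theta, 180.0), grid, cdf / cdf[-1])
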