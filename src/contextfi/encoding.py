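"""Probabilistic voxel population encoding model of orientation.

The model describes a trial's voxel activity vector m (K voxels) as a
weighted sum of J orientation-tuned basis channels plus two Gaussian noise
sources::

    m = W (f(theta) + eps) + eta,   eps ~ N(0, sigma^2 I_J),
    eta ~ N(0, Sigma_eta),          Sigma_eta = rho tau tau^T + (1-rho) I o tau tau^T

so that p(m | theta) = N(m; mu(theta), Omega) with mu(theta) = W f(theta)
and Omega = sigma^2 W W^T + Sigma_eta. The basis channels are rectified
cosines raised to a power, with preferred orientations equally spaced over
[0, 180).

Fitting is two-stage: ordinary least squares for W, then maximum
likelihood for the noise parameters (sigma, tau, rho) with W held fixed.
Orientation is decoded per trial as the maximum-likelihood orientation on
a grid, and the observed Fisher information is the negative second
derivative of the log-likelihood at the true orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .circstats import circ_corr_orientation, circ_mean_orientation, wrap_orientation
from .profiles import FIProfile

__all__ = [
    "BasisSet",
    "EncodingModelParams",
    "VoxelDataset",
    "LikelihoodProfile",
    "VoxelEncodingModel",
    "basis_response",
    "fit_weights",
    "fit_noise",
    "residual_covariance",
    "log_likelihood",
    "decode_mle",
    "observed_fi",
    "observed_fi_exact",
    "analytic_fi",
    "crossval_fit",
    "window_average_fi",
    "circular_correlation",
    "surround_modulation_index",
    "roi_select",
    "ROI_RULES",
]


# ---------------------------------------------------------------------------
# model components


@dataclass
class BasisSet:
    """Rectified-cosine orientation channels.

    ``n_basis`` channels with preferred orientations ``phase_offset + j *
    180/n_basis``; channel response max(0, cos(pi (theta - phi_j)/90)) **
    ``exponent``.
    """

    n_basis: int = 8
    exponent: float = 5.0
    phase_offset: float = 0.0

    def __post_init__(self):
        if self.n_basis < 2:
            raise ValueError("need at least 2 basis channels")

    @property
    def preferred_orientations(self) -> np.ndarray:
        return wrap_orientation(
            self.phase_offset + np.arange(self.n_basis) * (180.0 / self.n_basis)
        )

    def response(self, theta) -> np.ndarray:
        """Channel responses f(theta); output shape theta.shape + (n_basis,)."""
        theta = np.asarray(theta, dtype=float)
        delta = theta[..., None] - self.preferred_orientations
        # cos(pi * delta / 90) has period 180 in delta, so circularity is free
        half = np.maximum(0.0, np.cos(np.pi * delta / 90.0))
        return half**self.exponent


def basis_response(theta, basis: BasisSet) -> np.ndarray:
    """Basis channel response vector f(theta)."""
    return basis.response(theta)


def residual_covariance(tau, rho) -> np.ndarray:
    """Voxel residual covariance: rho*tau tau^T off-diagonal, tau_i^2 diagonal."""
    tau = np.asarray(tau, dtype=float)
    outer = np.outer(tau, tau)
    return rho * outer + (1.0 - rho) * np.diag(tau**2)


@dataclass
class EncodingModelParams:
    """Full parameter set (W, sigma, tau, rho) of the generative model."""

    basis: BasisSet
    W: np.ndarray  # (K, J)
    channel_sd: float
    tau: np.ndarray  # (K,)
    rho: float
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.tau = np.asarray(self.tau, dtype=float)
        if self.W.shape[1] != self.basis.n_basis:
            raise ValueError("W column count must match basis size")
        if self.W.shape[0] != self.tau.size:
            raise ValueError("tau length must match voxel count")
        if self.channel_sd < 0:
            raise ValueError("channel_sd must be nonnegative")
        if np.any(self.tau <= 0):
            raise ValueError("tau must be positive")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")

    @property
    def n_voxels(self) -> int:
        return self.W.shape[0]

    def mu(self, theta) -> np.ndarray:
        """Mean response mu(theta) = W f(theta)."""
        return self.basis.response(theta) @ self.W.T

    def covariance(self) -> np.ndarray:
        return self.channel_sd**2 * (self.W @ self.W.T) + residual_covariance(
            self.tau, self.rho
        )

    def cholesky(self) -> np.ndarray:
        """Lower Cholesky factor of Omega (cached; Omega is theta-independent)."""
        if self._chol is None:
            try:
                self._chol = sla.cholesky(self.covariance(), lower=True)
            except sla.LinAlgError as err:
                raise ValueError("Omega is not positive definite") from err
        return self._chol


@dataclass
class VoxelDataset:
    """Trials-by-voxels responses with per-trial orientations.

    ``prf_center`` / ``prf_size`` are optional per-voxel population
    receptive field summaries (visual degrees) used for eccentricity ROI
    selection.
    """

    responses: np.ndarray  # (N, K)
    theta: np.ndarray  # (N,)
    prf_center: np.ndarray | None = None
    prf_size: np.ndarray | None = None

    def __post_init__(self):
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        self.theta = np.asarray(self.theta, dtype=float)
        if self.responses.shape[0] != self.theta.size:
            raise ValueError("responses and theta disagree on trial count")

    @property
    def n_trials(self) -> int:
        return self.responses.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.responses.shape[1]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("responses", data=self.responses)
            f.create_dataset("theta_deg", data=self.theta)
            if self.prf_center is not None:
                f.create_dataset("prf_center_deg", data=self.prf_center)
            if self.prf_size is not None:
                f.create_dataset("prf_size_deg", data=self.prf_size)

    @classmethod
    def from_hdf5(cls, path) -> "VoxelDataset":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                responses=f["responses"][...],
                theta=f["theta_deg"][...],
                prf_center=(
                    f["prf_center_deg"][...] if "prf_center_deg" in f else None
                ),
                prf_size=f["prf_size_deg"][...] if "prf_size_deg" in f else None,
            )


@dataclass
class LikelihoodProfile:
    """Orientation log-likelihood of one trial on a uniform grid."""

    grid: np.ndarray
    loglik: np.ndarray
    mle: float
    observed_fi: float | None = None


# ---------------------------------------------------------------------------
# two-stage fitting


def fit_weights(data: VoxelDataset, basis: BasisSet) -> np.ndarray:
    """Stage one: ordinary least-squares channel weights, W-hat = (X'X)^-1 X'M.

    Returns W with shape (K voxels, J channels).
    """
    X = basis.response(data.theta)  # (N, J)
    if data.n_trials <= basis.n_basis:
        raise ValueError("need more trials than basis channels for OLS")
    gram = X.T @ X
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("basis design matrix is rank deficient")
    return np.linalg.solve(gram, X.T @ data.responses).T


def _noise_nll(params_vec, scatter, WWt, n_trials, n_voxels):
    """Negative log-likelihood of residuals (constant dropped) and its
    gradient in (sigma, rho, tau).

    ``scatter`` is R^T R of the stage-one residuals, so each evaluation is
    O(K^3) independent of trial count. The gradient uses
    d NLL = 0.5 tr[(N Omega^-1 - Omega^-1 S Omega^-1) d Omega].
    """
    sigma = params_vec[0]
    rho = params_vec[1]
    tau = params_vec[2:]
    omega = sigma**2 * WWt + residual_covariance(tau, rho)
    try:
        c, low = sla.cho_factor(omega, lower=True)
    except sla.LinAlgError:
        return 1e300, np.zeros_like(params_vec)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    inv_s = sla.cho_solve((c, low), scatter)  # Omega^-1 S
    nll = 0.5 * (n_trials * logdet + np.trace(inv_s))

    inv = sla.cho_solve((c, low), np.eye(len(tau)))
    a = n_trials * inv - inv_s @ inv  # N Omega^-1 - Omega^-1 S Omega^-1
    a = 0.5 * (a + a.T)
    grad = np.empty_like(params_vec)
    grad[0] = sigma * np.sum(a * WWt)
    outer = np.outer(tau, tau)
    grad[1] = 0.5 * (np.sum(a * outer) - np.sum(np.diag(a) * tau**2))
    grad[2:] = rho * (a @ tau) + (1.0 - rho) * tau * np.diag(a)
    return nll, grad


def fit_noise(
    data: VoxelDataset,
    W: np.ndarray,
    basis: BasisSet,
    n_starts: int = 3,
    maxiter: int = 300,
):
    """Stage two: ML estimate of (sigma, tau, rho) with W fixed.

    Multi-start SLSQP on (sigma, rho); tau is initialized at the per-voxel
    residual SDs. Returns ``(channel_sd, tau, rho, info)`` where ``info``
    carries convergence diagnostics and the final log-likelihood.
    """
    X = basis.response(data.theta)
    resid = data.responses - X @ W.T
    scatter = resid.T @ resid
    WWt = W @ W.T
    n, k = resid.shape
    tau0 = np.maximum(resid.std(axis=0, ddof=1), 1e-3)

    starts = [(0.3, 0.05), (0.1, 0.3), (0.6, 0.01)][:n_starts]
    bounds = [(0.0, None), (0.0, 0.99)] + [(1e-4, None)] * k
    best = None
    n_converged = 0
    for sigma0, rho0 in starts:
        x0 = np.concatenate([[sigma0, rho0], tau0])
        res = optimize.minimize(
            _noise_nll,
            x0,
            args=(scatter, WWt, n, k),
            method="SLSQP",
            jac=True,
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-9},
        )
        n_converged += bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if n_converged == 0:
        warnings.warn(
            "noise-parameter optimizer did not report convergence from any "
            "start; returning best candidate",
            RuntimeWarning,
        )
    sigma = float(best.x[0])
    rho = float(best.x[1])
    tau = np.asarray(best.x[2:])
    const = 0.5 * n * k * np.log(2.0 * np.pi)
    info = {
        "converged": n_converged > 0,
        "n_starts_converged": int(n_converged),
        "loglik": float(-(best.fun + const)),
        "message": str(best.message),
    }
    return sigma, tau, rho, info


# ---------------------------------------------------------------------------
# likelihood, decoding, observed FI


def log_likelihood(m, theta, params: EncodingModelParams) -> float:
    """Exact multivariate-normal log-density log p(m | theta)."""
    chol = params.cholesky()
    diff = np.asarray(m, dtype=float) - params.mu(float(theta))
    z = sla.solve_triangular(chol, diff, lower=True)
    k = params.n_voxels
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return float(-0.5 * (k * np.log(2.0 * np.pi) + logdet + z @ z))


def _loglik_grid(m, params: EncodingModelParams, grid: np.ndarray) -> np.ndarray:
    chol = params.cholesky()
    mu = params.mu(grid)  # (T, K)
    diff = np.asarray(m, dtype=float)[None, :] - mu
    z = sla.solve_triangular(chol, diff.T, lower=True)
    quad = np.einsum("ij,ij->j", z, z)
    k = params.n_voxels
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (k * np.log(2.0 * np.pi) + logdet + quad)


def decode_mle(
    m, params: EncodingModelParams, grid_step: float = 0.5
) -> LikelihoodProfile:
    """Maximum-likelihood orientation decoding on a uniform grid.

    Ties at the argmax resolve to the lowest grid index.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    grid = np.arange(0.0, 180.0, grid_step)
    ll = _loglik_grid(m, params, grid)
    return LikelihoodProfile(grid=grid, loglik=ll, mle=float(grid[np.argmax(ll)]))


def observed_fi(profile: LikelihoodProfile, theta_true: float) -> float:
    """Observed FI from a gridded log-likelihood: -l''(theta*) by centered
    second differences, linearly interpolated between the two bracketing
    grid points when theta* falls off-grid."""
    grid = profile.grid
    step = grid[1] - grid[0]
    n = grid.size
    ll = profile.loglik
    second = (np.roll(ll, -1) - 2.0 * ll + np.roll(ll, 1)) / step**2
    pos = wrap_orientation(theta_true) / step
    i0 = int(np.floor(pos)) % n
    frac = pos - np.floor(pos)
    val = (1.0 - frac) * second[i0] + frac * second[(i0 + 1) % n]
    return float(-val)


def observed_fi_exact(
    m, theta_true: float, params: EncodingModelParams, step: float = 0.5
) -> float:
    """Observed FI by centered second differences of the exact log-density
    evaluated at theta* and theta* +/- step (no grid involved)."""
    lm = log_likelihood(m, theta_true - step, params)
    l0 = log_likelihood(m, theta_true, params)
    lp = log_likelihood(m, theta_true + step, params)
    return float(-(lp - 2.0 * l0 + lm) / step**2)


def analytic_fi(params: EncodingModelParams, theta, dtheta: float = 1e-3) -> float:
    """Gaussian-model Fisher information mu'(theta)^T Omega^-1 mu'(theta).

    This is the expectation of the observed FI over response noise.
    """
    dmu = (params.mu(theta + dtheta) - params.mu(theta - dtheta)) / (2.0 * dtheta)
    chol = params.cholesky()
    z = sla.solve_triangular(chol, dmu, lower=True)
    return float(z @ z)


# ---------------------------------------------------------------------------
# estimator


class VoxelEncodingModel(BaseEstimator):
    """Scikit-learn style estimator wrapping the two-stage fit and decoding.

    Parameters
    ----------
    n_basis, exponent, phase_offset : basis configuration.
    grid_step : orientation grid spacing (degrees) for decoding.
    n_starts : multi-start count for the noise-parameter optimizer.

    Attributes (after ``fit``)
    --------------------------
    W_ : (K, J) channel weights.
    channel_sd_, tau_, rho_ : noise parameters.
    loglik_ : final training log-likelihood of the noise stage.
    converged_ : whether any optimizer start reported convergence.
    """

    def __init__(
        self,
        n_basis: int = 8,
        exponent: float = 5.0,
        phase_offset: float = 0.0,
        grid_step: float = 0.5,
        n_starts: int = 3,
    ):
        self.n_basis = n_basis
        self.exponent = exponent
        self.phase_offset = phase_offset
        self.grid_step = grid_step
        self.n_starts = n_starts

    @property
    def basis_(self) -> BasisSet:
        return BasisSet(self.n_basis, self.exponent, self.phase_offset)

    def fit(self, X, y):
        """Fit to responses ``X`` (N trials x K voxels) and orientations ``y``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on trial count")
        if not np.all(np.isfinite(X)):
            raise ValueError("responses must be finite")
        var = X.var(axis=0)
        if np.any(var == 0):
            keep = var > 0
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance voxel(s) before "
                "fitting",
                RuntimeWarning,
            )
            X = X[:, keep]
        data = VoxelDataset(responses=X, theta=wrap_orientation(y))
        basis = self.basis_
        self.W_ = fit_weights(data, basis)
        sigma, tau, rho, info = fit_noise(data, self.W_, basis, self.n_starts)
        self.channel_sd_, self.tau_, self.rho_ = sigma, tau, rho
        self.loglik_ = info["loglik"]
        self.converged_ = info["converged"]
        self.fit_info_ = info
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def params_(self) -> EncodingModelParams:
        return EncodingModelParams(
            basis=self.basis_,
            W=self.W_,
            channel_sd=self.channel_sd_,
            tau=self.tau_,
            rho=self.rho_,
        )

    def decode(self, m) -> LikelihoodProfile:
        return decode_mle(m, self.params_, self.grid_step)

    def predict(self, X) -> np.ndarray:
        """Decoded (maximum-likelihood) orientation per trial."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        params = self.params_
        return np.array(
            [decode_mle(row, params, self.grid_step).mle for row in X]
        )

    def observed_fi(self, X, theta_true) -> np.ndarray:
        """Observed FI at the true orientation for each trial."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        theta_true = np.atleast_1d(np.asarray(theta_true, dtype=float))
        params = self.params_
        return np.array(
            [
                observed_fi_exact(row, t, params, self.grid_step)
                for row, t in zip(X, theta_true)
            ]
        )


# ---------------------------------------------------------------------------
# cross-validated decoding and FI


def crossval_fit(
    data: VoxelDataset,
    n_folds: int = 20,
    n_phase_models: int = 4,
    seed: int = 0,
    n_basis: int = 8,
    exponent: float = 5.0,
    grid_step: float = 0.5,
    n_starts: int = 3,
) -> pd.DataFrame:
    """Cross-validated decoding and observed FI for every trial.

    Trials are shuffled (seeded) and split into ``n_folds`` contiguous
    folds; each fold is decoded with models fit on the remaining folds. An
    ensemble of ``n_phase_models`` basis sets with phase offsets equally
    spaced over one inter-channel spacing is fit, and per-trial results are
    averaged across the ensemble (observed FI arithmetically, decoded
    orientation circularly).

    Returns a DataFrame with columns trial, fold, theta_deg, mle_deg,
    observed_fi.
    """
    n = data.n_trials
    if n_folds < 2 or n_folds > n:
        raise ValueError("fold count must be in [2, n_trials]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    # contiguous blocks after the shuffle; remainders spread over early folds
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        if chunk.size == 0:
            raise ValueError("a fold received zero trials")
        fold_of[chunk] = f

    offsets = np.arange(n_phase_models) * (180.0 / n_basis) / n_phase_models
    mles = np.zeros((n_phase_models, n))
    fis = np.zeros((n_phase_models, n))
    for p, off in enumerate(offsets):
        for f in range(n_folds):
            held = fold_of == f
            model = VoxelEncodingModel(
                n_basis=n_basis,
                exponent=exponent,
                phase_offset=float(off),
                grid_step=grid_step,
                n_starts=n_starts,
            ).fit(data.responses[~held], data.theta[~held])
            params = model.params_
            for i in np.where(held)[0]:
                prof = decode_mle(data.responses[i], params, grid_step)
                mles[p, i] = prof.mle
                fis[p, i] = observed_fi(prof, data.theta[i])

    mle_avg = (
        mles[0]
        if n_phase_models == 1
        else circ_mean_orientation(mles, axis=0)
    )
    return pd.DataFrame(
        {
            "trial": np.arange(n),
            "fold": fold_of,
            "theta_deg": data.theta,
            "mle_deg": mle_avg,
            "observed_fi": fis.mean(axis=0),
        }
    )


def window_average_fi(
    theta,
    j,
    window_deg: float = 25.0,
    centers=None,
    normalize: bool = False,
) -> FIProfile:
    """Average per-trial observed FI within a sliding circular window.

    ``fi(center)`` is the mean of ``j`` over trials whose true orientation
    lies within ``window_deg`` centered at ``center`` (circular distance);
    ``sem`` is the within-window standard error. Empty windows give NaN.
    """
    theta = np.asarray(theta, dtype=float)
    j = np.asarray(j, dtype=float)
    if centers is None:
        centers = np.arange(0.0, 180.0, 1.0)
    centers = np.asarray(centers, dtype=float)
    half = window_deg / 2.0
    fi = np.full(centers.size, np.nan)
    sem = np.full(centers.size, np.nan)
    for i, c in enumerate(centers):
        d = np.abs(90.0 - np.mod(90.0 - (theta - c), 180.0))
        sel = d <= half
        cnt = int(sel.sum())
        if cnt >= 1:
            fi[i] = j[sel].mean()
            sem[i] = j[sel].std(ddof=1) / np.sqrt(cnt) if cnt > 1 else 0.0
    prof = FIProfile(grid=centers, fi=fi, sem=sem, meta={"window_deg": window_deg})
    return prof.normalized() if normalize else prof


circular_correlation = circ_corr_orientation


def surround_modulation_index(
    theta_surr,
    j_surr,
    theta_base,
    j_base,
    window=(22.5, 47.5),
):
    """Percentage change of observed FI near the surround orientation.

    The surround-minus-baseline difference of the mean unnormalized
    observed FI within ``window`` is expressed as a percentage of the
    baseline mean FI across all orientations; significance is an unpaired
    (Welch) t test on the within-window samples.

    Returns ``(percent_change, t_statistic, p_value)``.
    """
    theta_surr = np.asarray(theta_surr, dtype=float)
    theta_base = np.asarray(theta_base, dtype=float)
    j_surr = np.asarray(j_surr, dtype=float)
    j_base = np.asarray(j_base, dtype=float)
    lo, hi = window

    def in_window(t):
        span = np.mod(hi - lo, 180.0)
        return np.mod(t - lo, 180.0) <= span

    s = j_surr[in_window(theta_surr)]
    b = j_base[in_window(theta_base)]
    if s.size == 0 or b.size == 0:
        raise ValueError("empty surround/baseline window")
    percent = 100.0 * (s.mean() - b.mean()) / j_base.mean()
    tt = stats.ttest_ind(s, b, equal_var=False)
    return float(percent), float(tt.statistic), float(tt.pvalue)


# ---------------------------------------------------------------------------
# eccentricity ROI selection

# (lambda c, s) -> boolean mask; thresholds in visual degrees
ROI_RULES = {
    "center_inner": lambda c, s, t=(1.5,): c + 2 * s < t[0],
    "center_outer": lambda c, s, t=(1.5, 5.0): (t[0] < c + 2 * s) & (c + 2 * s < t[1]),
    "boundary": lambda c, s, t=(5.0, 9.0): (t[0] < c) & (c < t[1]),
    "surround_inner": lambda c, s, t=(9.0, 15.0): (t[0] < c - 2 * s)
    & (c - 2 * s < t[1]),
    "surround_outer": lambda c, s, t=(15.0, 30.0): (t[0] < c - 2 * s)
    & (c - 2 * s < t[1]),
}


def roi_select(data: VoxelDataset, rule: str, thresholds=None) -> VoxelDataset:
    """Select voxels by pRF eccentricity rule.

    Rules place voxels strictly inside the stimulus center
    (``center_inner``, ``center_outer``), at the center-surround boundary
    (``boundary``), or strictly inside the surround (``surround_inner``,
    ``surround_outer``), using the pRF center c and size s as c +/- 2s
    margins.
    """
    if data.prf_center is None or data.prf_size is None:
        raise ValueError("ROI selection requires pRF metadata")
    if rule not in ROI_RULES:
        raise KeyError(f"unknown ROI rule {rule!r}")
    fn = ROI_RULES[rule]
    c = np.asarray(data.prf_center, dtype=float)
    s = np.asarray(data.prf_size, dtype=float)
    mask = fn(c, s) if thresholds is None else fn(c, s, tuple(thresholds))
    return VoxelDataset(
        responses=data.responses[:, mask],
        theta=data.theta,
        prf_center=c[mask],
        prf_size=s[mask],
    )
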