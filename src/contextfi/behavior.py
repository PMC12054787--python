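"""Behavioral Fisher information from orientation-estimation trials.

The Cramér–Rao lower bound ties the bias b(theta) and variance
sigma^2(theta) of an estimator to the Fisher information of the underlying
sensory encoding:

    J(theta) >= (1 + b'(theta))^2 / sigma^2(theta)

Assuming the bound tight (true for maximum-likelihood and Bayesian
decoders alike), the right-hand side read off a sliding-window analysis of
trial-by-trial estimation errors measures encoding precision without
committing to a decoding model. The square root of J, normalized to unit
integral, doubles as the orientation prior implied by efficient coding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .circstats import signed_orientation_diff, wrap_orientation
from .profiles import BiasProfile, FIProfile

__all__ = [
    "signed_circular_error",
    "sliding_bias_sd",
    "crlb_fi",
    "normalize_fi",
    "bootstrap_fi",
    "behavioral_fi",
    "fold_symmetric",
]


def signed_circular_error(theta, estimate):
    """Signed estimation error (estimate - theta) wrapped into (-90, 90]."""
    return signed_orientation_diff(estimate, theta)


def _window_stats(theta, err, grid, half, detrend, min_trials=2):
    """Windowed mean/SD of errors via a sort + prefix-sum sweep.

    With ``detrend``, the SD is computed on errors after subtracting the
    windowed bias curve interpolated at each trial's orientation, which
    removes the variance the bias slope would otherwise contribute.
    """
    order = np.argsort(theta)
    ts = theta[order]
    es = err[order]
    # tile three periods so every window is a contiguous slice
    t3 = np.concatenate([ts - 180.0, ts, ts + 180.0])
    e3 = np.concatenate([es, es, es])
    c1 = np.concatenate([[0.0], np.cumsum(e3)])
    c2 = np.concatenate([[0.0], np.cumsum(e3**2)])
    lo = np.searchsorted(t3, grid - half, side="left")
    hi = np.searchsorted(t3, grid + half, side="right")
    n = (hi - lo).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n >= 1, (c1[hi] - c1[lo]) / n, np.nan)
    if detrend:
        # second pass: residuals around the interpolated bias curve
        ext_grid = np.concatenate([grid, [grid[0] + 180.0]])
        ext_mean = np.concatenate([mean, [mean[0]]])
        fitted = np.interp(np.mod(t3, 180.0), ext_grid, ext_mean)
        r3 = e3 - np.where(np.isfinite(fitted), fitted, 0.0)
        c1r = np.concatenate([[0.0], np.cumsum(r3)])
        c2r = np.concatenate([[0.0], np.cumsum(r3**2)])
        with np.errstate(invalid="ignore", divide="ignore"):
            m_r = (c1r[hi] - c1r[lo]) / n
            var = ((c2r[hi] - c2r[lo]) / n - m_r**2) * n / np.maximum(n - 1, 1)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            var = ((c2[hi] - c2[lo]) / n - mean**2) * n / np.maximum(n - 1, 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    bad = n < min_trials
    mean[bad] = np.nan
    sd[bad] = np.nan
    return mean, sd, n


def sliding_bias_sd(
    trials: pd.DataFrame,
    window_deg: float = 18.0,
    step_deg: float = 0.5,
    detrend: bool = True,
) -> BiasProfile:
    """Sliding-window estimation bias and SD across orientation.

    For each grid point, the bias is the mean signed circular error of
    trials whose stimulus orientation falls within the centered window
    (wrapping at the domain edges) and the SD is the standard deviation of
    those errors. Windows holding fewer than two trials are flagged NaN,
    never silently zeroed. ``detrend`` subtracts the local bias curve
    before the SD pass so that bias slope does not inflate the variance.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    if window_deg <= 0:
        raise ValueError("window_deg must be positive")
    theta = wrap_orientation(trials["theta_deg"].to_numpy(float))
    err = signed_circular_error(theta, trials["estimate_deg"].to_numpy(float))
    grid = np.arange(0.0, 180.0, step_deg)
    mean, sd, n = _window_stats(theta, err, grid, window_deg / 2.0, detrend)
    return BiasProfile(
        grid=grid,
        bias=mean,
        sd=sd,
        window_deg=window_deg,
        step_deg=step_deg,
        n_trials=n,
    )


def _interp_gaps(values, step, max_gap_deg=2.0):
    """Periodic linear interpolation across NaN runs no longer than
    ``max_gap_deg``; longer runs stay missing."""
    v = values.copy()
    nan = np.isnan(v)
    if not nan.any() or nan.all():
        return v
    n = v.size
    idx = np.arange(n)
    ext_idx = np.concatenate([idx[~nan], idx[~nan][:1] + n])
    ext_val = np.concatenate([v[~nan], v[~nan][:1]])
    filled = np.interp(idx, ext_idx, ext_val, period=n)
    # measure each NaN run length; only fill short runs
    runs = []
    in_run = False
    for i in np.concatenate([idx, idx]):  # double sweep to catch wrapped runs
        if np.isnan(values[i % n]) and not in_run:
            in_run, start = True, i
        elif not np.isnan(values[i % n]) and in_run:
            in_run = False
            runs.append((start, i))
    max_pts = int(round(max_gap_deg / step))
    for start, stop in runs:
        if stop - start <= max_pts:
            for i in range(start, stop):
                v[i % n] = filled[i % n]
    return v


def crlb_fi(
    profile: BiasProfile,
    smooth_sd_deg: float | None = 2.0,
    max_gap_deg: float = 2.0,
) -> FIProfile:
    """Fisher information from a bias/SD profile via the Cramér–Rao bound.

    J(theta) = (1 + b'(theta))^2 / sd(theta)^2, with b' from centered
    finite differences on the (optionally Gaussian-smoothed, SD
    ``smooth_sd_deg``) periodic bias curve. NaN gaps no wider than
    ``max_gap_deg`` are interpolated first; wider gaps propagate as
    missing. A zero SD raises (infinite FI): regularize or mask upstream.
    """
    step = profile.step_deg
    bias = _interp_gaps(profile.bias, step, max_gap_deg)
    sd = _interp_gaps(profile.sd, step, max_gap_deg)
    if np.any(sd[np.isfinite(sd)] == 0):
        raise ValueError("sd is zero at some grid points: FI is unbounded there")
    if smooth_sd_deg and smooth_sd_deg > 0:
        finite = np.isfinite(bias)
        if finite.all():
            bias = gaussian_filter1d(bias, smooth_sd_deg / step, mode="wrap")
        # with gaps, smooth only the finite stretch values through a filled copy
        else:
            fill = _interp_gaps(bias, step, max_gap_deg=180.0)
            sm = gaussian_filter1d(fill, smooth_sd_deg / step, mode="wrap")
            bias = np.where(finite, sm, np.nan)
    bprime = (np.roll(bias, -1) - np.roll(bias, 1)) / (2.0 * step)
    with np.errstate(invalid="ignore", divide="ignore"):
        fi = (1.0 + bprime) ** 2 / sd**2
    return FIProfile(
        grid=profile.grid.copy(),
        fi=fi,
        meta={
            "window_deg": profile.window_deg,
            "step_deg": step,
            "smooth_sd_deg": smooth_sd_deg,
        },
    )


def normalize_fi(profile: FIProfile) -> FIProfile:
    """Normalized square-root FI: sqrt(J) / integral sqrt(J) d(theta)."""
    return profile.normalized()


def behavioral_fi(
    trials: pd.DataFrame,
    window_deg: float = 18.0,
    step_deg: float = 0.5,
    smooth_sd_deg: float | None = 2.0,
    detrend: bool = True,
) -> FIProfile:
    """Trials -> normalized behavioral FI profile (single pass, no SEM).

    Grid points whose window SD is exactly zero (possible for tiny or
    heavily resampled trial sets) are masked as missing rather than
    propagated as infinite FI.
    """
    prof = sliding_bias_sd(trials, window_deg, step_deg, detrend)
    prof.sd[prof.sd == 0] = np.nan
    return normalize_fi(crlb_fi(prof, smooth_sd_deg))


def bootstrap_fi(
    trials: pd.DataFrame,
    n_boot: int = 500,
    seed: int = 0,
    window_deg: float = 18.0,
    step_deg: float = 0.5,
    smooth_sd_deg: float | None = 2.0,
    detrend: bool = True,
) -> FIProfile:
    """Behavioral FI with bootstrap SEM.

    Trials are resampled with replacement ``n_boot`` times; the SEM at each
    grid point is the standard deviation of the normalized sqrt-FI across
    resamples.
    """
    if n_boot < 2:
        raise ValueError("need at least two bootstrap resamples")
    rng = np.random.default_rng(seed)
    point = behavioral_fi(trials, window_deg, step_deg, smooth_sd_deg, detrend)
    reps = np.empty((n_boot, point.grid.size))
    n = len(trials)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        reps[b] = behavioral_fi(
            trials.iloc[idx], window_deg, step_deg, smooth_sd_deg, detrend
        ).fi_sqrt_norm
    sem = np.nanstd(reps, axis=0, ddof=1)
    return FIProfile(
        grid=point.grid,
        fi=point.fi,
        fi_sqrt_norm=point.fi_sqrt_norm,
        sem=sem,
        total_resource=point.total_resource,
        meta=dict(point.meta, n_boot=n_boot, seed=seed),
    )


def fold_symmetric(profile, center: float = 0.0):
    """Fold a profile about a symmetry axis, averaging +delta with -delta.

    For a ``BiasProfile`` the bias is sign-flipped on the negative branch
    before averaging (bias is antisymmetric under reflection) while the SD
    averages directly; for an ``FIProfile`` both fi and fi_sqrt_norm
    average directly. Returns a profile of the same type on the grid
    center + delta, delta in [0, 90].
    """
    grid = profile.grid
    step = float(grid[1] - grid[0])
    n = grid.size
    deltas = np.arange(0.0, 90.0 + step / 2, step)

    def index_of(angle):
        return int(round(np.mod(angle - grid[0], 180.0) / step)) % n

    def fold(values, flip=False):
        out = np.empty(deltas.size)
        for i, d in enumerate(deltas):
            plus = values[index_of(center + d)]
            minus = values[index_of(center - d)]
            if flip:
                minus = -minus
            out[i] = np.nanmean([plus, minus])
        return out

    new_grid = center + deltas
    if isinstance(profile, BiasProfile):
        return BiasProfile(
            grid=new_grid,
            bias=fold(profile.bias, flip=True),
            sd=fold(profile.sd),
            window_deg=profile.window_deg,
            step_deg=step,
        )
    if isinstance(profile, FIProfile):
        return FIProfile(
            grid=new_grid,
            fi=fold(profile.fi),
            fi_sqrt_norm=(
                None
                if profile.fi_sqrt_norm is None
                else fold(profile.fi_sqrt_norm)
            ),
            sem=None if profile.sem is None else fold(profile.sem),
            total_resource=profile.total_resource,
            meta=dict(profile.meta, folded_about=center),
        )
    raise TypeError("fold_symmetric expects a BiasProfile or FIProfile")
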