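"""Circular statistics for axial (180-degree periodic) orientation data.

Orientations live in [0, 180). All axial quantities are handled by the
standard doubled-angle device: an orientation theta maps to the angle
2*theta on the full circle, circular moments are computed there, and
results are mapped back by halving.
"""

from __future__ import annotations

import numpy as np

PERIOD = 180.0


def wrap_orientation(theta):
    """Wrap orientation(s) into [0, 180)."""
    return np.mod(theta, PERIOD)


def signed_orientation_diff(a, b):
    """Minimal signed difference a - b on the orientation circle, in (-90, 90].

    This is the signed circular estimation error when ``a`` is an estimate
    and ``b`` the true orientation.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return 90.0 - np.mod(90.0 - d, PERIOD)


def circ_mean_orientation(theta, weights=None, axis=None):
    """Circular mean of orientations via the doubled angle, in [0, 180)."""
    ang = np.deg2rad(2.0 * np.asarray(theta, dtype=float))
    if weights is None:
        c = np.mean(np.cos(ang), axis=axis)
        s = np.mean(np.sin(ang), axis=axis)
    else:
        w = np.asarray(weights, dtype=float)
        c = np.sum(w * np.cos(ang), axis=axis) / np.sum(w, axis=axis)
        s = np.sum(w * np.sin(ang), axis=axis) / np.sum(w, axis=axis)
    return wrap_orientation(np.rad2deg(np.arctan2(s, c)) / 2.0)


def circ_resultant_orientation(theta, axis=None):
    """Mean resultant length R of doubled-angle orientations (0 <= R <= 1)."""
    ang = np.deg2rad(2.0 * np.asarray(theta, dtype=float))
    c = np.mean(np.cos(ang), axis=axis)
    s = np.mean(np.sin(ang), axis=axis)
    return np.hypot(c, s)


def circ_sd_orientation(theta, axis=None):
    """Circular standard deviation of orientations, in degrees of orientation.

    Computed as sqrt(-2 ln R) on the doubled-angle circle and halved to map
    back to orientation units.
    """
    r = circ_resultant_orientation(theta, axis=axis)
    r = np.clip(r, 1e-300, 1.0)
    return np.rad2deg(np.sqrt(-2.0 * np.log(r))) / 2.0


def circ_corr_orientation(theta, estimates):
    """Circular correlation coefficient for two axial samples.

    Orientation (period-180) data are doubled to the full circle and the
    Jammalamadaka-SenGupta circular correlation is computed::

        r = sum sin(a - abar) sin(b - bbar)
            / sqrt(sum sin^2(a - abar) * sum sin^2(b - bbar))

    Raises ``ValueError`` when either sample has zero angular variance
    (the coefficient is undefined).
    """
    theta = np.asarray(theta, dtype=float)
    estimates = np.asarray(estimates, dtype=float)
    if theta.shape != estimates.shape or theta.size < 3:
        raise ValueError("need two equal-length samples of at least 3 angles")
    a = np.deg2rad(2.0 * theta)
    b = np.deg2rad(2.0 * estimates)
    abar = np.arctan2(np.sin(a).sum(), np.cos(a).sum())
    bbar = np.arctan2(np.sin(b).sum(), np.cos(b).sum())
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0.0:
        raise ValueError("circular correlation undefined: zero angular variance")
    return float((sa * sb).sum() / denom)


def periodic_integral(values, step):
    """Integral of a 180-periodic function sampled uniformly on [0, 180).

    For uniform samples of a periodic function, the trapezoid rule with
    wrap-around reduces to the rectangle sum, which is what is computed.
    """
    return float(np.nansum(values) * step)
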