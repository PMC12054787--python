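"""Containers for orientation-resolved analysis products.

``BiasProfile`` holds sliding-window estimation bias/SD curves;
``FIProfile`` holds Fisher information (raw and normalized square root)
on an orientation grid. Both are plain dataclasses with CSV round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circstats import periodic_integral


@dataclass
class BiasProfile:
    """Sliding-window estimation bias and SD as functions of orientation.

    ``bias`` is b(theta) in degrees, ``sd`` is sigma(theta) in degrees and
    ``mean_estimate`` is g(theta) = theta + b(theta). Grid points whose
    window held fewer than two trials are NaN.
    """

    grid: np.ndarray
    bias: np.ndarray
    sd: np.ndarray
    window_deg: float
    step_deg: float
    n_trials: np.ndarray | None = None

    @property
    def mean_estimate(self) -> np.ndarray:
        return self.grid + self.bias

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"theta_deg": self.grid, "bias_deg": self.bias, "sd_deg": self.sd}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, window_deg=np.nan, step_deg=np.nan) -> "BiasProfile":
        df = pd.read_csv(path)
        grid = df["theta_deg"].to_numpy(float)
        step = float(grid[1] - grid[0]) if np.isnan(step_deg) else step_deg
        return cls(
            grid=grid,
            bias=df["bias_deg"].to_numpy(float),
            sd=df["sd_deg"].to_numpy(float),
            window_deg=window_deg,
            step_deg=step,
        )


@dataclass
class FIProfile:
    """Fisher information on an orientation grid.

    ``fi`` is J(theta) in deg^-2. ``fi_sqrt_norm`` is the normalized square
    root, sqrt(J)/integral(sqrt(J)), a density over [0, 180) that under
    efficient coding is read as the orientation prior. ``total_resource``
    stores the normalizer integral(sqrt(J)) d(theta).
    """

    grid: np.ndarray
    fi: np.ndarray
    fi_sqrt_norm: np.ndarray | None = None
    sem: np.ndarray | None = None
    total_resource: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def normalized(self) -> "FIProfile":
        """Return a copy with fi_sqrt_norm and total_resource filled in."""
        fi = np.asarray(self.fi, dtype=float)
        valid = ~np.isnan(fi)
        if not valid.any() or np.nanmax(fi) <= 0:
            raise ValueError("cannot normalize an all-zero FI profile")
        if np.nanmin(fi) < 0:
            raise ValueError("FI must be nonnegative")
        root = np.sqrt(fi)
        total = periodic_integral(np.where(valid, root, 0.0), self.step)
        # missing grid points carry no mass; the density is defined on the rest
        norm = root / total
        return FIProfile(
            grid=self.grid.copy(),
            fi=fi.copy(),
            fi_sqrt_norm=norm,
            sem=None if self.sem is None else self.sem.copy(),
            total_resource=total,
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"theta_deg": self.grid, "fi": self.fi}
        if self.fi_sqrt_norm is not None:
            data["fi_sqrt_norm"] = self.fi_sqrt_norm
        if self.sem is not None:
            data["sem"] = self.sem
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FIProfile":
        df = pd.read_csv(path)
        return cls(
            grid=df["theta_deg"].to_numpy(float),
            fi=df["fi"].to_numpy(float),
            fi_sqrt_norm=(
                df["fi_sqrt_norm"].to_numpy(float) if "fi_sqrt_norm" in df else None
            ),
            sem=df["sem"].to_numpy(float) if "sem" in df else None,
        )


@dataclass
class PriorProfile:
    """A 180-periodic orientation prior density on a uniform grid.

    ``density`` is probability per degree and integrates to 1 over one
    period.
    """

    grid: np.ndarray
    density: np.ndarray

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def normalize(self) -> "PriorProfile":
        z = periodic_integral(self.density, self.step)
        return PriorProfile(self.grid.copy(), self.density / z)

    def density_at(self, theta) -> np.ndarray:
        """Periodic linear interpolation of the density."""
        theta = np.mod(np.asarray(theta, dtype=float), 180.0)
        ext_grid = np.concatenate([self.grid, [self.grid[0] + 180.0]])
        ext_den = np.concatenate([self.density, [self.density[0]]])
        return np.interp(theta, ext_grid, ext_den)

    def to_fi_profile(self, total_resource: float = 1.0) -> FIProfile:
        """FI profile whose normalized sqrt equals this prior (efficient code).

        ``total_resource`` sets integral(sqrt(J)) d(theta), i.e. the overall
        amount of coding resource; J = (total_resource * density)^2.
        """
        root = total_resource * self.density
        return FIProfile(
            grid=self.grid.copy(),
            fi=root**2,
            fi_sqrt_norm=self.density.copy(),
            total_resource=total_resource,
        )
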