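"""Complex steerable pyramid, frequency-domain construction.

The pyramid splits an image into orientation x spatial-frequency bands
with polar-separable filters in the Fourier plane: log-raised-cosine
radial bands (one octave apart, transitions telescoping so the squared
masks tile the plane exactly) and cos^(K-1) angular lobes restricted to a
half-plane. The half-plane restriction makes each band an analytic
(complex) signal, so the squared magnitude of a band coefficient is a
phase-insensitive local energy — the quadrature-pair energy a complex
steerable pyramid is used for.

Bands are kept at the full image resolution (no decimation); this changes
nothing about band content, only its sampling.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as _fft

__all__ = ["SteerablePyramid"]


def _lowpass(r, cutoff):
    """Log-raised-cosine lowpass: 1 below cutoff/2, 0 above cutoff."""
    out = np.zeros_like(r)
    out[r <= cutoff / 2.0] = 1.0
    trans = (r > cutoff / 2.0) & (r < cutoff)
    out[trans] = np.cos(
        (np.pi / 2.0) * (np.log2(r[trans] / cutoff) + 1.0)
    )
    return out


class SteerablePyramid:
    """Precomputed frequency-domain masks for a fixed image size.

    Parameters
    ----------
    image_size : side length of the (square) input images.
    n_orientations : number of angular channels (default 6).
    n_scales : number of radial bands (default 6), finest first.
    """

    def __init__(self, image_size: int, n_orientations: int = 6, n_scales: int = 6):
        if image_size < 2 ** (n_scales + 1):
            raise ValueError(
                f"image of size {image_size} is too small for {n_scales} scales"
            )
        self.image_size = image_size
        self.n_orientations = n_orientations
        self.n_scales = n_scales

        fx = np.fft.fftfreq(image_size) * 2.0 * np.pi
        gx = fx[None, :]
        gy = fx[:, None]
        r = np.hypot(gx, gy)
        phi = np.arctan2(gy, gx)

        # angular lobes: cos^(K-1) on a half-plane -> analytic bands
        k = n_orientations
        lobes = []
        for c in range(k):
            d = np.mod(phi - c * np.pi / k + np.pi, 2.0 * np.pi) - np.pi
            lobe = np.where(np.abs(d) < np.pi / 2.0, np.cos(d) ** (k - 1), 0.0)
            lobes.append(lobe)

        # radial bands: cutoff pi/2^s, transitions telescope exactly
        radial = []
        for s in range(n_scales):
            lo_prev = _lowpass(r, np.pi / 2.0**s)
            hi = np.sqrt(np.maximum(0.0, 1.0 - _lowpass(r, np.pi / 2.0 ** (s + 1)) ** 2))
            radial.append(lo_prev * hi)

        masks = np.empty(
            (n_scales, n_orientations, image_size, image_size), dtype=np.float32
        )
        for s in range(n_scales):
            for c in range(k):
                masks[s, c] = (radial[s] * lobes[c]).astype(np.float32)
        self.masks = masks
        self.residual_lowpass = _lowpass(r, np.pi / 2.0**n_scales).astype(np.float32)

    def band_coefficients(self, image) -> np.ndarray:
        """Complex band coefficients, shape (n_scales, n_orientations, n, n)."""
        image = np.asarray(image, dtype=np.float32)
        if image.shape != (self.image_size, self.image_size):
            raise ValueError("image shape does not match the pyramid")
        spectrum = _fft.fft2(image).astype(np.complex64)
        return _fft.ifft2(spectrum[None, None] * self.masks, axes=(-2, -1))

    def band_energies(self, image) -> np.ndarray:
        """Per-band energy maps real^2 + imag^2, shape (S, K, n, n)."""
        coeffs = self.band_coefficients(image)
        return (coeffs.real**2 + coeffs.imag**2).astype(np.float32)

    def scale_energy_maps(self, image) -> np.ndarray:
        """Energy summed over orientation channels per scale, shape (S, n, n).

        Each pixel of a map is an orientation-nonselective simulated voxel.
        """
        return self.band_energies(image).sum(axis=1)
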