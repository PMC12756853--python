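"""Conditioning of spectra before cross-correlation.

Three steps, in a fixed order:

1. **High-pass filter** — the raster is Fourier transformed, multiplied by
   an inverse Gaussian ``H(f) = 1 - exp(-|f|^2 / (2 sigma^2))`` and
   transformed back.  ``|f|`` is the isotropic normalized spatial
   frequency in cycles/pixel (Nyquist = 0.5) and ``sigma = FWHM/2.3548``;
   the default FWHM of 0.2355 gives ``sigma = 0.1``.  This suppresses
   broad, low-resolution structure (baseline rolls, very bright ridges)
   while leaving peak-scale features essentially untouched; the DC term is
   removed exactly.
2. **Zero-float** — subtract the mean.
3. **Normalize** — divide by the standard deviation (population, divisor
   ``N``) so the variance is 1.

The combination makes the subsequent normalized cross-correlation
insensitive to overall intensity scaling and baseline offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import SpectrumGrid

__all__ = ["FilterSpec", "highpass_filter", "zero_float_normalize", "preprocess"]

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))
DEFAULT_FWHM = 0.2355


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum is flat (zero variance) and cannot be
    standardized."""


@dataclass(frozen=True)
class FilterSpec:
    """High-pass filter settings.

    fwhm : full width at half maximum of the Gaussian that is subtracted
        from 1, in normalized spatial-frequency units (cycles/pixel,
        Nyquist = 0.5).  The default 0.2355 corresponds to sigma = 0.1.
    enabled : switch the filter off entirely (the zero-float/normalize
        steps still run).
    """

    fwhm: float = DEFAULT_FWHM
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (self.fwhm > 0):
            raise ValueError(f"filter FWHM must be positive, got {self.fwhm}")

    @property
    def sigma(self) -> float:
        return self.fwhm / FWHM_PER_SIGMA


def _freq_sq(shape: tuple[int, ...]) -> np.ndarray:
    """|f|^2 on the unshifted FFT grid, f in cycles/pixel per axis."""
    grids = np.meshgrid(
        *[np.fft.fftfreq(n) for n in shape], indexing="ij", sparse=True
    )
    out = np.zeros(shape)
    for g in grids:
        out = out + g**2
    return out


def highpass_filter(grid: SpectrumGrid, spec: FilterSpec = FilterSpec()) -> SpectrumGrid:
    """Apply the inverse-Gaussian high-pass in Fourier space.

    The output is real; its spatial mean (DC component) is exactly zero
    because ``H(0) = 0``.
    """
    if not spec.enabled:
        return grid.copy()
    f2 = _freq_sq(grid.shape)
    H = 1.0 - np.exp(-f2 / (2.0 * spec.sigma**2))
    out = np.fft.ifftn(np.fft.fftn(grid.data) * H).real
    return SpectrumGrid(out, list(grid.axes))


def zero_float_normalize(grid: SpectrumGrid) -> SpectrumGrid:
    """Subtract the mean and scale to unit (population) variance."""
    mu = grid.data.mean()
    sd = grid.data.std()  # divisor N
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSpectrumError(
            "flat spectrum (zero variance) cannot be normalized"
        )
    return SpectrumGrid((grid.data - mu) / sd, list(grid.axes))


def preprocess(grid: SpectrumGrid, spec: FilterSpec = FilterSpec()) -> SpectrumGrid:
    """Full conditioning chain: filter, zero-float, normalize."""
    return zero_float_normalize(highpass_filter(grid, spec))
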