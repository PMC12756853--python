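"""Core data model: per-axis metadata and N-dimensional intensity rasters.

A processed frequency-domain NMR spectrum is represented as a real-valued
raster (:class:`SpectrumGrid`) plus one :class:`AxisHeader` per dimension.
The internal axis convention is:

* ``axes[-1]`` is the direct (acquisition) dimension;
* along every axis the array index increases toward **higher** ppm, so
  ``origin_ppm`` is the chemical shift of the minimum-ppm edge;
* the chemical shift is affine in the (1-based) pixel index with slope
  ``ss`` (ppm/pixel) and the grid center sits at index ``(n + 1) / 2``,
  i.e. ``center_ppm = origin_ppm + ((n + 1) / 2) * ss``.

Only relative offsets matter for alignment, so the single normative
statement is the center identity above; everything downstream derives
pixel/ppm conversions from it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = ["AxisHeader", "SpectrumGrid"]


@dataclass(frozen=True)
class AxisHeader:
    """Metadata for one spectral dimension.

    Parameters
    ----------
    n : int
        Number of points (pixels) along the axis, at least 2.
    sw : float
        Spectral width in Hz (> 0).
    obs : float
        Observe/transmitter frequency in MHz (> 0); ``sw / obs`` is the
        axis span in ppm.
    origin_ppm : float
        Chemical shift of the minimum-ppm edge of the axis.
    label : str
        Optional axis label (nucleus name); cosmetic only.
    """

    n: int
    sw: float
    obs: float
    origin_ppm: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"axis needs at least 2 points, got n={self.n}")
        if not (self.sw > 0):
            raise ValueError(f"spectral width must be positive, got sw={self.sw}")
        if not (self.obs > 0):
            raise ValueError(f"observe frequency must be positive, got obs={self.obs}")
        if not np.isfinite(self.origin_ppm):
            raise ValueError("origin_ppm must be finite")

    @property
    def ss(self) -> float:
        """Spectral sampling in ppm per pixel: ``(sw / obs) / n``."""
        return (self.sw / self.obs) / self.n

    @property
    def span_ppm(self) -> float:
        """Physical extent of the axis in ppm: ``sw / obs``."""
        return self.sw / self.obs

    @property
    def center_ppm(self) -> float:
        """Chemical shift at the grid center, ``origin_ppm + ((n+1)/2) * ss``."""
        return self.origin_ppm + (self.n + 1) / 2.0 * self.ss

    def with_(self, **kwargs) -> "AxisHeader":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def ppm_scale(self) -> np.ndarray:
        """ppm coordinate of every pixel (0-based index ``i`` maps to
        1-based ``i + 1``), increasing with index."""
        idx = np.arange(1, self.n + 1, dtype=float)
        return self.center_ppm + (idx - (self.n + 1) / 2.0) * self.ss


@dataclass
class SpectrumGrid:
    """A real-valued intensity raster with per-axis headers.

    ``data.ndim`` must equal ``len(axes)`` and each extent must match the
    corresponding header's ``n``.  Intensities must be finite.
    """

    data: np.ndarray
    axes: list[AxisHeader]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.axes = list(self.axes)
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"data has {self.data.ndim} dimensions but {len(self.axes)} "
                "axis headers were given"
            )
        for d, (extent, ax) in enumerate(zip(self.data.shape, self.axes)):
            if extent != ax.n:
                raise ValueError(
                    f"axis {d}: data extent {extent} != header n={ax.n}"
                )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("spectrum contains non-finite intensities")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def copy(self) -> "SpectrumGrid":
        return SpectrumGrid(self.data.copy(), list(self.axes))

    def ss(self) -> tuple[float, ...]:
        """Per-axis spectral sampling (ppm/pixel)."""
        return tuple(ax.ss for ax in self.axes)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, SpectrumGrid):
            return NotImplemented
        return self.axes == other.axes and np.array_equal(self.data, other.data)


def validate_same_shape(a: SpectrumGrid, b: SpectrumGrid) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
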