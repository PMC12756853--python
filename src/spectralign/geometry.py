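"""Grid geometry: ppm-per-pixel sampling, center-referenced origin offsets,
Fourier-interpolation resampling, and real-space resizing.

Two spectra can only be cross-correlated once they share the same spectral
sampling (ppm/pixel) and the same physical extent.  The spectral sampling
of one axis is ``SS = (sw/obs)/n``; spectrum 2 is Fourier-interpolated to
spectrum 1's sampling by resizing it to ``n_new = n_s2 * SS_s2 / SS_s1``
pixels over the same ppm span, then symmetrically cropped or zero-padded
in real space until the spans match.  Because the minimum-ppm origin moves
under both operations, origin bookkeeping is done at the grid *center*,
which both operations preserve: the residual referencing offset between
two prepared spectra is simply the difference of their center chemical
shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import AxisHeader, SpectrumGrid

__all__ = [
    "SamplingInfo",
    "spectral_sampling",
    "origin_offset_center",
    "resample_target_size",
    "fourier_resize",
    "resize_to_match",
]


@dataclass(frozen=True)
class SamplingInfo:
    """Spectral sampling (ppm/pixel) and center chemical shift per axis."""

    ss: tuple[float, ...]
    center_ppm: tuple[float, ...]

    @classmethod
    def of(cls, grid: SpectrumGrid) -> "SamplingInfo":
        return cls(
            ss=tuple(ax.ss for ax in grid.axes),
            center_ppm=tuple(ax.center_ppm for ax in grid.axes),
        )


def spectral_sampling(axis: AxisHeader) -> float:
    """ppm per pixel for one axis: ``(sw/obs)/n``."""
    return (axis.sw / axis.obs) / axis.n


def origin_offset_center(
    a1: AxisHeader, a2: AxisHeader, shared_ss: float, *, rtol: float = 1e-6
) -> float:
    """Center-referenced origin offset between two axes that already share
    point count and sampling.

    Equals ``(O1 + ((n+1)/2)*SS) - (O2 + ((n+1)/2)*SS) = O1 - O2`` for a
    shared ``n`` and ``SS``.  Calling it on axes with mismatched ``n`` or
    sampling is a precondition error: resample and resize first.
    """
    if a1.n != a2.n:
        raise ValueError(f"axes must share point count: {a1.n} != {a2.n}")
    for ax in (a1, a2):
        if not math.isclose(ax.ss, shared_ss, rel_tol=rtol):
            raise ValueError(
                f"axis sampling {ax.ss!r} differs from shared value {shared_ss!r}"
            )
    return (a1.origin_ppm + (a1.n + 1) / 2.0 * shared_ss) - (
        a2.origin_ppm + (a2.n + 1) / 2.0 * shared_ss
    )


def resample_target_size(n_s2: int, ss_s1: float, ss_s2: float) -> int:
    """Pixel count that resamples an ``n_s2``-point axis of sampling
    ``ss_s2`` onto sampling ``ss_s1``: ``n_s2 / (ss_s1 / ss_s2)``, rounded
    half-up so the physical span is preserved to within half a pixel.
    """
    if n_s2 <= 0 or ss_s1 <= 0 or ss_s2 <= 0:
        raise ValueError("n_s2, ss_s1, ss_s2 must all be positive")
    n_new = math.floor(n_s2 * ss_s2 / ss_s1 + 0.5)
    if n_new < 2:
        raise ValueError(
            f"resampling {n_s2} points from ss={ss_s2} to ss={ss_s1} leaves a "
            f"degenerate {n_new}-point grid"
        )
    return n_new


def _fourier_resize_axis(a: np.ndarray, m: int, axis: int) -> np.ndarray:
    """Band-limited resize of one axis from n to m points via centered
    Fourier crop/pad.  Nyquist bins are split (pad) or folded (crop) so the
    operation keeps real data real and is self-inverse for band-limited
    input.  Amplitudes (and hence the mean) are preserved."""
    n = a.shape[axis]
    if m == n:
        return a.copy()
    F = np.fft.fftshift(np.fft.fft(a, axis=axis), axes=axis)
    sl = [slice(None)] * a.ndim

    def take(idx):
        sl2 = list(sl)
        sl2[axis] = idx
        return tuple(sl2)

    if m < n:
        start = n // 2 - m // 2
        G = F[take(slice(start, start + m))].copy()
        if m % 2 == 0:
            # fold the +Nyquist source bin into the output's -Nyquist bin
            hi = n // 2 + m // 2
            if hi < n:
                G[take(0)] += F[take(hi)]
    else:
        shape = list(a.shape)
        shape[axis] = m
        G = np.zeros(shape, dtype=complex)
        start = m // 2 - n // 2
        G[take(slice(start, start + n))] = F
        if n % 2 == 0:
            # split the source Nyquist bin between the two new ± bins
            lo = start  # frequency -n/2
            hi = m // 2 + n // 2  # frequency +n/2
            half = 0.5 * G[take(lo)]
            G[take(lo)] = half
            G[take(hi)] = half.copy()
    G *= m / n
    out = np.fft.ifft(np.fft.ifftshift(G, axes=axis), axis=axis)
    return out.real


def fourier_resize(grid: SpectrumGrid, new_dims: tuple[int, ...]) -> SpectrumGrid:
    """Resample *grid* to ``new_dims`` points per axis by Fourier
    interpolation over the unchanged physical span.

    The mean intensity is preserved, the center chemical shift of every
    axis is unchanged, and the sampling becomes ``span / n_new``.
    """
    if len(new_dims) != grid.ndim:
        raise ValueError(f"expected {grid.ndim} sizes, got {len(new_dims)}")
    if any(m < 2 for m in new_dims):
        raise ValueError(f"all new dimensions must be >= 2, got {new_dims}")
    data = grid.data
    for axis, m in enumerate(new_dims):
        data = _fourier_resize_axis(data, int(m), axis)
    axes = []
    for ax, m in zip(grid.axes, new_dims):
        ss_new = ax.span_ppm / m
        # keep sw/obs (hence the span) fixed; re-derive the origin so the
        # center chemical shift is untouched
        origin = ax.center_ppm - (m + 1) / 2.0 * ss_new
        axes.append(ax.with_(n=int(m), origin_ppm=origin))
    return SpectrumGrid(data, axes)


def resize_to_match(grid: SpectrumGrid, target_span_ppm: tuple[float, ...]) -> SpectrumGrid:
    """Symmetric real-space crop or zero-pad so each axis spans
    ``target_span_ppm`` at its current sampling, keeping the center
    chemical shift fixed to within half a pixel.
    """
    if len(target_span_ppm) != grid.ndim:
        raise ValueError(
            f"expected {grid.ndim} spans, got {len(target_span_ppm)}"
        )
    data = grid.data
    axes: list[AxisHeader] = []
    for axis, (ax, span) in enumerate(zip(grid.axes, target_span_ppm)):
        ss = ax.ss
        m = math.floor(span / ss + 0.5)
        if m < 2:
            raise ValueError(
                f"target span {span} ppm is under 2 pixels at ss={ss}"
            )
        n = ax.n
        if m == n:
            axes.append(ax)
            continue
        if m > n:
            left = (m - n) // 2
            pads = [(0, 0)] * data.ndim
            pads[axis] = (left, m - n - left)
            data = np.pad(data, pads)
            origin = ax.origin_ppm - left * ss
        else:
            left = (n - m) // 2
            sl = [slice(None)] * data.ndim
            sl[axis] = slice(left, left + m)
            data = data[tuple(sl)]
            origin = ax.origin_ppm + left * ss
        # hold ss constant: sw scales with the new point count
        axes.append(ax.with_(n=m, sw=m * ss * ax.obs, origin_ppm=origin))
    return SpectrumGrid(np.ascontiguousarray(data), axes)
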