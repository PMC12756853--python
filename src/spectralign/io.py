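"""Reading and writing spectra: NMRPipe single-file binaries and a plain
text+header dialect.

NMRPipe format
--------------
A single-file NMRPipe spectrum is a 512-word float32 header followed by the
float32 raster.  Only processed, real-valued frequency-domain data are
supported (``ft2``/``ft3``): each used dimension must have its FT flag set
and the quadrature flag marking real data; interleaved complex planes are
rejected.  NMRPipe's per-axis ORIG field holds the frequency (Hz) of the
minimum-ppm edge; it is converted to ppm at read time as
``origin_ppm = ORIG / OBS`` so that all downstream arithmetic is in ppm.

NMRPipe rasters store the first point of each axis at the *maximum* ppm
edge; the internal convention is the opposite (index increases with ppm),
so every spectral axis is reversed on read and on write.

Text dialect
------------
The header file is UTF-8 ``key=value`` lines with keys ``ndim`` and, for
each 1-based axis ``i``, ``n_i``, ``sw_hz_i``, ``obs_mhz_i``,
``origin_ppm_i``.  The data file holds exactly ``prod(n_i)``
whitespace-separated finite decimal values in row-major order with the
direct dimension varying fastest.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .grid import AxisHeader, SpectrumGrid

__all__ = [
    "read_nmrpipe",
    "write_nmrpipe",
    "read_text_dialect",
    "write_text_dialect",
    "UnsupportedFormatError",
]

HEADER_WORDS = 512

# FDATA header word indices (fdatap.h layout).
FDMAGIC = 0
FDFLTFORMAT = 1
FDFLTORDER = 2
FDDIMCOUNT = 9
FDF3OBS = 10
FDF3SW = 11
FDF3ORIG = 12
FDF3FTFLAG = 13
FDF3SIZE = 15
FDDIMORDER = (24, 25, 26, 27)
FDF3QUADFLAG = 51
FDF1QUADFLAG = 55
FDF2QUADFLAG = 56
FDPIPEFLAG = 57
FDREALSIZE = 97
FDSIZE = 99
FDF2SW = 100
FDF2ORIG = 101
FDQUADFLAG = 106
FDF2OBS = 119
FDF1OBS = 218
FDSPECNUM = 219
FDF2FTFLAG = 220
FDTRANSPOSED = 221
FDF1FTFLAG = 222
FDF1SW = 229
FDF1ORIG = 249

FLTORDER_VALUE = 2.345  # byte-order canary written by NMRPipe
# bit pattern 0xEEEEEEEE, NMRPipe's float-format magic
FLTFORMAT_VALUE = np.frombuffer(np.uint32(0xEEEEEEEE).tobytes(), dtype=np.float32)[0]


class UnsupportedFormatError(ValueError):
    """Raised for files that are recognizably NMRPipe but not a supported
    real-valued frequency-domain layout."""


def _axis_fields(dim: int) -> tuple[int, int, int, int, int]:
    """(sw, obs, orig, ftflag, quadflag) header indices for NMRPipe
    dimension F``dim`` (1-based NMRPipe numbering: F2 = direct)."""
    table = {
        2: (FDF2SW, FDF2OBS, FDF2ORIG, FDF2FTFLAG, FDF2QUADFLAG),
        1: (FDF1SW, FDF1OBS, FDF1ORIG, FDF1FTFLAG, FDF1QUADFLAG),
        3: (FDF3SW, FDF3OBS, FDF3ORIG, FDF3FTFLAG, FDF3QUADFLAG),
    }
    return table[dim]


def read_nmrpipe(path: str | os.PathLike) -> SpectrumGrid:
    """Read a single-file NMRPipe 2D (ft2) or 3D (ft3) spectrum.

    Returns a :class:`SpectrumGrid` with the direct dimension last and the
    index increasing toward higher ppm along every axis.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    UnsupportedFormatError
        For time-domain data, complex layouts, transposed streams, or a
        header magic mismatch.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < HEADER_WORDS * 4:
        raise UnsupportedFormatError(f"{path}: file shorter than an NMRPipe header")
    hdr = np.frombuffer(raw[: HEADER_WORDS * 4], dtype=np.float32).copy()
    swapped = False
    if abs(float(hdr[FDFLTORDER]) - FLTORDER_VALUE) > 1e-4:
        hdr = hdr.byteswap()
        swapped = True
        if abs(float(hdr[FDFLTORDER]) - FLTORDER_VALUE) > 1e-4:
            raise UnsupportedFormatError(
                f"{path}: header magic mismatch (not an NMRPipe file?)"
            )

    ndim = int(round(float(hdr[FDDIMCOUNT])))
    if ndim not in (2, 3):
        raise UnsupportedFormatError(f"{path}: FDDIMCOUNT={ndim}, expected 2 or 3")
    if int(round(float(hdr[FDTRANSPOSED]))) != 0:
        raise UnsupportedFormatError(f"{path}: transposed data streams not supported")
    if int(round(float(hdr[FDQUADFLAG]))) != 1:
        raise UnsupportedFormatError(
            f"{path}: complex (quadrature) data layout not supported"
        )

    nx = int(round(float(hdr[FDSIZE])))
    ny = int(round(float(hdr[FDSPECNUM])))
    shape = [ny, nx]
    dims = [1, 2]  # NMRPipe F-dim for each data axis, slow -> fast
    if ndim == 3:
        nz = int(round(float(hdr[FDF3SIZE])))
        shape = [nz, ny, nx]
        dims = [3, 1, 2]

    axes = []
    for fdim in dims:
        i_sw, i_obs, i_orig, i_ft, i_quad = _axis_fields(fdim)
        if int(round(float(hdr[i_ft]))) != 1:
            raise UnsupportedFormatError(
                f"{path}: dimension F{fdim} is time-domain (FT flag unset)"
            )
        if int(round(float(hdr[i_quad]))) != 1:
            raise UnsupportedFormatError(
                f"{path}: dimension F{fdim} holds complex data"
            )
        obs = float(hdr[i_obs])
        sw = float(hdr[i_sw])
        orig_hz = float(hdr[i_orig])
        n = shape[dims.index(fdim)]
        axes.append(AxisHeader(n=n, sw=sw, obs=obs, origin_ppm=orig_hz / obs))

    npts = int(np.prod(shape))
    data = np.frombuffer(raw[HEADER_WORDS * 4 :], dtype=np.float32)
    if swapped:
        data = data.byteswap()
    if data.size != npts:
        raise UnsupportedFormatError(
            f"{path}: data block holds {data.size} values, header implies {npts}"
        )
    arr = data.astype(np.float64).reshape(shape)
    # NMRPipe: first point = max ppm; internal: index increases with ppm.
    arr = arr[(np.s_[::-1],) * len(shape)]
    return SpectrumGrid(np.ascontiguousarray(arr), axes)


def write_nmrpipe(grid: SpectrumGrid, path: str | os.PathLike) -> None:
    """Write *grid* as a single-file real NMRPipe spectrum (ft2/ft3)."""
    if grid.ndim not in (2, 3):
        raise ValueError(f"only 2D/3D spectra supported, got {grid.ndim}D")
    if not np.all(np.isfinite(grid.data)):
        raise ValueError("refusing to write non-finite intensities")
    hdr = np.zeros(HEADER_WORDS, dtype=np.float32)
    hdr[FDMAGIC] = 0.0
    hdr[FDFLTFORMAT] = FLTFORMAT_VALUE
    hdr[FDFLTORDER] = FLTORDER_VALUE
    hdr[FDDIMCOUNT] = grid.ndim
    for slot, v in zip(FDDIMORDER, (2.0, 1.0, 3.0, 4.0)):
        hdr[slot] = v
    hdr[FDQUADFLAG] = 1.0
    hdr[FDTRANSPOSED] = 0.0
    hdr[FDPIPEFLAG] = 1.0 if grid.ndim == 3 else 0.0

    dims = [1, 2] if grid.ndim == 2 else [3, 1, 2]
    for fdim, ax in zip(dims, grid.axes):
        i_sw, i_obs, i_orig, i_ft, i_quad = _axis_fields(fdim)
        hdr[i_sw] = ax.sw
        hdr[i_obs] = ax.obs
        hdr[i_orig] = ax.origin_ppm * ax.obs  # back to Hz
        hdr[i_ft] = 1.0
        hdr[i_quad] = 1.0

    hdr[FDSIZE] = grid.shape[-1]
    hdr[FDREALSIZE] = grid.shape[-1]
    hdr[FDSPECNUM] = grid.shape[-2]
    if grid.ndim == 3:
        hdr[FDF3SIZE] = grid.shape[0]

    arr = grid.data[(np.s_[::-1],) * grid.ndim].astype(np.float32)
    with open(path, "wb") as fh:
        fh.write(hdr.tobytes())
        fh.write(np.ascontiguousarray(arr).tobytes())


def read_text_dialect(
    header_path: str | os.PathLike, data_path: str | os.PathLike
) -> SpectrumGrid:
    """Read the plain text+header dialect.

    Raises on missing/duplicate keys, on a count mismatch between the
    header's ``prod(n_i)`` and the number of data values, and on
    non-finite values.
    """
    kv: dict[str, str] = {}
    for lineno, line in enumerate(Path(header_path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{header_path}:{lineno}: expected key=value, got {line!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key in kv:
            raise ValueError(f"{header_path}: duplicate key {key!r}")
        kv[key] = val.strip()

    def need(key: str) -> str:
        if key not in kv:
            raise ValueError(f"{header_path}: missing key {key!r}")
        return kv[key]

    ndim = int(need("ndim"))
    axes = [
        AxisHeader(
            n=int(need(f"n_{i}")),
            sw=float(need(f"sw_hz_{i}")),
            obs=float(need(f"obs_mhz_{i}")),
            origin_ppm=float(need(f"origin_ppm_{i}")),
        )
        for i in range(1, ndim + 1)
    ]
    shape = tuple(ax.n for ax in axes)
    values = np.loadtxt(data_path, dtype=np.float64).ravel()
    if values.size != int(np.prod(shape)):
        raise ValueError(
            f"{data_path}: {values.size} values for header shape {shape} "
            f"({int(np.prod(shape))} expected)"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{data_path}: non-finite values in raster")
    return SpectrumGrid(values.reshape(shape), axes)


def write_text_dialect(
    grid: SpectrumGrid,
    header_path: str | os.PathLike,
    data_path: str | os.PathLike,
) -> None:
    """Write *grid* in the text dialect (row-major, direct dimension fastest)."""
    if not np.all(np.isfinite(grid.data)):
        raise ValueError("refusing to write non-finite intensities")
    lines = [f"ndim={grid.ndim}"]
    for i, ax in enumerate(grid.axes, 1):
        lines += [
            f"n_{i}={ax.n}",
            f"sw_hz_{i}={ax.sw!r}",
            f"obs_mhz_{i}={ax.obs!r}",
            f"origin_ppm_{i}={ax.origin_ppm!r}",
        ]
    Path(header_path).write_text("\n".join(lines) + "\n")
    np.savetxt(data_path, grid.data.reshape(-1, grid.shape[-1]), fmt="%.9e")


def read_spectrum(path: str | os.PathLike) -> SpectrumGrid:
    """Auto-detecting reader: ``.hdr``/``.txt`` pairs use the text dialect
    (given either member of the pair), anything else is read as NMRPipe."""
    p = Path(path)
    if p.suffix in {".hdr", ".txt"}:
        hdr = p.with_suffix(".hdr")
        dat = p.with_suffix(".txt")
        return read_text_dialect(hdr, dat)
    return read_nmrpipe(p)


def write_spectrum(grid: SpectrumGrid, path: str | os.PathLike) -> None:
    """Auto-detecting writer, mirror of :func:`read_spectrum`."""
    p = Path(path)
    if p.suffix in {".hdr", ".txt"}:
        write_text_dialect(grid, p.with_suffix(".hdr"), p.with_suffix(".txt"))
    else:
        write_nmrpipe(grid, p)
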