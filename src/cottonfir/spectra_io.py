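"""Reading, writing, normalizing and band-intensity extraction for mid-IR spectra.

A :class:`Spectrum` holds one absorbance trace on an ascending wavenumber grid
(cm^-1).  Instrument exports are typically descending; canonicalization reorders
them on construction so every downstream operation can assume ascending order.

Band intensities are multi-point averages centred on the grid point nearest to a
nominal wavenumber (default three points, i.e. the nearest point plus one
neighbour on each side).  No baseline correction or interpolation is applied:
the maturity/crystallinity ratios are affine-invariant, so the raw absorbance
trace on its native grid is all that is needed.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BandIntensities",
    "SpectrumParseError",
    "DegenerateSpectrumError",
    "MATURITY_BAND_CENTERS",
    "CRYSTALLINITY_BAND_CENTERS",
    "ALGORITHM_BAND_CENTERS",
    "read_spectrum",
    "write_spectrum",
    "normalize_region",
    "band_intensity",
    "extract_bands",
]

#: Band centres (cm^-1) feeding the maturity ratio R1 = (I956-I1500)/(I1032-I1500).
MATURITY_BAND_CENTERS = (956.0, 1032.0, 1500.0)
#: Band centres (cm^-1) feeding the crystallinity ratio R2 = (I708-I800)/(I730-I800).
CRYSTALLINITY_BAND_CENTERS = (708.0, 730.0, 800.0)
ALGORITHM_BAND_CENTERS = MATURITY_BAND_CENTERS + CRYSTALLINITY_BAND_CENTERS

#: Largest admissible grid step (cm^-1); FT-IR exports are 1-16 cm^-1.
MAX_GRID_STEP = 16.0


class SpectrumParseError(ValueError):
    """A spectral file violated its dialect or the grid invariants."""


class DegenerateSpectrumError(ValueError):
    """A spectrum that defeats an operation (empty region, zero denominator...)."""


@dataclass
class Spectrum:
    """One absorbance trace on an ascending wavenumber grid.

    Parameters
    ----------
    wavenumbers
        Grid in cm^-1.  Any order on input; stored ascending.
    absorbances
        Unitless absorbance values, one per grid point.
    sample_id, replicate_id
        Free-text provenance labels.
    """

    wavenumbers: np.ndarray
    absorbances: np.ndarray
    sample_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if w.ndim != 1 or a.ndim != 1:
            raise SpectrumParseError("wavenumbers and absorbances must be 1-D")
        if w.size != a.size:
            raise SpectrumParseError(
                f"length mismatch: {w.size} wavenumbers vs {a.size} absorbances"
            )
        if w.size < 2:
            raise SpectrumParseError("a spectrum needs at least 2 grid points")
        order = np.argsort(w, kind="stable")
        w = w[order]
        a = a[order]
        steps = np.diff(w)
        if np.any(steps <= 0):
            dup = w[:-1][steps <= 0][0]
            raise SpectrumParseError(f"duplicate wavenumber {dup:g} cm^-1 in grid")
        if np.any(steps > MAX_GRID_STEP):
            raise SpectrumParseError(
                f"grid step exceeds {MAX_GRID_STEP:g} cm^-1 (max {steps.max():g})"
            )
        if not np.all(np.isfinite(a)) or not np.all(np.isfinite(w)):
            raise SpectrumParseError("non-finite value in spectrum")
        self.wavenumbers = w
        self.absorbances = a

    def __len__(self) -> int:
        return self.wavenumbers.size

    def scaled(self, a: float, b: float = 0.0) -> "Spectrum":
        """Return the affine image a*I(nu) + b (same grid)."""
        return replace(self, absorbances=a * self.absorbances + b)


@dataclass(frozen=True)
class BandIntensities:
    """The six multi-point band averages consumed by the ratio algorithms."""

    i956: float
    i1032: float
    i1500: float
    i708: float
    i730: float
    i800: float
    window_points: int = 3

    def __post_init__(self) -> None:
        if self.window_points < 1 or self.window_points % 2 == 0:
            raise ValueError("window_points must be odd and >= 1")
        for name in ("i956", "i1032", "i1500", "i708", "i730", "i800"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite band intensity {name}")


# ---------------------------------------------------------------------------
# dialects

def _as_stream(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    return io.StringIO(str(source))


def _parse_two_column(stream: TextIO, sample_id: str, replicate_id: str) -> Spectrum:
    ws: list[float] = []
    ab: list[float] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise SpectrumParseError(
                f"line {lineno}: expected 'wavenumber absorbance', got {raw.strip()!r}"
            )
        try:
            ws.append(float(parts[0]))
            ab.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumParseError(f"line {lineno}: non-numeric field: {exc}") from exc
    if not ws:
        raise SpectrumParseError("no data records found")
    return Spectrum(np.array(ws), np.array(ab), sample_id=sample_id, replicate_id=replicate_id)


def _parse_csv_matrix(stream: TextIO) -> list[Spectrum]:
    try:
        df = pd.read_csv(stream, index_col=0)
    except Exception as exc:  # pandas raises several parse error types
        raise SpectrumParseError(f"unreadable csv_matrix: {exc}") from exc
    if df.shape[1] < 2:
        raise SpectrumParseError("csv_matrix needs >= 2 wavenumber columns")
    try:
        grid = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise SpectrumParseError(f"non-numeric wavenumber header: {exc}") from exc
    out = []
    for rid, row in df.iterrows():
        out.append(
            Spectrum(grid.copy(), row.to_numpy(dtype=float),
                     sample_id=str(rid), replicate_id=str(rid))
        )
    if not out:
        raise SpectrumParseError("csv_matrix has no data rows")
    return out


def _parse_jcampdx(stream: TextIO) -> Spectrum:
    """Minimal fixed-abscissa JCAMP-DX: ##XYDATA=(X++(Y..Y)) with uniform DELTAX."""
    header: dict[str, str] = {}
    ys: list[float] = []
    first_x: float | None = None
    in_data = False
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "XYDATA":
                if "(X++(Y..Y))" not in val.replace(" ", ""):
                    raise SpectrumParseError(
                        f"line {lineno}: unsupported XYDATA form {val!r}"
                    )
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            header[key] = val
            continue
        if in_data:
            parts = line.split()
            try:
                x = float(parts[0])
                row_y = [float(p) for p in parts[1:]]
            except ValueError as exc:
                raise SpectrumParseError(f"line {lineno}: non-numeric field") from exc
            if first_x is None:
                first_x = x
            ys.extend(row_y)
    if first_x is None or not ys:
        raise SpectrumParseError("no XYDATA block found")
    xfactor = float(header.get("XFACTOR", 1.0))
    yfactor = float(header.get("YFACTOR", 1.0))
    n = len(ys)
    if "DELTAX" in header:
        dx = float(header["DELTAX"])
    elif "LASTX" in header and "NPOINTS" in header:
        lastx = float(header["LASTX"]) / xfactor
        npoints = int(header["NPOINTS"])
        if npoints != n:
            raise SpectrumParseError(f"NPOINTS={npoints} but {n} ordinates read")
        dx = (lastx - first_x) / (n - 1)
    else:
        raise SpectrumParseError("need DELTAX or LASTX+NPOINTS to build the grid")
    grid = (first_x + dx * np.arange(n)) * xfactor
    return Spectrum(grid, np.array(ys) * yfactor,
                    sample_id=header.get("TITLE", ""))


def read_spectrum(source, dialect: str = "two_column", *, sample_id: str = "",
                  replicate_id: str = ""):
    """Parse a spectrum (or, for ``csv_matrix``, a list of replicate spectra).

    Parameters
    ----------
    source
        Text stream or raw text in the named dialect.
    dialect
        ``two_column`` (whitespace/comma "wavenumber absorbance" records, ``#``
        comments), ``csv_matrix`` (first column replicate id, headers are
        wavenumbers) or ``jcampdx`` (``##XYDATA=(X++(Y..Y))``).

    Returns
    -------
    Spectrum or list of Spectrum
        Canonicalized (ascending-grid) spectra regardless of file row order.
    """
    stream = _as_stream(source)
    if dialect == "two_column":
        return _parse_two_column(stream, sample_id, replicate_id)
    if dialect == "csv_matrix":
        return _parse_csv_matrix(stream)
    if dialect == "jcampdx":
        return _parse_jcampdx(stream)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_spectrum(s: Spectrum, dialect: str = "two_column") -> str:
    """Serialize a spectrum; re-reading reproduces grid and values to < 1e-9."""
    if dialect == "two_column":
        lines = [f"# sample_id={s.sample_id} replicate_id={s.replicate_id}"]
        lines += [f"{w:.12g} {a:.12g}" for w, a in zip(s.wavenumbers, s.absorbances)]
        return "\n".join(lines) + "\n"
    if dialect == "csv_matrix":
        header = "id," + ",".join(f"{w:.12g}" for w in s.wavenumbers)
        rid = s.replicate_id or s.sample_id or "spectrum"
        row = rid + "," + ",".join(f"{a:.12g}" for a in s.absorbances)
        return header + "\n" + row + "\n"
    if dialect == "jcampdx":
        steps = np.diff(s.wavenumbers)
        dx = steps[0]
        if not np.allclose(steps, dx, rtol=0, atol=1e-9):
            raise ValueError("jcampdx dialect requires a uniform grid")
        lines = [
            f"##TITLE={s.sample_id or 'spectrum'}",
            "##JCAMP-DX=4.24",
            "##XUNITS=1/CM",
            "##YUNITS=ABSORBANCE",
            f"##FIRSTX={s.wavenumbers[0]:.12g}",
            f"##LASTX={s.wavenumbers[-1]:.12g}",
            f"##DELTAX={dx:.12g}",
            f"##NPOINTS={len(s)}",
            "##XYDATA=(X++(Y..Y))",
        ]
        per_line = 6
        for i in range(0, len(s), per_line):
            chunk = s.absorbances[i:i + per_line]
            lines.append(
                f"{s.wavenumbers[i]:.12g} " + " ".join(f"{y:.12g}" for y in chunk)
            )
        lines.append("##END=")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# band extraction

def normalize_region(s: Spectrum, lo: float = 600.0, hi: float = 1800.0) -> Spectrum:
    """Restrict to [lo, hi] cm^-1 and scale so the region's mean absorbance is 1.

    Used for plot/export parity only; the ratio algorithms are invariant to the
    scaling and never require it.
    """
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise DegenerateSpectrumError(f"no grid points in [{lo:g}, {hi:g}] cm^-1")
    region = s.absorbances[mask]
    mean = region.mean()
    if mean == 0:
        raise DegenerateSpectrumError("zero mean absorbance in normalization region")
    return replace(s, wavenumbers=s.wavenumbers[mask].copy(), absorbances=region / mean)


def _nearest_index(w: np.ndarray, center: float) -> int:
    # ties between two equally near grid points break toward the higher wavenumber
    d = np.abs(w - center)
    return int(w.size - 1 - np.argmin(d[::-1]))


def band_intensity(s: Spectrum, center: float, window_points: int = 3) -> float:
    """Multi-point band average: mean absorbance over the grid point nearest to
    ``center`` and ``(window_points - 1) / 2`` neighbours on each side."""
    if window_points < 1 or window_points % 2 == 0:
        raise ValueError("window_points must be odd and >= 1")
    w = s.wavenumbers
    if center < w[0] or center > w[-1]:
        raise DegenerateSpectrumError(
            f"band center {center:g} cm^-1 outside grid [{w[0]:g}, {w[-1]:g}]"
        )
    idx = _nearest_index(w, center)
    half = (window_points - 1) // 2
    if idx - half < 0 or idx + half >= w.size:
        raise DegenerateSpectrumError(
            f"{window_points}-point window at {center:g} cm^-1 extends past grid edge"
        )
    return float(s.absorbances[idx - half: idx + half + 1].mean())


def extract_bands(s: Spectrum, window_points: int = 3) -> BandIntensities:
    """Evaluate the six algorithm bands (956/1032/1500 and 708/730/800 cm^-1)."""
    values = {}
    failures = []
    for center in ALGORITHM_BAND_CENTERS:
        try:
            values[center] = band_intensity(s, center, window_points)
        except DegenerateSpectrumError as exc:
            failures.append((center, str(exc)))
    if failures:
        detail = "; ".join(f"{c:g} cm^-1 ({msg})" for c, msg in failures)
        raise DegenerateSpectrumError(f"bands unavailable: {detail}")
    return BandIntensities(
        i956=values[956.0], i1032=values[1032.0], i1500=values[1500.0],
        i708=values[708.0], i730=values[730.0], i800=values[800.0],
        window_points=window_points,
    )
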