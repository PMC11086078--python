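"""Band-ratio maturity (M_IR) and crystallinity (CI_IR) indices.

The two indices map three-band intensity ratios onto calibrated scales:

    R1    = (I956 - I1500) / (I1032 - I1500)        M_IR  = (R1 - 0.14) / 0.45
    R2    = (I708 - I800)  / (I730 - I800)          CI_IR = ((R2 - 1.4) / 2.0) * 100

Both ratios are affine-invariant in the absorbance trace: a global scale
cancels in the ratio and a global offset cancels in the differences, which is
what makes the method robust to contact-pressure and path-length variation in
ATR sampling.  Indices are never clipped; out-of-range values signal degenerate
spectra and are surfaced with a warning instead of being hidden.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .spectra_io import BandIntensities, DegenerateSpectrumError, Spectrum, extract_bands

__all__ = [
    "R1_OFFSET", "R1_SCALE", "R2_OFFSET", "R2_SCALE",
    "MaturityClass", "CrystallinityClass", "MaturityIndices", "AggregatedIndices",
    "compute_r1", "compute_m_ir", "compute_r2", "compute_ci_ir",
    "classify_maturity", "classify_crystallinity",
    "indices_from_bands", "indices_for_sample",
]

# calibration constants of the M_IR / CI_IR conversions
R1_OFFSET = 0.14
R1_SCALE = 0.45
R2_OFFSET = 1.4
R2_SCALE = 2.0

# class thresholds; the closed middle interval takes both boundaries
MATURITY_HIGH = 0.80     # m_ir  > 0.80  -> mature
MATURITY_LOW = 0.59      # m_ir  < 0.59  -> immature
CRYSTALLINITY_HIGH = 80.0  # ci_ir > 80   -> high
CRYSTALLINITY_LOW = 59.0   # ci_ir < 59   -> low


class MaturityClass(str, Enum):
    MATURE = "mature"
    INTERMEDIATE = "intermediate"
    IMMATURE = "immature"


class CrystallinityClass(str, Enum):
    HIGH = "high"
    MIDDLE = "middle"
    LOW = "low"


def compute_r1(b: BandIntensities) -> float:
    """Maturity band ratio R1 = (I956 - I1500) / (I1032 - I1500)."""
    denom = b.i1032 - b.i1500
    if denom == 0:
        raise DegenerateSpectrumError("R1 undefined: I1032 equals I1500")
    return (b.i956 - b.i1500) / denom


def compute_m_ir(r1: float) -> float:
    """Maturity index M_IR = (R1 - 0.14) / 0.45; not clipped."""
    return (r1 - R1_OFFSET) / R1_SCALE


def compute_r2(b: BandIntensities) -> float:
    """Crystallinity band ratio R2 = (I708 - I800) / (I730 - I800)."""
    denom = b.i730 - b.i800
    if denom == 0:
        raise DegenerateSpectrumError("R2 undefined: I730 equals I800")
    return (b.i708 - b.i800) / denom


def compute_ci_ir(r2: float) -> float:
    """Crystallinity index CI_IR (%) = ((R2 - 1.4) / 2.0) * 100; not clipped."""
    return (r2 - R2_OFFSET) / R2_SCALE * 100.0


def classify_maturity(m_ir: float) -> MaturityClass:
    """mature (> 0.80), intermediate (0.59-0.80 inclusive), immature (< 0.59)."""
    if m_ir > MATURITY_HIGH:
        return MaturityClass.MATURE
    if m_ir < MATURITY_LOW:
        return MaturityClass.IMMATURE
    return MaturityClass.INTERMEDIATE


def classify_crystallinity(ci_ir: float) -> CrystallinityClass:
    """high (> 80%), middle (59-80% inclusive), low (< 59%)."""
    if ci_ir > CRYSTALLINITY_HIGH:
        return CrystallinityClass.HIGH
    if ci_ir < CRYSTALLINITY_LOW:
        return CrystallinityClass.LOW
    return CrystallinityClass.MIDDLE


@dataclass(frozen=True)
class MaturityIndices:
    """Indices and class labels for one spectrum (or one aggregated sample)."""

    r1: float
    m_ir: float
    r2: float
    ci_ir: float
    maturity_class: MaturityClass
    crystallinity_class: CrystallinityClass

    @classmethod
    def from_bands(cls, b: BandIntensities) -> "MaturityIndices":
        r1 = compute_r1(b)
        m = compute_m_ir(r1)
        r2 = compute_r2(b)
        ci = compute_ci_ir(r2)
        if m < -0.5 or m > 2.0 or ci < -50.0 or ci > 150.0:
            warnings.warn(
                f"index outside plausible range (M_IR={m:.3g}, CI_IR={ci:.3g}%): "
                "likely degenerate spectrum; value reported unaltered",
                stacklevel=2,
            )
        return cls(r1=r1, m_ir=m, r2=r2, ci_ir=ci,
                   maturity_class=classify_maturity(m),
                   crystallinity_class=classify_crystallinity(ci))


@dataclass(frozen=True)
class AggregatedIndices:
    """Replicate mean and SEM of M_IR and CI_IR for one sample.

    SEM is the sample standard deviation (n-1 denominator) over sqrt(n); with a
    single replicate it is undefined and stored as ``None``.
    """

    mean_m_ir: float
    sem_m_ir: Optional[float]
    mean_ci_ir: float
    sem_ci_ir: Optional[float]
    n_replicates: int

    @property
    def mean_r1(self) -> float:
        return R1_SCALE * self.mean_m_ir + R1_OFFSET

    @property
    def mean_r2(self) -> float:
        return R2_OFFSET + R2_SCALE * self.mean_ci_ir / 100.0

    @property
    def maturity_class(self) -> MaturityClass:
        return classify_maturity(self.mean_m_ir)

    @property
    def crystallinity_class(self) -> CrystallinityClass:
        return classify_crystallinity(self.mean_ci_ir)


def indices_from_bands(b: BandIntensities) -> MaturityIndices:
    """Convenience wrapper around :meth:`MaturityIndices.from_bands`."""
    return MaturityIndices.from_bands(b)


def _sem(values: np.ndarray) -> Optional[float]:
    if values.size < 2:
        return None
    return float(values.std(ddof=1) / math.sqrt(values.size))


def indices_for_sample(replicates: Sequence[Spectrum],
                       window_points: int = 3) -> AggregatedIndices:
    """Compute per-replicate indices, then aggregate across replicates.

    Indices are computed per replicate and averaged afterwards (never the
    spectra themselves), so each replicate's scaling cancels individually and
    the SEM describes measurement repeatability on the index scale.
    """
    if len(replicates) < 1:
        raise ValueError("need at least one replicate spectrum")
    m_vals, ci_vals = [], []
    for i, s in enumerate(replicates):
        try:
            idx = MaturityIndices.from_bands(extract_bands(s, window_points))
        except (DegenerateSpectrumError, ValueError) as exc:
            rid = s.replicate_id or s.sample_id or f"replicate {i}"
            raise DegenerateSpectrumError(f"replicate {rid!r}: {exc}") from exc
        m_vals.append(idx.m_ir)
        ci_vals.append(idx.ci_ir)
    m = np.array(m_vals)
    ci = np.array(ci_vals)
    return AggregatedIndices(
        mean_m_ir=float(m.mean()), sem_m_ir=_sem(m),
        mean_ci_ir=float(ci.mean()), sem_ci_ir=_sem(ci),
        n_replicates=len(replicates),
    )
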