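"""Reporting statistics: Pearson correlation, polynomial fits, SEM, model choice.

Thin, contract-enforcing wrappers over scipy/numpy.  Significance stars follow
the convention p < 0.05 (*), < 0.01 (**), < 0.001 (***), < 0.0001 (****); a
p-value exactly equal to a threshold takes the weaker label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "FitResult", "stars_for_p", "pearson", "fit_polynomial", "sem",
    "model_selection",
]

_STAR_LEVELS: Tuple[Tuple[float, str], ...] = (
    (0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"),
)


def stars_for_p(p: float) -> str:
    """Significance stars; strict inequality at every threshold."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    for thresh, label in _STAR_LEVELS:
        if p < thresh:
            return label
    return "ns"


@dataclass(frozen=True)
class FitResult:
    kind: str                       # "linear" | "quadratic" | "exponential"
    coefficients: Tuple[float, ...]  # intercept-first
    r_squared: float
    p_value: float
    stars: str
    n: int
    pearson_r: Optional[float] = None  # linear kind only

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "exponential":
            a, b = self.coefficients
            return a * np.exp(b * x)
        return sum(c * x ** k for k, c in enumerate(self.coefficients))


def _validated_xy(x: Sequence[float], y: Sequence[float], min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points, got {x.size}")
    return x, y


def pearson(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float, str]:
    """Product-moment r with a two-sided t-test p-value and its star label."""
    x, y = _validated_xy(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), stars_for_p(float(p))


def sem(values: Sequence[float]) -> Optional[float]:
    """Standard error of the mean (sample sd / sqrt(n)); None when n < 2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return None
    return float(v.std(ddof=1) / math.sqrt(v.size))


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("constant y: R^2 undefined (zero total variance)")
    ss_res = float(((y - yhat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def _overall_f_p(y: np.ndarray, yhat: np.ndarray, n_params: int) -> float:
    """Two-sided p of the overall-regression F test."""
    n = y.size
    df_model = n_params - 1
    df_resid = n - n_params
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(((y - yhat) ** 2).sum())
    ss_reg = ss_tot - ss_res
    if df_resid <= 0:
        return float("nan")
    if ss_res <= 0:  # perfect fit
        return 0.0
    f = (ss_reg / df_model) / (ss_res / df_resid)
    return float(sps.f.sf(f, df_model, df_resid))


def fit_polynomial(x: Sequence[float], y: Sequence[float], degree: int) -> FitResult:
    """Unweighted least-squares polynomial fit (degree 1 or 2), intercept first."""
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    x, y = _validated_xy(x, y, degree + 2)
    if np.unique(x).size < degree + 1:
        raise ValueError(
            f"need >= {degree + 1} distinct x values for degree {degree}")
    design = np.vander(x, degree + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < degree + 1:
        raise ValueError("rank-deficient design matrix")
    yhat = design @ coef
    r2 = _r_squared(y, yhat)
    p = _overall_f_p(y, yhat, degree + 1)
    r = None
    if degree == 1:
        r, _, _ = pearson(x, y)
    return FitResult(kind="linear" if degree == 1 else "quadratic",
                     coefficients=tuple(float(c) for c in coef),
                     r_squared=r2, p_value=p, stars=stars_for_p(p),
                     n=x.size, pearson_r=r)


def _fit_exponential(x: np.ndarray, y: np.ndarray) -> FitResult:
    """y = a*exp(b*x) by least squares on log y; R^2 on the original scale."""
    if np.any(y <= 0):
        raise ValueError("exponential model requires strictly positive y")
    design = np.vander(x, 2, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(design, np.log(y), rcond=None)
    if rank < 2:
        raise ValueError("rank-deficient design matrix")
    a = float(np.exp(coef[0]))
    b = float(coef[1])
    yhat = a * np.exp(b * x)
    r2 = _r_squared(y, yhat)
    p = _overall_f_p(y, yhat, 2)
    return FitResult(kind="exponential", coefficients=(a, b), r_squared=r2,
                     p_value=p, stars=stars_for_p(p), n=x.size)


# tie-break order: simplest model wins within 1e-12 of the best R^2
_COMPLEXITY = {"linear": 0, "quadratic": 1, "exponential": 2}


def model_selection(x: Sequence[float], y: Sequence[float]):
    """Fit linear, quadratic and exponential curves; pick the best R^2.

    The exponential model is skipped (with a notice) when any y <= 0.  Ties
    within 1e-12 go to the lower-complexity model.

    Returns
    -------
    (winner, fits, notices)
        ``winner`` is the winning kind, ``fits`` maps kind -> FitResult,
        ``notices`` lists skipped models.
    """
    x, y = _validated_xy(x, y, 4)
    fits: Dict[str, FitResult] = {
        "linear": fit_polynomial(x, y, 1),
        "quadratic": fit_polynomial(x, y, 2),
    }
    notices: List[str] = []
    try:
        fits["exponential"] = _fit_exponential(x, y)
    except ValueError as exc:
        notices.append(f"exponential model skipped: {exc}")
    best_r2 = max(f.r_squared for f in fits.values())
    candidates = [k for k, f in fits.items() if best_r2 - f.r_squared <= 1e-12]
    winner = min(candidates, key=_COMPLEXITY.__getitem__)
    return winner, fits, notices
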