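"""Growing-degree-day accumulation and boll development timing.

Cotton development is driven by accumulated heat units (DD60 convention):
each day contributes the daily mean temperature above a 60 degF / 15.6 degC
threshold, negative contributions clamped to zero by default.  Flowering dates
follow the fruiting-branch lattice: the first flower opens at the anchor
coordinate (node 6, position 1) and each step up a node adds 3 days, each step
out a position adds 6 days.  Boll development takes six weeks, so a boll's
maturation window can collide with end-of-season defoliant sprays - those
bolls are flagged mild or severe depending on which spray interrupts them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries", "PhenologyConfig", "DefoliationImpact",
    "gdd_cumulative", "flowering_dap", "maturation_dap",
    "defoliation_impact", "event_daps", "phenology_table",
]


class DefoliationImpact(str, Enum):
    NONE = "none"
    MILD = "mild"
    SEVERE = "severe"


@dataclass
class TemperatureSeries:
    """Daily maximum/minimum temperatures indexed by day after planting (DAP)."""

    dap: np.ndarray
    tmax: np.ndarray
    tmin: np.ndarray
    units: str = "celsius"  # "celsius" | "fahrenheit"

    def __post_init__(self) -> None:
        self.dap = np.asarray(self.dap, dtype=int)
        self.tmax = np.asarray(self.tmax, dtype=float)
        self.tmin = np.asarray(self.tmin, dtype=float)
        if self.units not in ("celsius", "fahrenheit"):
            raise ValueError(f"unknown temperature units {self.units!r}")
        if not (self.dap.size == self.tmax.size == self.tmin.size):
            raise ValueError("dap/tmax/tmin length mismatch")
        if self.dap.size and np.any(np.diff(self.dap) <= 0):
            raise ValueError("dap must be strictly increasing")
        if np.any(self.dap < 0):
            raise ValueError("dap must be >= 0")
        if np.any(self.tmax < self.tmin):
            bad = int(self.dap[self.tmax < self.tmin][0])
            raise ValueError(f"tmax < tmin on dap {bad}")

    @classmethod
    def from_csv(cls, source, units: Optional[str] = None) -> "TemperatureSeries":
        df = pd.read_csv(source)
        cols = {c.lower(): c for c in df.columns}
        try:
            dap = df[cols["dap"]]
            tmax = df[cols["tmax"]]
            tmin = df[cols["tmin"]]
        except KeyError as exc:
            raise ValueError(f"temperature CSV missing column {exc}") from exc
        if units is None:
            units = str(df[cols["units"]].iloc[0]) if "units" in cols else "celsius"
        return cls(dap.to_numpy(), tmax.to_numpy(), tmin.to_numpy(), units=units)


def _c_to_f(t: float) -> float:
    return t * 9.0 / 5.0 + 32.0


@dataclass
class PhenologyConfig:
    """Thresholds and anchors of the cotton development timeline.

    ``t_threshold_c`` is the DD60 base temperature (15.6 degC = 60 degF).
    ``event_gdd`` thresholds (emergence 50, squaring 431) are Fahrenheit
    degree-days, the convention the DD60 literature reports them in; they are
    converted automatically when the temperature series is Celsius.
    Spray days: defoliator passes on 139 and 146 DAP, harvest on 156 DAP.
    """

    t_threshold_c: float = 15.6
    anchor_node: int = 6
    anchor_position: int = 1
    anchor_flowering_dap: int = 60
    dap_per_node: int = 3
    dap_per_position: int = 6
    development_days: int = 42
    event_gdd: Dict[str, float] = field(
        default_factory=lambda: {"emergence": 50.0, "squaring": 431.0})
    event_gdd_units: str = "fahrenheit"
    spray_daps: Dict[str, int] = field(
        default_factory=lambda: {"defoliator_1": 139, "defoliator_2": 146,
                                 "harvest": 156})

    def __post_init__(self) -> None:
        for name in ("dap_per_node", "dap_per_position", "development_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def threshold_in(self, units: str) -> float:
        if units == "celsius":
            return self.t_threshold_c
        if units == "fahrenheit":
            return _c_to_f(self.t_threshold_c)
        raise ValueError(f"unknown units {units!r}")

    def event_threshold_in(self, event: str, units: str) -> float:
        gdd = self.event_gdd[event]
        if units == self.event_gdd_units:
            return gdd
        # degree-day differences convert by the 9/5 scale factor only
        if units == "celsius" and self.event_gdd_units == "fahrenheit":
            return gdd * 5.0 / 9.0
        if units == "fahrenheit" and self.event_gdd_units == "celsius":
            return gdd * 9.0 / 5.0
        raise ValueError(f"unknown units {units!r}")


def gdd_cumulative(ts: TemperatureSeries, cfg: PhenologyConfig | None = None,
                   clamp_negative: bool = True) -> pd.DataFrame:
    """Daily and cumulative growing degree days.

    Each day contributes ``(tmax + tmin)/2 - Tt`` in the series' own units,
    clamped at zero unless ``clamp_negative`` is false.

    Returns
    -------
    pandas.DataFrame
        Columns ``dap``, ``daily_gdd``, ``cumulative_gdd``.
    """
    cfg = cfg or PhenologyConfig()
    tt = cfg.threshold_in(ts.units)
    daily = (ts.tmax + ts.tmin) / 2.0 - tt
    if clamp_negative:
        daily = np.maximum(daily, 0.0)
    return pd.DataFrame({
        "dap": ts.dap,
        "daily_gdd": daily,
        "cumulative_gdd": np.cumsum(daily),
    })


def flowering_dap(node: int, position: int, cfg: PhenologyConfig | None = None) -> int:
    """Day after planting on which the boll at (node, position) flowers."""
    cfg = cfg or PhenologyConfig()
    if node < cfg.anchor_node:
        raise ValueError(
            f"node {node} below first fruiting branch (node {cfg.anchor_node})")
    if position < 1:
        raise ValueError("position must be >= 1")
    return (cfg.anchor_flowering_dap
            + cfg.dap_per_node * (node - cfg.anchor_node)
            + cfg.dap_per_position * (position - 1))


def maturation_dap(node: int, position: int, cfg: PhenologyConfig | None = None) -> int:
    """Flowering day plus the six-week boll development window."""
    cfg = cfg or PhenologyConfig()
    return flowering_dap(node, position, cfg) + cfg.development_days


def defoliation_impact(node: int, position: int,
                       cfg: PhenologyConfig | None = None) -> DefoliationImpact:
    """Flag bolls whose maturation runs past a defoliant spray.

    severe: matures after the second (major) spray; mild: matures in the window
    between the two sprays; none otherwise.
    """
    cfg = cfg or PhenologyConfig()
    m = maturation_dap(node, position, cfg)
    if m > cfg.spray_daps["defoliator_2"]:
        return DefoliationImpact.SEVERE
    if m > cfg.spray_daps["defoliator_1"]:
        return DefoliationImpact.MILD
    return DefoliationImpact.NONE


def event_daps(ts: TemperatureSeries,
               cfg: PhenologyConfig | None = None) -> Dict[str, Optional[int]]:
    """First DAP at which cumulative GDD reaches each configured event threshold.

    Events whose threshold is never reached map to ``None``.
    """
    cfg = cfg or PhenologyConfig()
    gdd = gdd_cumulative(ts, cfg, clamp_negative=True)
    out: Dict[str, Optional[int]] = {}
    cum = gdd["cumulative_gdd"].to_numpy()
    daps = gdd["dap"].to_numpy()
    for event in cfg.event_gdd:
        thresh = cfg.event_threshold_in(event, ts.units)
        hit = np.nonzero(cum >= thresh)[0]
        out[f"{event}_dap"] = int(daps[hit[0]]) if hit.size else None
    return out


def phenology_table(nodes, positions,
                    cfg: PhenologyConfig | None = None) -> pd.DataFrame:
    """Flowering/maturation/defoliation-impact lattice over nodes x positions.

    The mild/severe split is an inference from the spray timeline, not a
    measured outcome; downstream reports carry it as a flag only.
    """
    cfg = cfg or PhenologyConfig()
    rows = []
    for node in nodes:
        for pos in positions:
            rows.append({
                "node": node,
                "position": pos,
                "location": f"{node}-{pos}",
                "flowering_dap": flowering_dap(node, pos, cfg),
                "maturation_dap": maturation_dap(node, pos, cfg),
                "defoliation_impact": defoliation_impact(node, pos, cfg).value,
            })
    return pd.DataFrame(rows)
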