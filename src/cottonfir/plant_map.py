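"""Node/position boll architecture, lint metrics and per-location aggregation.

An Upland cotton plant carries bolls on sympodial (fruiting) branches: a boll's
coordinate is "mainstem node - branch position" (cotyledon node = 0; fruiting
branches start around node 6), printed as e.g. ``16-4``.  Single-boll IR
indices are aggregated per location across plants here, since conventional
maturity instruments need more fiber than a single boll yields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .band_indices import AggregatedIndices
from .spectra_io import Spectrum
from .stats_report import sem

__all__ = [
    "BollRecord", "PlantMap", "parse_location", "format_location",
    "lint_percentage", "plant_totals", "location_series",
    "combine_locations", "join_conventional", "attach_indices",
    "indices_table",
]


def parse_location(label: str) -> Tuple[int, int]:
    """Parse a "node-position" label, e.g. ``"16-4"`` -> ``(16, 4)``."""
    try:
        node_s, pos_s = label.split("-")
        node, pos = int(node_s), int(pos_s)
    except ValueError as exc:
        raise ValueError(f"malformed location label {label!r}") from exc
    if node < 0 or pos < 1:
        raise ValueError(f"location {label!r} out of range (node >= 0, position >= 1)")
    return node, pos


def format_location(node: int, position: int) -> str:
    return f"{node}-{position}"


@dataclass
class BollRecord:
    """One boll: its coordinates, lint masses, spectra and derived quantities."""

    plant_id: str
    node: int
    position: int
    lint_mass: float = 0.0
    seed_cotton_mass: Optional[float] = None
    replicate_spectra: List[Spectrum] = field(default_factory=list)
    indices: Optional[AggregatedIndices] = None
    flowering_dap: Optional[int] = None
    harvest_maturity_dap: Optional[int] = None

    def __post_init__(self) -> None:
        if self.node < 0:
            raise ValueError("node must be >= 0 (cotyledon node = 0)")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.lint_mass < 0:
            raise ValueError("lint_mass must be >= 0")
        if self.seed_cotton_mass is not None and self.seed_cotton_mass < self.lint_mass:
            raise ValueError("seed_cotton_mass must be >= lint_mass")

    @property
    def label(self) -> str:
        return format_location(self.node, self.position)


@dataclass
class PlantMap:
    """All bolls of one plant; labels must be unique within the plant."""

    plant_id: str
    bolls: List[BollRecord] = field(default_factory=list)
    planting_date: Optional[str] = None

    def __post_init__(self) -> None:
        labels = [b.label for b in self.bolls]
        if len(labels) != len(set(labels)):
            seen = set()
            dup = next(l for l in labels if l in seen or seen.add(l))
            raise ValueError(f"duplicate boll label {dup!r} in plant {self.plant_id!r}")

    def boll_at(self, node: int, position: int) -> Optional[BollRecord]:
        for b in self.bolls:
            if b.node == node and b.position == position:
                return b
        return None


def lint_percentage(lint_mass: float, seed_cotton_mass: float) -> float:
    """Lint mass over seed-cotton mass, in percent."""
    if seed_cotton_mass <= 0:
        raise ValueError("seed_cotton_mass must be > 0")
    if lint_mass < 0:
        raise ValueError("lint_mass must be >= 0")
    return 100.0 * lint_mass / seed_cotton_mass


def plant_totals(p: PlantMap) -> Dict[str, Optional[float]]:
    """Plant-level yield summary: boll count, total/mean lint, lint percentage.

    Lint percentage is the ratio of totals, reported only when every boll has a
    seed-cotton mass (never imputed).  A mean of per-boll percentages is also
    exposed (``lint_pct_per_boll_mean``) because a summary table can be read
    either way; neither is claimed as canonical.
    """
    if not p.bolls:
        raise ValueError(f"plant {p.plant_id!r} has no bolls")
    lint = np.array([b.lint_mass for b in p.bolls])
    out: Dict[str, Optional[float]] = {
        "boll_number": len(p.bolls),
        "total_lint": float(lint.sum()),
        "mean_lint": float(lint.sum() / len(p.bolls)),
    }
    if all(b.seed_cotton_mass is not None for b in p.bolls):
        seed = np.array([b.seed_cotton_mass for b in p.bolls])
        out["lint_pct"] = float(100.0 * lint.sum() / seed.sum())
        out["lint_pct_per_boll_mean"] = float(
            np.mean([lint_percentage(l, s) for l, s in zip(lint, seed)]))
    else:
        out["lint_pct"] = None
        out["lint_pct_per_boll_mean"] = None
    return out


def _index_value(b: BollRecord, index: str) -> Tuple[float, Optional[float]]:
    if b.indices is None:
        raise ValueError(f"boll {b.label} of plant {b.plant_id!r} has no indices")
    if index == "m_ir":
        return b.indices.mean_m_ir, b.indices.sem_m_ir
    if index == "ci_ir":
        return b.indices.mean_ci_ir, b.indices.sem_ci_ir
    raise ValueError(f"unknown index {index!r}")


def location_series(p: PlantMap, axis: str, fixed: Optional[int] = None,
                    index: str = "m_ir") -> List[Tuple[int, float, Optional[float]]]:
    """Ordered (coordinate, value, sem) series along one architectural axis.

    ``by_node_at_position``: one entry per occupied node at position ``fixed``,
    value = the boll's replicate mean with its replicate SEM.
    ``by_position``: mean over the plant's nodes per position, SEM across bolls.
    An empty selection yields an empty series, not an error.
    """
    if axis == "by_node_at_position":
        if fixed is None:
            raise ValueError("by_node_at_position requires fixed=<position>")
        picked = sorted((b for b in p.bolls if b.position == fixed),
                        key=lambda b: b.node)
        return [(b.node, *_index_value(b, index)) for b in picked]
    if axis == "by_position":
        by_pos: Dict[int, List[float]] = {}
        for b in p.bolls:
            by_pos.setdefault(b.position, []).append(_index_value(b, index)[0])
        return [(pos, float(np.mean(vals)), sem(vals))
                for pos, vals in sorted(by_pos.items())]
    raise ValueError(f"unknown axis {axis!r}")


def combine_locations(plants: Sequence[PlantMap]) -> pd.DataFrame:
    """Across-plant mean and SEM of M_IR / CI_IR at each node-position location.

    A location contributes when present in at least one plant; single-plant
    locations carry NaN SEMs (undefined, not zero).  The study's physical
    analogue blended fibers from the same location before re-measuring; here the
    per-plant replicate-mean indices are averaged instead.
    """
    if not plants:
        raise ValueError("need at least one plant")
    rows: Dict[str, Dict[str, list]] = {}
    for p in plants:
        for b in p.bolls:
            m, _ = _index_value(b, "m_ir")
            ci, _ = _index_value(b, "ci_ir")
            slot = rows.setdefault(b.label, {"m": [], "ci": [],
                                             "node": b.node, "position": b.position})
            slot["m"].append(m)
            slot["ci"].append(ci)
    records = []
    for label, slot in rows.items():
        m = np.array(slot["m"])
        ci = np.array(slot["ci"])
        records.append({
            "location": label, "node": slot["node"], "position": slot["position"],
            "n_plants": m.size,
            "mean_m_ir": m.mean(), "sem_m_ir": sem(m) if m.size > 1 else np.nan,
            "mean_ci_ir": ci.mean(), "sem_ci_ir": sem(ci) if ci.size > 1 else np.nan,
        })
    df = pd.DataFrame(records).sort_values(["node", "position"]).reset_index(drop=True)
    return df


def join_conventional(combined: pd.DataFrame, conventional: pd.DataFrame,
                      min_overlap: int = 3) -> pd.DataFrame:
    """Inner-join the combined IR table with conventional (MIC / M_AFIS) values.

    The conventional table must be keyed by a unique ``location`` column;
    fewer than ``min_overlap`` shared locations makes downstream correlation
    meaningless and raises.
    """
    if "location" not in conventional.columns:
        raise ValueError("conventional table needs a 'location' column")
    dup = conventional["location"][conventional["location"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate location {dup.iloc[0]!r} in conventional table")
    joined = combined.merge(conventional, on="location", how="inner")
    if len(joined) < min_overlap:
        raise ValueError(
            f"only {len(joined)} overlapping locations (< {min_overlap}); "
            "correlation undefined")
    return joined


def attach_indices(p: PlantMap, window_points: int = 3) -> PlantMap:
    """Compute and store AggregatedIndices on every boll from its spectra."""
    from .band_indices import indices_for_sample

    for b in p.bolls:
        if not b.replicate_spectra:
            raise ValueError(f"boll {b.label} of plant {p.plant_id!r} has no spectra")
        b.indices = indices_for_sample(b.replicate_spectra, window_points)
    return p


def indices_table(plants: Sequence[PlantMap]) -> pd.DataFrame:
    """Tidy per-boll index table (one row per boll across all plants)."""
    rows = []
    for p in plants:
        for b in p.bolls:
            idx = b.indices
            if idx is None:
                raise ValueError(f"boll {b.label} of plant {p.plant_id!r} has no indices")
            rows.append({
                "plant_id": p.plant_id, "node": b.node, "position": b.position,
                "location": b.label, "sample_id": f"{p.plant_id}:{b.label}",
                "n_replicates": idx.n_replicates,
                "r1": idx.mean_r1, "m_ir": idx.mean_m_ir,
                "sem_m_ir": np.nan if idx.sem_m_ir is None else idx.sem_m_ir,
                "maturity_class": idx.maturity_class.value,
                "r2": idx.mean_r2, "ci_ir": idx.mean_ci_ir,
                "sem_ci_ir": np.nan if idx.sem_ci_ir is None else idx.sem_ci_ir,
                "crystallinity_class": idx.crystallinity_class.value,
                "lint_mass_g": b.lint_mass,
            })
    return pd.DataFrame(rows)
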