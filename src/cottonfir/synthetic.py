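"""Synthetic cellulose-like ATR FT-IR spectra and virtual cotton plants.

No raw fiber spectra accompany the study conditions this package models, so
testability rests on a generator that (a) renders cellulose-like absorbance
traces from a parametric band inventory and (b) inverts the maturity /
crystallinity algorithms: given target M_IR and CI_IR, the amplitudes of the
956 cm^-1 and 708 cm^-1 bands are solved so the rendered spectrum's multi-point
band averages hit the target ratios exactly.  Because every band average is
linear in band amplitudes, the inversion is an exact 2x2 linear solve - the
noiseless closed loop (targets -> spectrum -> extract_bands -> indices) closes
to machine precision.

Virtual plants add the within-plant structure reported for field-grown cotton:
a quadratic maturity profile over mainstem nodes (rising from the lowest
fruiting branch to the mid-canopy, falling toward the terminal nodes), a
per-position decline along each fruiting branch, a maturity penalty for bolls
whose development window collides with defoliant sprays, and a positive linear
crystallinity-maturity relation with biological scatter.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import phenology as phen
from .band_indices import R1_OFFSET, R1_SCALE, R2_OFFSET, R2_SCALE
from .plant_map import BollRecord, PlantMap, format_location
from .spectra_io import Spectrum, band_intensity

__all__ = [
    "Band", "BandModel", "VirtualPlantConfig",
    "default_band_model", "target_to_band_amplitudes", "render_spectrum",
    "make_virtual_plant", "make_virtual_experiment",
]


@dataclass(frozen=True)
class Band:
    center: float      # cm^-1
    width: float       # cm^-1 (gaussian sigma / lorentzian half-width)
    amplitude: float   # unitless absorbance at peak

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")


@dataclass
class BandModel:
    """Parametric band inventory on a uniform wavenumber grid.

    The two bands whose amplitudes encode the indices (956 and 708 cm^-1) are
    listed alongside decoy cellulose bands (water bend at 1620, C-H bends at
    1422/1366/1312, the C-O stretching cluster at 1200-1000, the beta-glycosidic
    895 band, crystal-form bands at 800-700, and O-H/C-H stretches above 2700).
    There is deliberately no band at 1500 cm^-1: the algorithms treat I1500 as a
    local baseline, so the model keeps it a low-absorbance valley.
    """

    bands: List[Band]
    shape: str = "gaussian"          # "gaussian" | "lorentzian"
    grid: Tuple[float, float, float] = (600.0, 4000.0, 2.0)  # lo, hi, step

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")
        lo, hi, step = self.grid
        if step <= 0 or hi <= lo:
            raise ValueError("grid must be (lo, hi, step) with step > 0, hi > lo")

    def wavenumber_grid(self) -> np.ndarray:
        lo, hi, step = self.grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    def band_at(self, center: float) -> Band:
        for b in self.bands:
            if b.center == center:
                return b
        raise ValueError(f"no band at {center:g} cm^-1 in model")

    def with_amplitude(self, center: float, amplitude: float) -> "BandModel":
        new = copy.deepcopy(self)
        for i, b in enumerate(new.bands):
            if b.center == center:
                new.bands[i] = replace(b, amplitude=amplitude)
                return new
        raise ValueError(f"no band at {center:g} cm^-1 in model")

    def profile(self, band: Band, grid: Optional[np.ndarray] = None) -> np.ndarray:
        """Unit-free intensity of one band across the grid."""
        nu = self.wavenumber_grid() if grid is None else grid
        d = nu - band.center
        if self.shape == "gaussian":
            return band.amplitude * np.exp(-d * d / (2.0 * band.width ** 2))
        return band.amplitude * band.width ** 2 / (d * d + band.width ** 2)

    def render(self) -> np.ndarray:
        nu = self.wavenumber_grid()
        total = np.zeros_like(nu)
        for b in self.bands:
            total += self.profile(b, nu)
        return total


def default_band_model() -> BandModel:
    """Cellulose-like band inventory; widths are design choices, not claims."""
    return BandModel(bands=[
        # O-H / C-H stretching region (outside the analysis window; decoys)
        Band(3340.0, 120.0, 0.40),
        Band(2900.0, 40.0, 0.10),
        # adsorbed-water O-H bend
        Band(1620.0, 40.0, 0.15),
        # C-H vibrations
        Band(1422.0, 12.0, 0.08),
        Band(1366.0, 12.0, 0.08),
        Band(1312.0, 12.0, 0.06),
        # C-O stretching cluster
        Band(1160.0, 15.0, 0.35),
        Band(1110.0, 15.0, 0.45),
        Band(1060.0, 14.0, 0.55),
        Band(1032.0, 12.0, 0.60),
        Band(1000.0, 12.0, 0.30),
        # maturity-encoding band (amplitude solved per target)
        Band(956.0, 10.0, 0.20),
        # beta-glycosidic linkage
        Band(895.0, 10.0, 0.05),
        # cellulose crystal-form region
        Band(800.0, 8.0, 0.02),
        Band(730.0, 9.0, 0.06),
        # crystallinity-encoding band (amplitude solved per target)
        Band(708.0, 8.0, 0.15),
    ])


_M_BAND = 956.0
_CI_BAND = 708.0


def _six_band_averages(values: np.ndarray, grid: np.ndarray,
                       window_points: int) -> Dict[float, float]:
    s = Spectrum(grid, values)
    return {c: band_intensity(s, c, window_points)
            for c in (956.0, 1032.0, 1500.0, 708.0, 730.0, 800.0)}


def target_to_band_amplitudes(m_ir: float, ci_ir: float,
                              model: Optional[BandModel] = None,
                              window_points: int = 3) -> BandModel:
    """Solve the 956/708 band amplitudes so the rendered spectrum hits the targets.

    The target ratios are r1 = 0.45*m_ir + 0.14 and r2 = 1.4 + 2*ci_ir/100.
    Band averages are linear in amplitudes, so the two ratio constraints form a
    2x2 linear system in the two free amplitudes (cross-leakage of each band
    into the other ratio's windows is included, not assumed zero).
    """
    model = model if model is not None else default_band_model()
    r1_t = R1_SCALE * m_ir + R1_OFFSET
    r2_t = R2_OFFSET + R2_SCALE * ci_ir / 100.0
    grid = model.wavenumber_grid()

    base = np.zeros_like(grid)
    unit_m = unit_ci = None
    for b in model.bands:
        if b.center == _M_BAND:
            unit_m = model.profile(replace(b, amplitude=1.0), grid)
        elif b.center == _CI_BAND:
            unit_ci = model.profile(replace(b, amplitude=1.0), grid)
        else:
            base += model.profile(b, grid)
    if unit_m is None or unit_ci is None:
        raise ValueError("model must contain bands at 956 and 708 cm^-1")

    bav = _six_band_averages(base, grid, window_points)
    uav = _six_band_averages(unit_m, grid, window_points)
    vav = _six_band_averages(unit_ci, grid, window_points)

    def constraint(av: Dict[float, float], num: float, ref: float, den: float,
                   ratio: float) -> float:
        # contribution to (I_num - I_ref) - ratio * (I_den - I_ref)
        return (av[num] - av[ref]) - ratio * (av[den] - av[ref])

    a_mat = np.array([
        [constraint(uav, 956.0, 1500.0, 1032.0, r1_t),
         constraint(vav, 956.0, 1500.0, 1032.0, r1_t)],
        [constraint(uav, 708.0, 800.0, 730.0, r2_t),
         constraint(vav, 708.0, 800.0, 730.0, r2_t)],
    ])
    rhs = -np.array([
        constraint(bav, 956.0, 1500.0, 1032.0, r1_t),
        constraint(bav, 708.0, 800.0, 730.0, r2_t),
    ])
    amp_m, amp_ci = np.linalg.solve(a_mat, rhs)
    if amp_m < 0 or amp_ci < 0:
        raise ValueError(
            f"targets (M_IR={m_ir:g}, CI_IR={ci_ir:g}%) require a negative band "
            f"amplitude (956: {amp_m:.4g}, 708: {amp_ci:.4g})")
    return model.with_amplitude(_M_BAND, float(amp_m)).with_amplitude(
        _CI_BAND, float(amp_ci))


def render_spectrum(model: BandModel, noise_sigma: float = 0.0,
                    seed=0, sample_id: str = "", replicate_id: str = "") -> Spectrum:
    """Render the band model plus i.i.d. Gaussian noise; deterministic per seed.

    ``seed`` may be an int, a sequence of ints (hierarchical stream key) or a
    ``numpy.random.Generator``.
    """
    grid = model.wavenumber_grid()
    values = model.render()
    if noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, size=grid.size)
    return Spectrum(grid, values, sample_id=sample_id, replicate_id=replicate_id)


@dataclass
class VirtualPlantConfig:
    """Ground-truth structure of one virtual plant.

    ``m_ir_profile`` gives intercept-first quadratic coefficients of true M_IR
    over mainstem node at position 1; defaults put the maturity peak at node 13
    (0.87) falling to ~0.67 at node 6 and ~0.61 at node 21, matching the
    mid-canopy maximum reported for field plants.  ``position_decay`` subtracts
    per position step along the branch; bolls flagged by the defoliation
    timeline lose ``defoliation_penalty`` (half of it when mildly affected).
    True CI_IR follows ci = ci_alpha + ci_beta * m + N(0, ci_noise), a positive
    linear maturity-crystallinity relation with biological scatter.
    Replicates emulate re-sampling the fiber tuft: five measurements per boll
    with absorbance noise ``noise_sigma``.
    """

    node_range: Tuple[int, int] = (6, 21)
    position_occupancy: Tuple[float, ...] = (0.95, 0.70, 0.35, 0.15, 0.05)
    m_ir_profile: Tuple[float, float, float] = (0.194, 0.104, -0.004)
    position_decay: float = 0.02
    ci_alpha: float = -2.0
    ci_beta: float = 105.0
    ci_noise: float = 3.0
    defoliation_penalty: float = 0.12
    replicate_count: int = 5
    noise_sigma: float = 0.001
    seed: int = 0
    plant_id: str = "A"
    plant_index: int = 0

    def __post_init__(self) -> None:
        if not all(0.0 <= o <= 1.0 for o in self.position_occupancy):
            raise ValueError("occupancy probabilities must lie in [0, 1]")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")

    def true_m_ir(self, node: int, position: int,
                  impact: phen.DefoliationImpact) -> float:
        c0, c1, c2 = self.m_ir_profile
        m = c0 + c1 * node + c2 * node * node - self.position_decay * (position - 1)
        if impact is phen.DefoliationImpact.SEVERE:
            m -= self.defoliation_penalty
        elif impact is phen.DefoliationImpact.MILD:
            m -= self.defoliation_penalty / 2.0
        return m


def _boll_rng(cfg: VirtualPlantConfig, *stream: int) -> np.random.Generator:
    # hierarchical, collision-free streams: (master seed, plant, *key)
    return np.random.default_rng([cfg.seed, cfg.plant_index, *stream])


def make_virtual_plant(cfg: VirtualPlantConfig,
                       phen_cfg: Optional[phen.PhenologyConfig] = None,
                       band_model: Optional[BandModel] = None,
                       ) -> Tuple[PlantMap, pd.DataFrame]:
    """Generate one virtual plant and its hidden truth table.

    Returns the PlantMap (bolls with rendered replicate spectra, no indices)
    and a DataFrame of per-boll ground truth (true_m_ir, true_ci_ir, phenology
    dates, defoliation impact) kept separate from the plant so recovery
    experiments cannot leak it.
    """
    phen_cfg = phen_cfg or phen.PhenologyConfig()
    band_model = band_model if band_model is not None else default_band_model()
    lo, hi = cfg.node_range

    occupied: List[Tuple[int, int]] = []
    for attempt in range(100):
        rng = _boll_rng(cfg, 0, attempt)
        occupied = [(node, pos + 1)
                    for node in range(lo, hi + 1)
                    for pos, occ in enumerate(cfg.position_occupancy)
                    if rng.random() < occ]
        if occupied:
            break
    else:
        raise RuntimeError("no bolls placed after 100 occupancy resamples")

    bolls: List[BollRecord] = []
    truth_rows = []
    for node, pos in occupied:
        impact = phen.defoliation_impact(node, pos, phen_cfg)
        true_m = cfg.true_m_ir(node, pos, impact)
        rng = _boll_rng(cfg, 1, node, pos)
        true_ci = cfg.ci_alpha + cfg.ci_beta * true_m + rng.normal(0.0, cfg.ci_noise)
        lint = max(0.3, 0.6 + 2.2 * true_m + rng.normal(0.0, 0.25))
        seed_cotton = lint / 0.36 * (1.0 + abs(rng.normal(0.0, 0.02)))

        boll_model = target_to_band_amplitudes(true_m, true_ci, band_model)
        spectra = [
            render_spectrum(
                boll_model, cfg.noise_sigma,
                seed=_boll_rng(cfg, 2, node, pos, rep),
                sample_id=f"{cfg.plant_id}:{format_location(node, pos)}",
                replicate_id=f"rep{rep + 1}",
            )
            for rep in range(cfg.replicate_count)
        ]
        f_dap = phen.flowering_dap(node, pos, phen_cfg)
        m_dap = phen.maturation_dap(node, pos, phen_cfg)
        bolls.append(BollRecord(
            plant_id=cfg.plant_id, node=node, position=pos,
            lint_mass=float(lint), seed_cotton_mass=float(seed_cotton),
            replicate_spectra=spectra,
            flowering_dap=f_dap, harvest_maturity_dap=m_dap,
        ))
        truth_rows.append({
            "plant_id": cfg.plant_id, "node": node, "position": pos,
            "location": format_location(node, pos),
            "true_m_ir": true_m, "true_ci_ir": true_ci,
            "lint_mass_g": float(lint),
            "flowering_dap": f_dap, "maturation_dap": m_dap,
            "defoliation_impact": impact.value,
        })
    plant = PlantMap(plant_id=cfg.plant_id, bolls=bolls)
    return plant, pd.DataFrame(truth_rows)


def make_virtual_experiment(n_plants: int = 3, seed: int = 0,
                            cfg: Optional[VirtualPlantConfig] = None,
                            phen_cfg: Optional[phen.PhenologyConfig] = None,
                            ) -> Tuple[List[PlantMap], pd.DataFrame]:
    """Generate a multi-plant experiment (plants A, B, C, ... sharing one profile)."""
    base = cfg or VirtualPlantConfig()
    plants, truths = [], []
    for i in range(n_plants):
        pid = chr(ord("A") + i) if i < 26 else f"P{i}"
        pcfg = replace(base, seed=seed, plant_id=pid, plant_index=i)
        plant, truth = make_virtual_plant(pcfg, phen_cfg)
        plants.append(plant)
        truths.append(truth)
    return plants, pd.concat(truths, ignore_index=True)
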