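"""Synthetic per-cell spot tables under a 2-D nucleus model.

The nucleus is the unit disk (a microscopy projection).  Each physical
chromosome copy is modeled as an oriented territory: a segment with a
uniformly placed center and a uniformly random axis, whose targeted loci
sit at ordered axial positions (pter at one end, the pericentromere in the
middle, qter at the other end, ``arm_span`` apart) plus isotropic Gaussian
jitter (``territory_sd``).  This orientation is what makes a displaced
terminal signal — one far from any pericentromeric anchor of its own
chromosome — a detectable signature of translocation.  Loci belonging to a
fused group (a Robertsonian centromeric fusion) are co-placed within
``fusion_distance`` of each other.

Detection noise: each true signal is dropped with probability
``1 - p_detect``, duplicated ("split") with probability ``p_split`` (the
duplicate lands close enough to re-merge at extraction), and spurious spots
arrive per color as a Poisson count with mean ``background_rate`` at
uniform positions.

Unless disabled, true signals that do not share a fused group are
rejection-sampled to lie more than ``min_separation`` apart — the analyst's
practice of scoring only well-spread nuclei, and the condition under which
noise-free extraction recovers the expected pattern exactly in every cell.
Chance-colocalization studies set ``min_separation=None`` or use the uniform
territory mode (``territory_sd=inf``), where every locus position is i.i.d.
uniform in the disk.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .karyotype import KaryotypeSpec, parse_karyotype_spec
from .panel import Color, Hybridization, Panel, genome_units

__all__ = [
    "SimulationConfig",
    "CasePopulation",
    "SPOT_COLUMNS",
    "simulate_hybridization",
    "simulate_case",
    "write_spot_table",
    "read_spot_table",
    "hyb_rng",
]

SPOT_COLUMNS = ("cell_id", "hyb_id", "color", "x", "y")


@dataclass(frozen=True)
class SimulationConfig:
    """Nucleus-model and noise parameters (lengths in nucleus-radius units)."""

    n_cells: int = 20
    nucleus_radius: float = 1.0
    territory_sd: float = 0.03
    arm_span: float = 0.20
    fusion_distance: float = 0.10
    p_detect: float = 1.0
    p_split: float = 0.0
    background_rate: float = 0.0
    seed: int = 0
    min_separation: float | None = 0.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_detect <= 1.0 and 0.0 <= self.p_split <= 1.0):
            raise ValueError("p_detect and p_split must lie in [0, 1]")
        if self.fusion_distance >= self.nucleus_radius:
            raise ValueError("fusion_distance must be smaller than the nucleus radius")
        if self.territory_sd <= 0:
            raise ValueError("territory_sd must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")

    @property
    def uniform_territories(self) -> bool:
        return math.isinf(self.territory_sd)


@dataclass(frozen=True)
class CasePopulation:
    spec: KaryotypeSpec
    fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("population fraction must lie in [0, 1]")


def _as_populations(spec_or_populations) -> list[CasePopulation]:
    obj = spec_or_populations
    if isinstance(obj, str):
        obj = parse_karyotype_spec(obj)
    if isinstance(obj, KaryotypeSpec):
        return [CasePopulation(spec=obj, fraction=1.0)]
    pops = list(obj)
    if not pops:
        raise ValueError("at least one population required")
    out = []
    for p in pops:
        if not isinstance(p, CasePopulation):
            spec, frac = p
            if isinstance(spec, str):
                spec = parse_karyotype_spec(spec)
            p = CasePopulation(spec=spec, fraction=float(frac))
        out.append(p)
    total = sum(p.fraction for p in out)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"population fractions sum to {total}, expected 1")
    return out


def hyb_rng(seed: int, hyb_id: str) -> np.random.Generator:
    """Deterministic per-hybridization stream: CRC32 of the id spawns the
    substream, so reproducibility does not depend on iteration order."""
    key = zlib.crc32(hyb_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _uniform_disk(rng: np.random.Generator, radius: float) -> np.ndarray:
    r = radius * math.sqrt(rng.random())
    theta = rng.random() * 2.0 * math.pi
    return np.array([r * math.cos(theta), r * math.sin(theta)])


def _min_dist2(p: np.ndarray, others: list[np.ndarray]) -> float:
    if not others:
        return math.inf
    d = np.asarray(others) - p
    return float(np.min(np.einsum("ij,ij->i", d, d)))


def _axial_slots(unit) -> dict[int, float]:
    """Axial coordinate (in arm_span units) per locus index of one unit.

    pter loci sit at one end, the pericentromere at the middle, qter at the
    other end.  A derivative carrying two long (or two short) arms points
    them in opposite directions, as the physical chromosome does.
    """
    from .panel import LocusClass

    slots: dict[int, float] = {}
    p_sign, q_sign = -1.0, 1.0
    for i, (_, cls) in enumerate(unit.loci):
        if cls is LocusClass.CEN:
            slots[i] = 0.0
        elif cls is LocusClass.PTER:
            slots[i] = p_sign
            p_sign = -p_sign
        else:  # QTER (BAND targets are not simulated)
            slots[i] = q_sign
            q_sign = -q_sign
    return slots


def _place_cell(
    rng: np.random.Generator,
    units,
    index: dict,
    cfg: SimulationConfig,
) -> list[tuple[Color, float, float]]:
    """True-signal placement for one cell (before detection noise)."""
    R = cfg.nucleus_radius
    sep2 = None if cfg.min_separation is None else cfg.min_separation**2
    placed: list[np.ndarray] = []
    spots: list[tuple[Color, float, float]] = []

    for unit in units:
        matched = [
            (i, index[locus]) for i, locus in enumerate(unit.loci) if locus in index
        ]
        if not matched:
            continue
        groups = [g & {i for i, _ in matched} for g in unit.fused]
        groups = [g for g in groups if len(g) >= 2]
        grouped = set().union(*groups) if groups else set()

        if cfg.uniform_territories:
            # territory_sd -> inf: loci i.i.d. uniform; fused groups co-placed
            pts: dict[int, np.ndarray] = {}
            for g in groups:
                anchor = _uniform_disk(rng, R)
                for i in sorted(g):
                    pts[i] = _clip_disk(
                        anchor + _uniform_disk(rng, cfg.fusion_distance / 2.0), R
                    )
            for i, _ in matched:
                if i not in grouped:
                    pts[i] = _uniform_disk(rng, R)
            for i, color in matched:
                spots.append((color, *pts[i]))
                placed.append(pts[i])
            continue

        slots = _axial_slots(unit)
        for _attempt in range(200):
            center = _uniform_disk(rng, R)
            theta = rng.random() * 2.0 * math.pi
            axis = np.array([math.cos(theta), math.sin(theta)])
            pts = {}
            for g in groups:
                anchor_axial = min(slots[i] for i in g)
                anchor = (
                    center
                    + anchor_axial * cfg.arm_span * axis
                    + rng.normal(0.0, cfg.territory_sd, size=2)
                )
                for i in sorted(g):
                    pts[i] = anchor + _uniform_disk(rng, cfg.fusion_distance / 2.0)
            for i, _ in matched:
                if i not in grouped:
                    pts[i] = (
                        center
                        + slots[i] * cfg.arm_span * axis
                        + rng.normal(0.0, cfg.territory_sd, size=2)
                    )
            if any(float(p @ p) > R * R for p in pts.values()):
                continue
            if sep2 is None or _separated(pts, groups, placed, sep2):
                break
        else:
            # no admissible layout found; keep the last draw, clipped
            pts = {i: _clip_disk(p, R) for i, p in pts.items()}
        for i, color in matched:
            spots.append((color, *pts[i]))
            placed.append(pts[i])
    return spots


def _clip_disk(p: np.ndarray, radius: float) -> np.ndarray:
    norm = math.sqrt(p @ p)
    if norm <= radius:
        return p
    return p * (radius / norm)


def _separated(
    pts: dict[int, np.ndarray],
    groups: list[set[int]],
    placed: list[np.ndarray],
    sep2: float,
) -> bool:
    same_group = {}
    for gi, g in enumerate(groups):
        for i in g:
            same_group[i] = gi
    idx = list(pts)
    for a_pos, i in enumerate(idx):
        if _min_dist2(pts[i], placed) <= sep2:
            return False
        for j in idx[a_pos + 1 :]:
            if same_group.get(i, -1) == same_group.get(j, -2):
                continue
            d = pts[i] - pts[j]
            if float(d @ d) <= sep2:
                return False
    return True


def simulate_hybridization(
    populations,
    hyb: Hybridization,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one hybridization; returns a spot table DataFrame.

    Deterministic given (populations, hyb, config, seed).  Cell ids run
    densely from 1 to ``config.n_cells``; a cell whose signals all drop out
    simply contributes no rows.
    """
    pops = _as_populations(populations)
    if config.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if rng is None:
        rng = hyb_rng(config.seed, hyb.id)
    fractions = np.array([p.fraction for p in pops])
    units_by_pop = [genome_units(p.spec) for p in pops]
    index = hyb.target_index()
    split_r = config.fusion_distance / 4.0

    rows: list[tuple[int, str, str, float, float]] = []
    for cell_id in range(1, config.n_cells + 1):
        k = int(rng.choice(len(pops), p=fractions)) if len(pops) > 1 else 0
        true_spots = _place_cell(rng, units_by_pop[k], index, config)
        observed: list[tuple[Color, float, float]] = []
        for color, x, y in true_spots:
            if config.p_detect < 1.0 and rng.random() >= config.p_detect:
                continue
            observed.append((color, x, y))
            if config.p_split > 0.0 and rng.random() < config.p_split:
                dup = _clip_disk(
                    np.array([x, y]) + _uniform_disk(rng, split_r),
                    config.nucleus_radius,
                )
                observed.append((color, float(dup[0]), float(dup[1])))
        if config.background_rate > 0.0:
            for color in hyb.colors:
                for _ in range(rng.poisson(config.background_rate)):
                    p = _uniform_disk(rng, config.nucleus_radius)
                    observed.append((color, float(p[0]), float(p[1])))
        rows.extend(
            (cell_id, hyb.id, c.value, float(x), float(y)) for c, x, y in observed
        )
    return pd.DataFrame(rows, columns=list(SPOT_COLUMNS))


def simulate_case(
    spec_or_populations,
    panel: Panel,
    config: SimulationConfig,
) -> dict[str, pd.DataFrame]:
    """One spot table per hybridization, with per-hybridization seed streams."""
    pops = _as_populations(spec_or_populations)
    return {
        h.id: simulate_hybridization(pops, h, config, rng=hyb_rng(config.seed, h.id))
        for h in panel.hybridizations
    }


def write_spot_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_spot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spot table {path} missing columns {sorted(missing)}")
    return df
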