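"""Per-chromosome calling from >=20 cell patterns.

Rules implemented here mirror standard interphase-FISH scoring practice for
products of conception:

* copy number per target = modal per-cell cluster count of its color, with
  ties broken toward the diploid expectation of 2, then the smaller count;
* a secondary (mosaic) population requires at least ``mosaic_min_cells``
  cells (default 4) AND at least ``mosaic_min_fraction`` (default 20%) of
  cells — the "four of 20" rule, extended conservatively to other n;
* a two-color juxtaposition is abnormal only when seen in strictly more
  than ``fusion_cutoff`` (default 20%) of nuclei, so 4/20 is still normal;
* a terminal signal is "displaced" in a cell when no pericentromeric
  cluster of the same chromosome lies within ``displacement_radius``; a
  chromosome-level displacement call needs more than ``displacement_cutoff``
  of informative cells (see docs/methods.md for the choice of 0.40).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from scipy import stats

from .panel import Color, Hybridization, LocusClass
from .spotcall import CellPattern

__all__ = [
    "CallerConfig",
    "TargetCall",
    "FusionCall",
    "Interpretation",
    "ChromosomeCall",
    "call_copy_number",
    "call_fusion",
    "estimate_cutoff",
    "displaced_fraction",
    "call_chromosome",
    "interpret_chromosome",
    "refine_breakpoint",
]


@dataclass(frozen=True)
class CallerConfig:
    min_cells: int = 20
    mosaic_min_cells: int = 4
    mosaic_min_fraction: float = 0.20
    fusion_cutoff: float = 0.20  # strict: fraction must EXCEED this
    fusion_radius: float = 0.10
    displacement_radius: float = 0.30
    displacement_cutoff: float = 0.40

    def __post_init__(self) -> None:
        if self.mosaic_min_cells < 2:
            raise ValueError("mosaic_min_cells must be >= 2")
        if not (0.0 < self.fusion_cutoff < 1.0):
            raise ValueError("fusion_cutoff must lie strictly between 0 and 1")


@dataclass
class TargetCall:
    color: Color
    primary_copy_number: int
    secondary_copy_number: int | None
    secondary_fraction: float
    n_cells: int
    low_cell_warning: bool = False

    @property
    def is_mosaic(self) -> bool:
        return self.secondary_copy_number is not None


@dataclass
class FusionCall:
    color_pair: frozenset
    fraction: float
    abnormal: bool
    n_cells: int


class Interpretation(str, Enum):
    NORMAL = "NORMAL"
    GAIN = "GAIN"
    LOSS = "LOSS"
    TERMINAL_DEL_P = "TERMINAL_DEL_P"
    TERMINAL_DEL_Q = "TERMINAL_DEL_Q"
    FUSION = "FUSION"
    DISPLACED_TERMINAL = "DISPLACED_TERMINAL"
    MIXED = "MIXED"


@dataclass
class ChromosomeCall:
    chromosome: str
    n_cells: int
    target_calls: dict[str, TargetCall]  # keyed "pter" / "cen" / "qter"
    fusion_calls: list[FusionCall]
    displaced: dict[str, float]  # arm -> fraction of informative cells
    interpretation: Interpretation
    expected: int
    #: arm of an extra, unanchored terminal signal (ter > cen), if any
    extra_terminal: str | None = None
    #: arm of a missing terminal signal (ter < cen), if any
    lost_terminal: str | None = None
    #: arms whose displaced fraction exceeds the cutoff
    displaced_arms: tuple[str, ...] = ()
    #: (copy_number, fraction) secondary populations seen at the centromere
    mosaic_populations: list[tuple[int, float]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def _mode_pref2(counter: Counter) -> int:
    """Modal value; ties broken toward the count nearer 2, then smaller."""
    top = max(counter.values())
    candidates = [k for k, v in counter.items() if v == top]
    return min(candidates, key=lambda k: (abs(k - 2), k))


def call_copy_number(
    patterns: list[CellPattern], color: Color, config: CallerConfig
) -> TargetCall:
    if not patterns:
        raise ValueError("no cells to call")
    counts = Counter(p.count(color) for p in patterns)
    n = len(patterns)
    primary = _mode_pref2(counts)
    secondary = None
    sec_frac = 0.0
    others = {k: v for k, v in counts.items() if k != primary}
    if others:
        cand = max(others, key=lambda k: (others[k], -abs(k - 2), -k))
        if others[cand] >= config.mosaic_min_cells and others[cand] / n >= config.mosaic_min_fraction:
            secondary = cand
            sec_frac = others[cand] / n
    return TargetCall(
        color=color,
        primary_copy_number=primary,
        secondary_copy_number=secondary,
        secondary_fraction=sec_frac,
        n_cells=n,
        low_cell_warning=n < config.min_cells,
    )


def call_fusion(
    patterns: list[CellPattern], pair, config: CallerConfig
) -> FusionCall:
    if not patterns:
        raise ValueError("no cells to call")
    pair = frozenset(pair)
    if len(pair) != 2:
        raise ValueError("fusion pair must contain two distinct colors")
    n = len(patterns)
    fused = sum(1 for p in patterns if p.has_fusion(pair))
    fraction = fused / n
    return FusionCall(
        color_pair=pair,
        fraction=fraction,
        abnormal=fraction > config.fusion_cutoff,
        n_cells=n,
    )


def estimate_cutoff(
    normal_control_patterns: list[list[CellPattern]], confidence: float = 0.95
) -> float:
    """Laboratory normal cut-off from control samples.

    Returns the larger of (a) the maximum per-control fraction of cells
    showing any juxtaposition event and (b) the one-sided upper
    Clopper-Pearson confidence bound on the pooled fusion rate.
    """
    if not normal_control_patterns:
        raise ValueError("at least one control sample required")
    fracs = []
    fused_total = 0
    n_total = 0
    for control in normal_control_patterns:
        if not control:
            raise ValueError("empty control sample")
        fused = sum(1 for p in control if p.fusions)
        fracs.append(fused / len(control))
        fused_total += fused
        n_total += len(control)
    upper = float(stats.beta.ppf(confidence, fused_total + 1, n_total - fused_total))
    if math.isnan(upper):  # fused_total == n_total
        upper = 1.0
    return max(max(fracs), upper)


def displaced_fraction(
    patterns: list[CellPattern],
    terminal_color: Color,
    anchor_color: Color,
    radius: float,
) -> float:
    """Fraction of informative cells with a terminal cluster farther than
    ``radius`` from every anchor (pericentromeric) cluster.

    Cells without any anchor cluster are uninformative and excluded.
    """
    informative = 0
    displaced = 0
    for p in patterns:
        anchors = [c.centroid for c in p.clusters if anchor_color in c.colors]
        if not anchors:
            continue
        informative += 1
        terminals = [c.centroid for c in p.clusters if terminal_color in c.colors]
        for tx, ty in terminals:
            if all(
                (tx - ax) ** 2 + (ty - ay) ** 2 > radius * radius for ax, ay in anchors
            ):
                displaced += 1
                break
    return displaced / informative if informative else 0.0


def interpret_chromosome(
    target_calls: dict[str, TargetCall],
    fusion_calls: list[FusionCall],
    displaced: dict[str, float],
    config: CallerConfig,
    expected: int = 2,
) -> tuple[Interpretation, dict]:
    """Classify one chromosome's evidence relative to ``expected`` copies.

    Returns the interpretation plus structured details (extra/lost terminal
    arm, displaced arms) that genome assembly uses for pairing.
    """
    cen = target_calls["cen"].primary_copy_number
    ters = {
        arm: target_calls[key].primary_copy_number
        for arm, key in (("p", "pter"), ("q", "qter"))
        if key in target_calls
    }
    displaced_arms = tuple(
        arm for arm, frac in sorted(displaced.items()) if frac > config.displacement_cutoff
    )
    details: dict = {
        "extra_terminal": None,
        "lost_terminal": None,
        "displaced_arms": displaced_arms,
    }
    abnormal_fusion = any(f.abnormal for f in fusion_calls)

    uniform = all(t == cen for t in ters.values())
    if uniform:
        if abnormal_fusion:
            return Interpretation.FUSION, details
        if cen == expected:
            if displaced_arms:
                return Interpretation.DISPLACED_TERMINAL, details
            return Interpretation.NORMAL, details
        if displaced_arms:
            return Interpretation.MIXED, details
        return (Interpretation.GAIN if cen > expected else Interpretation.LOSS), details

    if cen == expected:
        lost = [arm for arm, t in ters.items() if t < cen]
        extra = [arm for arm, t in ters.items() if t > cen]
        if len(lost) == 1 and not extra:
            details["lost_terminal"] = lost[0]
            return (
                Interpretation.TERMINAL_DEL_P
                if lost[0] == "p"
                else Interpretation.TERMINAL_DEL_Q
            ), details
        if len(extra) == 1 and not lost:
            details["extra_terminal"] = extra[0]
            return Interpretation.DISPLACED_TERMINAL, details
    return Interpretation.MIXED, details


def call_chromosome(
    patterns: list[CellPattern],
    hyb: Hybridization,
    chromosome: str,
    config: CallerConfig,
    expected: int = 2,
) -> ChromosomeCall:
    """Full per-chromosome call for a single-chromosome hybridization."""
    cmap = hyb.color_map(chromosome)
    keys = {"cen": cmap[LocusClass.CEN]}
    if LocusClass.PTER in cmap:
        keys["pter"] = cmap[LocusClass.PTER]
    keys["qter"] = cmap[LocusClass.QTER]
    target_calls = {
        key: call_copy_number(patterns, color, config) for key, color in keys.items()
    }
    pairs = set()
    fusion_calls = []
    colors = list(keys.values())
    for i, a in enumerate(colors):
        for b in colors[i + 1 :]:
            pair = frozenset((a, b))
            if len(pair) == 2 and pair not in pairs:
                pairs.add(pair)
                fusion_calls.append(call_fusion(patterns, pair, config))
    displaced = {}
    anchor = keys["cen"]
    if "pter" in keys:
        displaced["p"] = displaced_fraction(
            patterns, keys["pter"], anchor, config.displacement_radius
        )
    displaced["q"] = displaced_fraction(
        patterns, keys["qter"], anchor, config.displacement_radius
    )
    interp, details = interpret_chromosome(
        target_calls, fusion_calls, displaced, config, expected
    )
    cen_call = target_calls["cen"]
    mosaic = (
        [(cen_call.secondary_copy_number, cen_call.secondary_fraction)]
        if cen_call.is_mosaic
        else []
    )
    flags = []
    if cen_call.low_cell_warning:
        flags.append(f"chr{chromosome}: fewer than {config.min_cells} cells analyzed")
    return ChromosomeCall(
        chromosome=chromosome,
        n_cells=len(patterns),
        target_calls=target_calls,
        fusion_calls=fusion_calls,
        displaced=displaced,
        interpretation=interp,
        expected=expected,
        extra_terminal=details["extra_terminal"],
        lost_terminal=details["lost_terminal"],
        displaced_arms=details["displaced_arms"],
        mosaic_populations=mosaic,
        flags=flags,
    )


def refine_breakpoint(
    ordered_band_presence: list[tuple[str, bool]],
) -> tuple[str | None, str] | None:
    """Locate a terminal breakpoint on one arm from ordered band presence.

    Bands are ordered centromere -> telomere.  Returns ``(last_present,
    first_absent)`` delimiting the half-open interval containing the break,
    ``None`` when every band is present, and ``(None, first_band)`` when the
    whole arm is absent.
    """
    if not ordered_band_presence:
        raise ValueError("empty band list")
    labels = [b for b, _ in ordered_band_presence]
    present = [p for _, p in ordered_band_presence]
    if present[-1]:
        return None
    j = len(present)
    while j > 0 and not present[j - 1]:
        j -= 1
    return (labels[j - 1] if j > 0 else None, labels[j])
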