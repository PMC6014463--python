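"""Probe panels and noise-free expected signal patterns.

Two built-in panels model the standard product-of-conception design:

* **Standard Resolution** — 23 hybridizations, one per autosome plus a joint
  X/Y hybridization.  Every non-acrocentric autosome and the X carry a green
  subtelomeric p (pter), yellow pericentromeric (cen) and red subtelomeric q
  (qter) target.  Acrocentrics (13, 14, 15, 21, 22) have no p-arm target.
  The Y is distinguished by an aqua pter target.
* **Acrocentric** — a single hybridization with one pericentromeric target
  per acrocentric chromosome in five distinct colors (13 yellow, 14 green,
  15 red, 21 aqua, 22 far red), used to detect Robertsonian translocations
  as consistently fused two-color signals.

:func:`expected_pattern` computes the signal pattern (per-color cluster
counts plus fusion events) any :class:`~icpkit.karyotype.KaryotypeSpec`
produces under a given hybridization, noise-free.  It is the ground truth
for the simulator and the oracle for end-to-end recovery tests.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .karyotype import (
    ACROCENTRICS,
    AUTOSOMES,
    CHROM_ORDER,
    CHROMOSOMES,
    EventKind,
    KaryotypeError,
    KaryotypeSpec,
    StructuralEvent,
    parse_karyotype_spec,
    render_karyotype_spec,
    strip_icp_decorations,
)

__all__ = [
    "Color",
    "LocusClass",
    "ProbeTarget",
    "Hybridization",
    "Panel",
    "SignalPattern",
    "build_standard_panel",
    "build_acrocentric_panel",
    "build_full_panel",
    "expected_pattern",
    "genome_units",
    "parse_karyotype_spec",
    "render_karyotype_spec",
    "KaryotypeSpec",
    "StructuralEvent",
    "EventKind",
    "KaryotypeError",
    "ACRO_CEN_COLORS",
]


class Color(str, Enum):
    AQUA = "AQUA"
    GREEN = "GREEN"
    YELLOW = "YELLOW"
    RED = "RED"
    FARRED = "FARRED"


class LocusClass(str, Enum):
    PTER = "PTER"
    CEN = "CEN"
    QTER = "QTER"
    BAND = "BAND"


#: Acrocentric-mix pericentromeric color per chromosome.
ACRO_CEN_COLORS: dict[str, Color] = {
    "13": Color.YELLOW,
    "14": Color.GREEN,
    "15": Color.RED,
    "21": Color.AQUA,
    "22": Color.FARRED,
}
ACRO_COLOR_CHROM: dict[Color, str] = {v: k for k, v in ACRO_CEN_COLORS.items()}


@dataclass(frozen=True)
class ProbeTarget:
    chromosome: str
    arm: str  # "p", "q" or "cen"
    locus_class: LocusClass
    color: Color
    band_label: str = ""

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(f"unknown chromosome {self.chromosome!r}")
        if self.locus_class is LocusClass.BAND and not self.band_label:
            raise ValueError("BAND target requires a band_label")

    @property
    def key(self) -> tuple[str, LocusClass, str]:
        return (self.chromosome, self.locus_class, self.band_label)


@dataclass(frozen=True)
class Hybridization:
    id: str
    targets: tuple[ProbeTarget, ...]

    def __post_init__(self) -> None:
        keys = [t.key for t in self.targets]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate probe targets in hybridization {self.id!r}")

    @property
    def chromosomes_covered(self) -> frozenset[str]:
        return frozenset(t.chromosome for t in self.targets)

    @property
    def colors(self) -> tuple[Color, ...]:
        seen: list[Color] = []
        for t in self.targets:
            if t.color not in seen:
                seen.append(t.color)
        return tuple(seen)

    def color_map(self, chromosome: str) -> dict[LocusClass, Color]:
        return {
            t.locus_class: t.color for t in self.targets if t.chromosome == chromosome
        }

    def target_index(self) -> dict[tuple[str, LocusClass], Color]:
        return {(t.chromosome, t.locus_class): t.color for t in self.targets}


@dataclass(frozen=True)
class Panel:
    name: str
    hybridizations: tuple[Hybridization, ...]

    def hyb_for(self, chromosome: str) -> Hybridization:
        for h in self.hybridizations:
            if chromosome in h.chromosomes_covered:
                return h
        raise KeyError(f"no hybridization covers chromosome {chromosome!r}")

    def __getitem__(self, hyb_id: str) -> Hybridization:
        for h in self.hybridizations:
            if h.id == hyb_id:
                return h
        raise KeyError(hyb_id)

    # JSON round-trip ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "hybridizations": [
                {
                    "id": h.id,
                    "targets": [
                        {
                            "chromosome": t.chromosome,
                            "arm": t.arm,
                            "locus_class": t.locus_class.value,
                            "band_label": t.band_label,
                            "color": t.color.value,
                        }
                        for t in h.targets
                    ],
                }
                for h in self.hybridizations
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "Panel":
        hybs = tuple(
            Hybridization(
                id=h["id"],
                targets=tuple(
                    ProbeTarget(
                        chromosome=t["chromosome"],
                        arm=t["arm"],
                        locus_class=LocusClass(t["locus_class"]),
                        color=Color(t["color"]),
                        band_label=t.get("band_label", ""),
                    )
                    for t in h["targets"]
                ),
            )
            for h in d["hybridizations"]
        )
        return cls(name=d["name"], hybridizations=hybs)

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "Panel":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text_or_path).read_text()
        return cls.from_dict(json.loads(text))


def _standard_targets(chromosome: str) -> tuple[ProbeTarget, ...]:
    cen = ProbeTarget(chromosome, "cen", LocusClass.CEN, Color.YELLOW)
    qter = ProbeTarget(chromosome, "q", LocusClass.QTER, Color.RED)
    if chromosome in ACROCENTRICS:
        return (cen, qter)
    pter_color = Color.AQUA if chromosome == "Y" else Color.GREEN
    pter = ProbeTarget(chromosome, "p", LocusClass.PTER, pter_color)
    return (pter, cen, qter)


def build_standard_panel() -> Panel:
    """Standard Resolution panel: 23 hybridizations covering all 24 types."""
    hybs = [
        Hybridization(id=f"chr{c}", targets=_standard_targets(c)) for c in AUTOSOMES
    ]
    hybs.append(
        Hybridization(id="chrXY", targets=_standard_targets("X") + _standard_targets("Y"))
    )
    return Panel(name="standard", hybridizations=tuple(hybs))


def build_acrocentric_panel() -> Panel:
    """Acrocentric mix: one hybridization, five pericentromeric targets."""
    targets = tuple(
        ProbeTarget(c, "cen", LocusClass.CEN, ACRO_CEN_COLORS[c])
        for c in sorted(ACROCENTRICS, key=CHROM_ORDER.get)
    )
    return Panel(name="acrocentric", hybridizations=(Hybridization("acro", targets),))


def build_full_panel() -> Panel:
    """Standard panel plus the acrocentric mix as a 24th hybridization.

    This is the workflow actually run on a case: each chromosome individually
    plus the Robertsonian screen in a separate analysis.
    """
    std = build_standard_panel()
    acro = build_acrocentric_panel()
    return Panel(
        name="standard+acrocentric",
        hybridizations=std.hybridizations + acro.hybridizations,
    )


# ---------------------------------------------------------------------------
# expected noise-free pattern


@dataclass
class SignalPattern:
    """Per-cell signal multiset: color cluster counts plus fusion events."""

    color_counts: dict[Color, int]
    fusions: Counter  # Counter[frozenset[Color]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalPattern):
            return NotImplemented
        mine = {c: n for c, n in self.color_counts.items() if n}
        theirs = {c: n for c, n in other.color_counts.items() if n}
        return mine == theirs and self.fusions == other.fusions

    def total_spots(self) -> int:
        return sum(self.color_counts.values())


@dataclass
class _Unit:
    """One physical chromosome: its targetable loci and fused locus groups."""

    loci: list[tuple[str, LocusClass]]
    fused: list[set[int]] = field(default_factory=list)

    def has(self, locus: tuple[str, LocusClass]) -> bool:
        return locus in self.loci


def _normal_unit(chromosome: str) -> _Unit:
    loci: list[tuple[str, LocusClass]] = []
    if chromosome not in ACROCENTRICS:
        loci.append((chromosome, LocusClass.PTER))
    loci.append((chromosome, LocusClass.CEN))
    loci.append((chromosome, LocusClass.QTER))
    return _Unit(loci=loci)


def _ter(arm: str) -> LocusClass:
    if arm == "p":
        return LocusClass.PTER
    if arm in ("q", "?"):
        return LocusClass.QTER
    raise KaryotypeError(f"cannot place terminal locus for arm {arm!r}")


def _take_unit(units: list[_Unit], chromosome: str, needs: tuple[str, LocusClass] | None = None) -> _Unit:
    for u in units:
        if (chromosome, LocusClass.CEN) in u.loci and not u.fused:
            if needs is None or u.has(needs):
                return u
    raise KaryotypeError(f"no intact copy of chromosome {chromosome} left to rearrange")


def genome_units(spec: KaryotypeSpec) -> list[_Unit]:
    """Expand a karyotype into physical chromosome units.

    Each unit later receives one chromosome-territory center in the nucleus
    model; loci in a fused group are constrained to colocalize.
    """
    units: list[_Unit] = []
    for c in AUTOSOMES:
        copies = spec.base_ploidy + spec.gains.count(c) - spec.losses.count(c)
        units.extend(_normal_unit(c) for _ in range(copies))
    for s in spec.sex[0]:
        units.append(_normal_unit(s))
    for c in spec.gains:
        if c in ("X", "Y"):
            units.append(_normal_unit(c))
    for c in spec.losses:
        if c in ("X", "Y"):
            units.remove(next(u for u in units if (c, LocusClass.CEN) in u.loci))

    for ev in spec.events:
        if ev.kind is EventKind.TERMINAL_DELETION:
            c, arm = ev.participants[0]
            u = _take_unit(units, c, needs=(c, _ter(arm)))
            u.loci.remove((c, _ter(arm)))
        elif ev.kind is EventKind.ROBERTSONIAN:
            (a, _), (b, _) = ev.participants
            units.remove(_take_unit(units, a))
            units.remove(_take_unit(units, b))
            der = _Unit(
                loci=[
                    (a, LocusClass.CEN),
                    (b, LocusClass.CEN),
                    (a, LocusClass.QTER),
                    (b, LocusClass.QTER),
                ],
                fused=[{0, 1}],
            )
            units.append(der)
            if ev.extra_copy_of is not None:
                units.append(_normal_unit(ev.extra_copy_of))
        elif ev.kind is EventKind.RECIPROCAL_TRANSLOCATION:
            (a, arm_a), (b, arm_b) = ev.participants
            ua = _take_unit(units, a, needs=(a, _ter(arm_a)))
            ua.loci.remove((a, _ter(arm_a)))
            ub = _take_unit(units, b, needs=(b, _ter(arm_b)))
            ub.loci.remove((b, _ter(arm_b)))
            # each derivative carries the partner's displaced terminal
            ua.loci.append((b, _ter(arm_b)))
            ub.loci.append((a, _ter(arm_a)))
        elif ev.kind is EventKind.UNBALANCED_DER:
            partner, kept = (
                (ev.participants[0], ev.participants[1])
                if ev.participants[1][0] == ev.der_of
                else (ev.participants[1], ev.participants[0])
            )
            (pa, parm), (ka, karm) = partner, kept
            u = _take_unit(units, ka, needs=(ka, _ter(karm)))
            u.loci.remove((ka, _ter(karm)))
            u.loci.append((pa, _ter(parm)))
        else:  # pragma: no cover - enum is closed
            raise KaryotypeError(f"unhandled event kind {ev.kind}")
    return units


def expected_pattern(spec: KaryotypeSpec, hyb: Hybridization) -> SignalPattern:
    """Noise-free per-cell signal pattern of ``spec`` under ``hyb``."""
    index = hyb.target_index()
    counts: dict[Color, int] = {c: 0 for c in hyb.colors}
    fusions: Counter = Counter()
    for unit in genome_units(spec):
        matched = [(i, index[locus]) for i, locus in enumerate(unit.loci) if locus in index]
        for _, color in matched:
            counts[color] += 1
        for group in unit.fused:
            colors = frozenset(color for i, color in matched if i in group)
            if len(colors) >= 2:
                fusions[colors] += 1
    return SignalPattern(color_counts=counts, fusions=fusions)
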