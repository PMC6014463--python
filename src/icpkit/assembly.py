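"""Genome-wide assembly of per-hybridization calls into a molecular karyotype.

The assembler consumes per-cell patterns from every hybridization of a case
and produces a :class:`GenomeCall`:

1. infer the baseline copy number (ploidy) as the modal pericentromeric
   count across autosomes;
2. infer the sex complement from the joint X/Y hybridization (Y copies from
   the aqua pter count, X copies from the shared pericentromeric count
   minus Y);
3. detect Robertsonian translocations from abnormal two-color fusions on
   the acrocentric mix, classifying them balanced/unbalanced from the
   participants' totals and consuming the corresponding whole-chromosome
   gain so the same evidence is never reported twice;
4. pair terminal losses with displaced extra terminals into unbalanced
   derivatives, and displaced-but-balanced chromosomes into reciprocal
   translocations (fewest-event pairing, ascending-chromosome tie-break);
5. assemble mosaic populations (whole-genome ploidy mosaics, sex-discordant
   populations such as maternal cell admixture, single-chromosome mosaics);
6. render the result in icp. nomenclature with a ``[cpN]`` suffix, N being
   the smallest number of cells analyzed in any hybridization.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .chromcall import (
    CallerConfig,
    ChromosomeCall,
    FusionCall,
    Interpretation,
    call_chromosome,
    call_copy_number,
    call_fusion,
)
from .karyotype import (
    ACROCENTRICS,
    AUTOSOMES,
    CHROM_ORDER,
    EventKind,
    KaryotypeError,
    KaryotypeSpec,
    StructuralEvent,
    parse_karyotype_spec,
    strip_icp_decorations,
)
from .panel import ACRO_COLOR_CHROM, Color, LocusClass, Panel
from .spotcall import CellPattern, extract_patterns

__all__ = [
    "Ploidy",
    "GenomeCall",
    "infer_ploidy",
    "infer_sex",
    "detect_robertsonian",
    "pair_translocations",
    "detect_mcc",
    "call_genome",
    "karyotype_case",
    "to_icp_string",
    "parse_icp_string",
    "classify_abnormal",
]


class Ploidy(str, Enum):
    DIPLOID = "DIPLOID"
    TRIPLOID = "TRIPLOID"
    TETRAPLOID = "TETRAPLOID"
    OTHER = "OTHER"


_PLOIDY_BY_BASELINE = {2: Ploidy.DIPLOID, 3: Ploidy.TRIPLOID, 4: Ploidy.TETRAPLOID}


@dataclass
class GenomeCall:
    """Assembled molecular karyotype for one case."""

    chromosome_count: int
    ploidy: Ploidy
    sex_complement: str
    populations: list[tuple[KaryotypeSpec, float | None]]
    cells_analyzed: dict[str, int]
    icp_string: str
    flags: list[str] = field(default_factory=list)
    chromosome_calls: dict[str, ChromosomeCall] = field(default_factory=dict)

    @property
    def primary(self) -> KaryotypeSpec:
        return self.populations[0][0]

    def to_dict(self) -> dict:
        return {
            "icp_string": self.icp_string,
            "chromosome_count": self.chromosome_count,
            "ploidy": self.ploidy.value,
            "sex": self.sex_complement,
            "populations": [
                {"karyotype": spec.render(), "fraction": frac}
                for spec, frac in self.populations
            ],
            "cells_analyzed": dict(self.cells_analyzed),
            "flags": list(self.flags),
            "aberrations": [
                {
                    "kind": ev.kind.value,
                    "participants": [list(p) for p in ev.participants],
                    "balanced": ev.balanced,
                    "extra_copy_of": ev.extra_copy_of,
                    "der_of": ev.der_of,
                }
                for ev in self.primary.events
            ]
            + [{"kind": "GAIN", "chromosome": c} for c in self.primary.gains]
            + [{"kind": "LOSS", "chromosome": c} for c in self.primary.losses],
        }


# ---------------------------------------------------------------------------


def infer_ploidy(chromosome_calls: dict[str, ChromosomeCall]) -> tuple[Ploidy, int]:
    """Baseline copy number = modal pericentromeric primary across autosomes."""
    cens = [
        call.target_calls["cen"].primary_copy_number
        for c, call in chromosome_calls.items()
        if c in AUTOSOMES
    ]
    if len(cens) < 2:
        raise ValueError("ploidy inference needs calls for at least two autosomes")
    counts = Counter(cens)
    top = max(counts.values())
    baseline = min((k for k, v in counts.items() if v == top), key=lambda k: (abs(k - 2), k))
    return _PLOIDY_BY_BASELINE.get(baseline, Ploidy.OTHER), baseline


def infer_sex(
    xy_patterns: list[CellPattern], config: CallerConfig, baseline: int = 2
) -> tuple[str, list[StructuralEvent], list[str]]:
    """Sex complement from the joint X/Y hybridization.

    Y copies come from the aqua (Yp) count; X copies from the shared
    pericentromeric (yellow) count minus Y, so a terminal X deletion cannot
    corrupt the X count.  A green (Xp) or red (q) deficit relative to the
    inferred complement becomes a terminal-deletion event; surpluses and
    other inconsistencies are flagged, not fatal.
    """
    aqua = call_copy_number(xy_patterns, Color.AQUA, config)
    yellow = call_copy_number(xy_patterns, Color.YELLOW, config)
    green = call_copy_number(xy_patterns, Color.GREEN, config)
    red = call_copy_number(xy_patterns, Color.RED, config)

    n_y = aqua.primary_copy_number
    n_x = max(yellow.primary_copy_number - n_y, 0)
    flags: list[str] = []
    events: list[StructuralEvent] = []
    if n_x == 0 and n_y == 0:
        flags.append("X/Y hybridization shows no sex chromosomes; defaulting to X")
        n_x = max(green.primary_copy_number, 1)
    sex = "X" * n_x + "Y" * n_y

    if green.primary_copy_number < n_x:
        events.append(
            StructuralEvent(EventKind.TERMINAL_DELETION, (("X", "p"),), balanced=False)
        )
    elif green.primary_copy_number > n_x:
        flags.append(
            f"X pter count {green.primary_copy_number} exceeds inferred X copies {n_x}"
        )
    expected_q = n_x + n_y
    if red.primary_copy_number < expected_q:
        target = "X" if n_x > 0 else "Y"
        if n_x > 0 and n_y > 0:
            flags.append("qter deficit on the joint X/Y hybridization; assigned to X")
        events.append(
            StructuralEvent(EventKind.TERMINAL_DELETION, ((target, "q"),), balanced=False)
        )
    elif red.primary_copy_number > expected_q:
        flags.append(
            f"X/Y qter count {red.primary_copy_number} exceeds sex complement {sex}"
        )
    return sex, events, flags


def detect_mcc(
    xy_patterns: list[CellPattern], config: CallerConfig
) -> tuple[str, float] | None:
    """Two sex-discordant cell classes on the X/Y hybridization.

    Splits cells by presence of the aqua (Yp) signal; when both classes meet
    the mosaic rule the minority class is returned as ``(sex, fraction)``.
    The caller cannot designate which class is fetal.
    """
    n = len(xy_patterns)
    if n == 0:
        return None
    with_y = [p for p in xy_patterns if p.count(Color.AQUA) > 0]
    without_y = [p for p in xy_patterns if p.count(Color.AQUA) == 0]
    minority = min(with_y, without_y, key=len)
    k = len(minority)
    if k >= config.mosaic_min_cells and k / n >= config.mosaic_min_fraction and k < n:
        yellow = call_copy_number(minority, Color.YELLOW, config)
        aqua = call_copy_number(minority, Color.AQUA, config)
        n_y = aqua.primary_copy_number
        n_x = max(yellow.primary_copy_number - n_y, 0)
        return ("X" * n_x + "Y" * n_y, k / n)
    return None


def detect_robertsonian(
    acro_patterns: list[CellPattern], config: CallerConfig, baseline: int = 2
) -> tuple[list[StructuralEvent], list[FusionCall], dict[str, int], list[str]]:
    """Robertsonian events from the acrocentric-mix hybridization.

    Every abnormal pairwise fusion yields one event; the event is unbalanced
    (with ``extra_copy_of``) when exactly one participant's total count
    exceeds the baseline.  Fusions joining more than two colors are flagged
    for review rather than auto-resolved.
    """
    colors = sorted(ACRO_COLOR_CHROM, key=lambda c: CHROM_ORDER[ACRO_COLOR_CHROM[c]])
    totals = {
        ACRO_COLOR_CHROM[color]: call_copy_number(
            acro_patterns, color, config
        ).primary_copy_number
        for color in colors
    }
    fusion_calls: list[FusionCall] = []
    events: list[StructuralEvent] = []
    flags: list[str] = []

    multi = sum(1 for p in acro_patterns for fs in p.fusions if len(fs) > 2)
    if multi / max(len(acro_patterns), 1) > config.fusion_cutoff:
        flags.append("fusion joining more than two acrocentric signals; not auto-resolved")

    for i, ca in enumerate(colors):
        for cb in colors[i + 1 :]:
            fc = call_fusion(acro_patterns, (ca, cb), config)
            fusion_calls.append(fc)
            if not fc.abnormal:
                continue
            a, b = sorted(
                (ACRO_COLOR_CHROM[ca], ACRO_COLOR_CHROM[cb]), key=CHROM_ORDER.get
            )
            over = [c for c in (a, b) if totals[c] > baseline]
            extra = over[0] if len(over) == 1 else None
            if len(over) > 1:
                flags.append(
                    f"both Robertsonian participants {a};{b} exceed baseline; "
                    "reported balanced with the gains left free"
                )
            events.append(
                StructuralEvent(
                    EventKind.ROBERTSONIAN,
                    ((a, "q"), (b, "q")),
                    balanced=extra is None,
                    extra_copy_of=extra,
                )
            )
    return events, fusion_calls, totals, flags


def pair_translocations(
    losses: list[tuple[str, str]],
    extras: list[tuple[str, str]],
    displaced_balanced: list[tuple[str, str]],
) -> tuple[list[StructuralEvent], list[str]]:
    """Fewest-event pairing of terminal-rearrangement evidence.

    ``losses`` are (chromosome, arm) with a missing terminal signal,
    ``extras`` carry a surplus displaced terminal, ``displaced_balanced``
    have normal counts but a displaced terminal.  Each loss+extra pair is an
    unbalanced derivative der(B)t(A;B); displaced-balanced chromosomes pair
    among themselves into balanced reciprocal translocations.  Unpaired
    losses remain terminal deletions; other leftovers are flagged.
    """
    events: list[StructuralEvent] = []
    flags: list[str] = []
    key = lambda t: CHROM_ORDER[t[0]]
    losses = sorted(losses, key=key)
    extras = sorted(extras, key=key)
    displaced_balanced = sorted(displaced_balanced, key=key)

    if losses and extras and (len(losses) > 1 or len(extras) > 1):
        flags.append(
            "multiple terminal gain/loss pairings possible; "
            "paired in ascending chromosome order"
        )
    while losses and extras:
        b, arm_b = losses.pop(0)
        a, arm_a = extras.pop(0)
        participants = tuple(
            sorted(((a, arm_a), (b, arm_b)), key=lambda t: CHROM_ORDER[t[0]])
        )
        events.append(
            StructuralEvent(
                EventKind.UNBALANCED_DER, participants, balanced=False, der_of=b
            )
        )
    for c, arm in losses:
        events.append(
            StructuralEvent(EventKind.TERMINAL_DELETION, ((c, arm),), balanced=False)
        )
    for c, arm in extras:
        flags.append(f"unplaced extra terminal signal on {c}{arm}; no matching loss")

    while len(displaced_balanced) >= 2:
        a, arm_a = displaced_balanced.pop(0)
        b, arm_b = displaced_balanced.pop(0)
        events.append(
            StructuralEvent(
                EventKind.RECIPROCAL_TRANSLOCATION,
                ((a, arm_a), (b, arm_b)),
                balanced=True,
            )
        )
    for c, arm in displaced_balanced:
        flags.append(f"displaced terminal on {c}{arm} with no partner; not assembled")
    return events, flags


# ---------------------------------------------------------------------------


def call_genome(
    patterns_by_hyb: dict[str, list[CellPattern]],
    panel: Panel,
    config: CallerConfig | None = None,
) -> GenomeCall:
    """Assemble every hybridization's patterns into one GenomeCall."""
    config = config or CallerConfig()
    flags: list[str] = []
    autosome_calls: dict[str, ChromosomeCall] = {}
    xy_patterns: list[CellPattern] | None = None
    acro_patterns: list[CellPattern] | None = None

    for hyb in panel.hybridizations:
        patterns = patterns_by_hyb.get(hyb.id)
        if patterns is None:
            continue
        covered = hyb.chromosomes_covered
        if covered == {"X", "Y"}:
            xy_patterns = patterns
        elif covered <= ACROCENTRICS and len(covered) == 5:
            acro_patterns = patterns
        elif len(covered) == 1:
            (chrom,) = covered
            autosome_calls[chrom] = call_chromosome(patterns, hyb, chrom, config)
        else:
            flags.append(f"hybridization {hyb.id}: unsupported chromosome mix; skipped")

    if not autosome_calls:
        raise ValueError("no autosomal hybridizations to assemble")

    ploidy, baseline = infer_ploidy(autosome_calls)
    if len(autosome_calls) < 20:
        flags.append(
            f"only {len(autosome_calls)} autosomes analyzed; ploidy inference is partial"
        )

    # re-interpret each autosome against the genome baseline
    for chrom, call in list(autosome_calls.items()):
        if call.expected != baseline:
            hyb = panel.hyb_for(chrom)
            autosome_calls[chrom] = call_chromosome(
                patterns_by_hyb[hyb.id], hyb, chrom, config, expected=baseline
            )

    if xy_patterns is not None:
        sex, sex_events, sex_flags = infer_sex(xy_patterns, config, baseline)
        flags.extend(sex_flags)
    else:
        sex, sex_events = "XX", []
        flags.append("no X/Y hybridization; sex complement defaulted to XX")

    gains: list[str] = []
    loss_list: list[str] = []
    term_losses: list[tuple[str, str]] = []
    term_extras: list[tuple[str, str]] = []
    disp_balanced: list[tuple[str, str]] = []
    for chrom in sorted(autosome_calls, key=CHROM_ORDER.get):
        call = autosome_calls[chrom]
        interp = call.interpretation
        if interp is Interpretation.GAIN:
            gains.extend([chrom] * (call.target_calls["cen"].primary_copy_number - baseline))
        elif interp is Interpretation.LOSS:
            loss_list.extend([chrom] * (baseline - call.target_calls["cen"].primary_copy_number))
        elif interp in (Interpretation.TERMINAL_DEL_P, Interpretation.TERMINAL_DEL_Q):
            term_losses.append((chrom, call.lost_terminal))
        elif interp is Interpretation.DISPLACED_TERMINAL:
            if call.extra_terminal is not None:
                term_extras.append((chrom, call.extra_terminal))
            else:
                arm = call.displaced_arms[0] if call.displaced_arms else "q"
                disp_balanced.append((chrom, arm))
        elif interp is Interpretation.MIXED:
            flags.append(f"chr{chrom}: conflicting evidence retained as MIXED")
        for f in call.flags:
            flags.append(f)

    events: list[StructuralEvent] = list(sex_events)

    if acro_patterns is not None:
        rob_events, _, _, rob_flags = detect_robertsonian(acro_patterns, config, baseline)
        flags.extend(rob_flags)
        for ev in rob_events:
            if ev.extra_copy_of is not None and ev.extra_copy_of in gains:
                gains.remove(ev.extra_copy_of)  # consumed by the derivative
            events.append(ev)

    pair_events, pair_flags = pair_translocations(term_losses, term_extras, disp_balanced)
    events.extend(pair_events)
    flags.extend(pair_flags)

    primary = KaryotypeSpec(
        base_ploidy=baseline,
        sex=(sex,),
        gains=tuple(gains),
        losses=tuple(loss_list),
        events=tuple(events),
    )

    populations = _assemble_populations(
        primary, autosome_calls, xy_patterns, baseline, config, flags
    )

    cells = {
        hyb_id: len(patterns) for hyb_id, patterns in patterns_by_hyb.items()
    }
    cp = min(cells.values()) if cells else 0
    icp = to_icp_string(populations, cp=cp)
    return GenomeCall(
        chromosome_count=primary.chromosome_count,
        ploidy=ploidy,
        sex_complement=sex,
        populations=populations,
        cells_analyzed=cells,
        icp_string=icp,
        flags=flags,
        chromosome_calls=autosome_calls,
    )


def _assemble_populations(
    primary: KaryotypeSpec,
    autosome_calls: dict[str, ChromosomeCall],
    xy_patterns: list[CellPattern] | None,
    baseline: int,
    config: CallerConfig,
    flags: list[str],
) -> list[tuple[KaryotypeSpec, float | None]]:
    """Mosaic composition: ploidy mosaics, sex-discordant populations, and
    single-chromosome mosaics, in that order of precedence."""
    # Whole-genome ploidy mosaic: the same two copy numbers {baseline, k2} on
    # most autosomes.  A hybridization where the minority class happened to
    # reach a per-hybridization majority is "flipped" (primary k2, secondary
    # baseline); its apparent gains/losses belong to the mosaic, not the
    # primary clone.
    sec = Counter()
    sec_fracs: dict[int, list[float]] = {}
    flipped: dict[int, list[str]] = {}
    for chrom, call in autosome_calls.items():
        for k2c, frac in call.mosaic_populations:
            prim = call.target_calls["cen"].primary_copy_number
            if prim == baseline and k2c != baseline:
                sec[k2c] += 1
                sec_fracs.setdefault(k2c, []).append(frac)
            elif k2c == baseline and prim != baseline:
                sec[prim] += 1
                sec_fracs.setdefault(prim, []).append(1.0 - frac)
                flipped.setdefault(prim, []).append(chrom)
    if sec:
        k2, support = sec.most_common(1)[0]
        if support >= max(len(autosome_calls) // 2, 2) and k2 != baseline:
            fracs = sorted(sec_fracs[k2])
            frac = fracs[len(fracs) // 2]
            delta = k2 - baseline
            gains1 = list(primary.gains)
            losses1 = list(primary.losses)
            for chrom in flipped.get(k2, []):
                for _ in range(abs(delta)):
                    bucket = gains1 if delta > 0 else losses1
                    if chrom in bucket:
                        bucket.remove(chrom)
            primary = KaryotypeSpec(
                base_ploidy=baseline,
                sex=primary.sex,
                gains=tuple(gains1),
                losses=tuple(losses1),
                events=primary.events,
            )
            sex1 = primary.sex[0]
            if k2 % baseline == 0:
                sex2 = sex1 * (k2 // baseline)
            elif baseline % k2 == 0 and len(sex1) % (baseline // k2) == 0:
                sex2 = sex1[: len(sex1) // (baseline // k2)]
            else:
                sex2 = sex1
            second = KaryotypeSpec(base_ploidy=k2, sex=(sex2,))
            pops = [(primary, 1.0 - frac), (second, frac)]
            return sorted(pops, key=lambda p: p[0].is_normal())

    mcc = detect_mcc(xy_patterns, config) if xy_patterns is not None else None

    # single-chromosome mosaics (secondary population on one or two autosomes)
    chrom_mosaics = [
        (chrom, call.mosaic_populations[0])
        for chrom, call in sorted(autosome_calls.items(), key=lambda kv: CHROM_ORDER[kv[0]])
        if call.mosaic_populations
    ]
    if not chrom_mosaics and mcc is None:
        return [(primary, None)]

    if chrom_mosaics and len(chrom_mosaics) <= 2:
        gains2 = list(primary.gains)
        losses2 = list(primary.losses)
        fracs = []
        for chrom, (k2, frac) in chrom_mosaics:
            delta = k2 - baseline
            fracs.append(frac)
            if delta > 0:
                gains2.extend([chrom] * delta)
            else:
                losses2.extend([chrom] * (-delta))
        frac = sorted(fracs)[len(fracs) // 2]
        sex2 = primary.sex[0]
        if mcc is not None and abs(mcc[1] - frac) <= 0.15:
            # the aberrant population carries the minority sex class
            sex2 = mcc[0] or sex2
            flags.append(
                "sex-discordant populations detected; aberrant line assigned the "
                "minority sex class (maternal admixture not distinguishable)"
            )
        second = KaryotypeSpec(
            base_ploidy=baseline,
            sex=(sex2,),
            gains=tuple(gains2),
            losses=tuple(losses2),
            events=primary.events,
        )
        pops = [(primary, 1.0 - frac), (second, frac)]
        return sorted(pops, key=lambda p: p[0].is_normal())

    if mcc is not None:
        sex2, frac = mcc
        if sex2 and sex2 != primary.sex[0]:
            flags.append(
                "two sex-discordant populations reported; maternal cell "
                "contamination and true mosaicism are not distinguished"
            )
            second = KaryotypeSpec(
                base_ploidy=baseline,
                sex=(sex2,),
                gains=primary.gains,
                losses=primary.losses,
                events=primary.events,
            )
            pops = [(primary, 1.0 - frac), (second, frac)]
            return sorted(pops, key=lambda p: p[0].is_normal())

    if chrom_mosaics:
        flags.append(
            f"{len(chrom_mosaics)} chromosomes show secondary populations; "
            "no consistent mosaic genome assembled"
        )
    return [(primary, None)]


def karyotype_case(
    spot_tables: dict[str, pd.DataFrame],
    panel: Panel,
    config: CallerConfig | None = None,
    n_cells: int | None = None,
) -> GenomeCall:
    """Full pipeline from spot tables: extract patterns, then assemble."""
    config = config or CallerConfig()
    patterns = {
        hyb_id: extract_patterns(table, config.fusion_radius, n_cells=n_cells)
        for hyb_id, table in spot_tables.items()
    }
    return call_genome(patterns, panel, config)


# ---------------------------------------------------------------------------
# nomenclature


def to_icp_string(
    populations: list[tuple[KaryotypeSpec, float | None]] | KaryotypeSpec,
    cp: int | None = None,
) -> str:
    """Render populations as ``icp.<clone>[/<clone>...][cpN]``."""
    if isinstance(populations, KaryotypeSpec):
        populations = [(populations, None)]
    if not populations:
        raise ValueError("no populations to render")
    body = "/".join(spec.render() for spec, _ in populations)
    suffix = f"[cp{cp}]" if cp is not None else ""
    return f"icp.{body}{suffix}"


def parse_icp_string(text: str) -> list[KaryotypeSpec]:
    """Parse an icp./cytogenetic result string into its clonal populations."""
    body, _cp = strip_icp_decorations(text)
    if not body.strip():
        raise KaryotypeError("empty result string")
    clones = [c for c in body.split("/") if c.strip()]
    return [parse_karyotype_spec(c) for c in clones]


def classify_abnormal(text: str) -> bool:
    """False iff the call is exactly 46,XX or 46,XY with no events and no
    additional populations."""
    clones = parse_icp_string(text)
    return not (len(clones) == 1 and clones[0].is_normal())
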