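"""Karyotype specifications and the icp./cytogenetic string mini-language.

A :class:`KaryotypeSpec` describes one clonal genome: a base ploidy (copies
per haploid autosome set), a sex-chromosome complement, whole-chromosome
gains/losses, and structural events (terminal deletions, reciprocal
translocations, unbalanced derivatives, Robertsonian fusions).

The string grammar accepts both plain cytogenetic karyotypes ("47,XX,+16")
and icp.-prefixed result strings ("icp.46,XY,der(13;14)(q10;q10),+14[cp20]").
The ``icp.`` prefix and ``[cpN]`` suffix are stripped before parsing, so one
grammar serves simulator input and published result strings alike.  Band
labels inside event parentheses (including "?") are carried as opaque text
and never interpreted genomically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X", "Y")
ACROCENTRICS: frozenset[str] = frozenset({"13", "14", "15", "21", "22"})
#: sort order used for event rendering (X after 22, Y last)
CHROM_ORDER: dict[str, int] = {c: i for i, c in enumerate(CHROMOSOMES, start=1)}


class KaryotypeError(ValueError):
    """Malformed or internally inconsistent karyotype string/spec."""


class EventKind(str, Enum):
    TERMINAL_DELETION = "TERMINAL_DELETION"
    RECIPROCAL_TRANSLOCATION = "RECIPROCAL_TRANSLOCATION"
    UNBALANCED_DER = "UNBALANCED_DER"
    ROBERTSONIAN = "ROBERTSONIAN"


@dataclass(frozen=True)
class StructuralEvent:
    """One structural aberration.

    participants
        ``((chromosome, arm), ...)`` — arm is ``"p"``, ``"q"`` or ``"?"``.
    balanced
        False for unbalanced derivatives and Robertsonian translocation
        trisomies.
    extra_copy_of
        For an unbalanced Robertsonian: which participant is present in an
        extra free copy (rendered as the trailing ``,+N``).
    der_of
        For UNBALANCED_DER: the participant that retains its centromere
        (``der(B)t(A;B)``: ``der_of == B`` — B loses its own terminal and
        carries A's instead).
    bands
        Opaque band text per participant, e.g. ``("q10", "q10")`` or
        ``("p?", "q?")``; empty means "render a default".
    """

    kind: EventKind
    participants: tuple[tuple[str, str], ...]
    balanced: bool = True
    extra_copy_of: str | None = None
    der_of: str | None = None
    bands: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind is EventKind.ROBERTSONIAN:
            for c, _ in self.participants:
                if c not in ACROCENTRICS:
                    raise KaryotypeError(
                        f"Robertsonian participant {c!r} is not acrocentric"
                    )
            if len(self.participants) != 2:
                raise KaryotypeError("Robertsonian needs exactly two participants")
        if self.kind is EventKind.RECIPROCAL_TRANSLOCATION and len(self.participants) != 2:
            raise KaryotypeError("reciprocal translocation needs exactly two participants")
        if self.kind is EventKind.UNBALANCED_DER:
            if self.der_of not in {c for c, _ in self.participants}:
                raise KaryotypeError("der_of must be one of the participants")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.participants)

    def sort_key(self) -> tuple[int, int]:
        return (min(CHROM_ORDER[c] for c in self.chromosomes), 0)

    def class_key(self) -> tuple:
        """Identity of the event ignoring band text (used for concordance)."""
        arms = tuple(
            (c, a if self.kind is not EventKind.ROBERTSONIAN else "q")
            for c, a in self.participants
        )
        return (self.kind.value, arms, self.balanced, self.extra_copy_of, self.der_of)


def _chrom_count_delta(ev: StructuralEvent) -> int:
    if ev.kind is EventKind.ROBERTSONIAN:
        # two acrocentrics fuse into one derivative (-1); an unbalanced form
        # adds one free extra copy (+1)
        return -1 + (1 if ev.extra_copy_of is not None else 0)
    return 0


@dataclass(frozen=True)
class KaryotypeSpec:
    """One clone's genome state.

    ``sex`` holds one or more equally long alternatives (e.g. ``("XX", "XY")``
    for a result reported as "XX or XY"); simulation uses the first.
    """

    base_ploidy: int = 2
    sex: tuple[str, ...] = ("XX",)
    gains: tuple[str, ...] = ()
    losses: tuple[str, ...] = ()
    events: tuple[StructuralEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.base_ploidy < 1:
            raise KaryotypeError("base_ploidy must be >= 1")
        if not self.sex:
            raise KaryotypeError("at least one sex-complement alternative required")
        lens = {len(s) for s in self.sex}
        if len(lens) != 1:
            raise KaryotypeError(f"sex alternatives differ in length: {self.sex}")
        for s in self.sex:
            if not s or set(s) - {"X", "Y"}:
                raise KaryotypeError(f"bad sex complement {s!r}")
        for c in self.gains + self.losses:
            if c not in CHROMOSOMES:
                raise KaryotypeError(f"unknown chromosome {c!r}")
        # losses may not exceed available copies
        for c in set(self.losses):
            avail = self.base_ploidy + self.gains.count(c) if c in AUTOSOMES else self.sex[0].count(c)
            if self.losses.count(c) > avail:
                raise KaryotypeError(f"more losses of {c} than available copies")

    @property
    def chromosome_count(self) -> int:
        n = self.base_ploidy * 22 + len(self.sex[0])
        n += len(self.gains) - len(self.losses)
        n += sum(_chrom_count_delta(ev) for ev in self.events)
        return n

    # ---- rendering -------------------------------------------------------

    def render(self) -> str:
        """Canonical cytogenetic-style string (no icp. prefix, no [cpN])."""
        tokens: list[tuple[tuple[int, int], str]] = []
        for ev in self.events:
            tokens.append((ev.sort_key(), _render_event(ev)))
        for c in self.gains:
            tokens.append(((CHROM_ORDER[c], 1), f"+{c}"))
        for c in self.losses:
            tokens.append(((CHROM_ORDER[c], 1), f"-{c}"))
        tokens.sort(key=lambda t: t[0])
        sex = " or ".join(self.sex)
        head = f"{self.chromosome_count},{sex}"
        if tokens:
            return head + "," + ",".join(t for _, t in tokens)
        return head

    def is_normal(self) -> bool:
        """True iff exactly 46,XX or 46,XY with no aberrations."""
        return (
            self.chromosome_count == 46
            and not self.gains
            and not self.losses
            and not self.events
            and all(s in ("XX", "XY") for s in self.sex)
        )

    def class_key(self) -> tuple:
        """Comparison key ignoring band text and the order of events."""
        events = tuple(sorted(ev.class_key() for ev in self.events))
        return (
            self.chromosome_count,
            tuple(sorted(self.gains, key=CHROM_ORDER.get)),
            tuple(sorted(self.losses, key=CHROM_ORDER.get)),
            events,
        )

    def same_class(self, other: "KaryotypeSpec") -> bool:
        """Class-level agreement: counts, gains/losses and event structure
        match and this spec's (first) sex complement is among ``other``'s
        alternatives (or vice versa)."""
        sexes_overlap = bool(set(self.sex) & set(other.sex))
        return sexes_overlap and self.class_key() == other.class_key()


def _render_event(ev: StructuralEvent) -> str:
    if ev.kind is EventKind.TERMINAL_DELETION:
        c, arm = ev.participants[0]
        band = ev.bands[0] if ev.bands else f"{arm}?"
        return f"del({c})({band})"
    (a, arm_a), (b, arm_b) = ev.participants[:2]
    if ev.kind is EventKind.ROBERTSONIAN:
        bands = ev.bands if len(ev.bands) == 2 else ("q10", "q10")
        s = f"der({a};{b})({bands[0]};{bands[1]})"
        if ev.extra_copy_of is not None:
            s += f",+{ev.extra_copy_of}"
        return s
    if ev.kind is EventKind.RECIPROCAL_TRANSLOCATION:
        bands = ev.bands if len(ev.bands) == 2 else (f"{arm_a}?", f"{arm_b}?")
        return f"t({a};{b})({bands[0]};{bands[1]})"
    if ev.kind is EventKind.UNBALANCED_DER:
        bands = ev.bands if len(ev.bands) == 2 else (f"{arm_a}?", f"{arm_b}?")
        return f"der({ev.der_of})t({a};{b})({bands[0]};{bands[1]})"
    raise KaryotypeError(f"cannot render {ev.kind}")


# ---- parsing -------------------------------------------------------------

_PREFIX_RE = re.compile(r"^\s*icp\.?\s*", re.IGNORECASE)
_SUFFIX_RE = re.compile(r"\[cp(\d*)\]\s*$")
_SEX_RE = re.compile(r"^[XY]+$")
_GAIN_RE = re.compile(r"^\+(\d{1,2}|X|Y)$")
_LOSS_RE = re.compile(r"^-(\d{1,2}|X|Y)$")
_ROB_RE = re.compile(r"^der\((\d{1,2});(\d{1,2})\)(?:\(([^;()]+);([^;()]+)\))?$")
_DER_T_RE = re.compile(
    r"^der\((\d{1,2}|X|Y)\)t\((\d{1,2}|X|Y);(\d{1,2}|X|Y)\)"
    r"(?:\(([^;()]+);([^;()]+)\))?$"
)
_T_RE = re.compile(r"^t\((\d{1,2}|X|Y);(\d{1,2}|X|Y)\)(?:\(([^;()]+);([^;()]+)\))?$")
_DEL_RE = re.compile(r"^del\((\d{1,2}|X|Y)\)\(([^()]+)\)$")
_DEL_COMPACT_RE = re.compile(r"^del\((\d{1,2}|X|Y)([pq])\)$")


def strip_icp_decorations(text: str) -> tuple[str, int | None]:
    """Remove an ``icp.`` prefix and ``[cpN]`` suffix; return (body, N)."""
    s = text.strip()
    s = _PREFIX_RE.sub("", s)
    m = _SUFFIX_RE.search(s)
    cp = None
    if m:
        cp = int(m.group(1)) if m.group(1) else None
        s = s[: m.start()]
    return s, cp


def _normalize(text: str) -> str:
    s = text.replace("−", "-").replace("–", "-")
    s = re.sub(r"\s*,\s*", ",", s)
    s = re.sub(r"\s*([();])\s*", r"\1", s)
    s = re.sub(r"\s+", " ", s).strip()
    return s


def _split_top(s: str) -> list[str]:
    out, depth, cur = [], 0, []
    for ch in s:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            out.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    out.append("".join(cur))
    return out


def _arm_of(band: str) -> str:
    band = band.strip()
    if band.startswith("p"):
        return "p"
    if band.startswith("q"):
        return "q"
    return "?"


def _chrom(tok: str) -> str:
    if tok not in CHROMOSOMES:
        raise KaryotypeError(f"unknown chromosome {tok!r}")
    return tok


def parse_karyotype_spec(text: str) -> KaryotypeSpec:
    """Parse one clone; raises :class:`KaryotypeError` naming the bad token.

    Multi-clone (mosaic) strings containing ``/`` belong to
    :func:`icpkit.assembly.parse_icp_string`.
    """
    body, _ = strip_icp_decorations(text)
    if "/" in body:
        raise KaryotypeError(
            "mosaic string: use assembly.parse_icp_string for '/'-joined clones"
        )
    s = _normalize(body)
    if not s:
        raise KaryotypeError("empty karyotype string")
    tokens = _split_top(s)
    if len(tokens) < 2:
        raise KaryotypeError(f"need at least count and sex complement in {text!r}")
    try:
        count = int(tokens[0])
    except ValueError:
        raise KaryotypeError(f"bad chromosome count token {tokens[0]!r}") from None
    sex_alts = tuple(t.strip() for t in tokens[1].split(" or "))
    for alt in sex_alts:
        if not _SEX_RE.match(alt):
            raise KaryotypeError(f"bad sex complement token {tokens[1]!r}")

    gains: list[str] = []
    losses: list[str] = []
    events: list[StructuralEvent] = []
    for tok in tokens[2:]:
        tok = tok.strip()
        if m := _GAIN_RE.match(tok):
            gains.append(_chrom(m.group(1)))
        elif m := _LOSS_RE.match(tok):
            losses.append(_chrom(m.group(1)))
        elif m := _ROB_RE.match(tok):
            a, b = sorted((_chrom(m.group(1)), _chrom(m.group(2))), key=CHROM_ORDER.get)
            bands = (m.group(3), m.group(4)) if m.group(3) else ()
            events.append(
                StructuralEvent(
                    EventKind.ROBERTSONIAN, ((a, "q"), (b, "q")), balanced=True, bands=bands
                )
            )
        elif m := _DER_T_RE.match(tok):
            der_of, a, b = _chrom(m.group(1)), _chrom(m.group(2)), _chrom(m.group(3))
            if der_of not in (a, b):
                raise KaryotypeError(f"der chromosome not in translocation: {tok!r}")
            bands = (m.group(4), m.group(5)) if m.group(4) else ("?", "?")
            arms = (_arm_of(bands[0]), _arm_of(bands[1]))
            events.append(
                StructuralEvent(
                    EventKind.UNBALANCED_DER,
                    ((a, arms[0]), (b, arms[1])),
                    balanced=False,
                    der_of=der_of,
                    bands=bands if m.group(4) else (),
                )
            )
        elif m := _T_RE.match(tok):
            a, b = _chrom(m.group(1)), _chrom(m.group(2))
            if m.group(3):
                bands = (m.group(3), m.group(4))
                arms = (_arm_of(bands[0]), _arm_of(bands[1]))
            elif a in ACROCENTRICS and b in ACROCENTRICS:
                # bare t(13;22) between acrocentrics: centromeric fusion
                a, b = sorted((a, b), key=CHROM_ORDER.get)
                events.append(
                    StructuralEvent(EventKind.ROBERTSONIAN, ((a, "q"), (b, "q")))
                )
                continue
            else:
                bands, arms = (), ("?", "?")
            events.append(
                StructuralEvent(
                    EventKind.RECIPROCAL_TRANSLOCATION,
                    ((a, arms[0]), (b, arms[1])),
                    balanced=True,
                    bands=bands,
                )
            )
        elif m := _DEL_RE.match(tok):
            c, band = _chrom(m.group(1)), m.group(2)
            arm = _arm_of(band)
            if arm == "?":
                raise KaryotypeError(f"cannot infer deleted arm from {tok!r}")
            events.append(
                StructuralEvent(
                    EventKind.TERMINAL_DELETION, ((c, arm),), balanced=False, bands=(band,)
                )
            )
        elif m := _DEL_COMPACT_RE.match(tok):
            c, arm = _chrom(m.group(1)), m.group(2)
            events.append(
                StructuralEvent(EventKind.TERMINAL_DELETION, ((c, arm),), balanced=False)
            )
        else:
            raise KaryotypeError(f"unrecognized token {tok!r} in {text!r}")

    # fold a trailing +N into a preceding Robertsonian over the same chromosome
    folded: list[StructuralEvent] = []
    for ev in events:
        if ev.kind is EventKind.ROBERTSONIAN and ev.extra_copy_of is None:
            for c in ev.chromosomes:
                if c in gains:
                    gains.remove(c)
                    ev = replace(ev, extra_copy_of=c, balanced=False)
                    break
        folded.append(ev)

    # infer base ploidy from the declared count
    residual = count - len(sex_alts[0]) - len(gains) + len(losses)
    residual -= sum(_chrom_count_delta(ev) for ev in folded)
    n_rob = sum(1 for ev in folded if ev.kind is EventKind.ROBERTSONIAN)
    if (residual % 22 != 0 or residual < 22) and n_rob:
        # tolerate counts that tally a Robertsonian derivative as two
        # chromosomes (e.g. "47,XX,der(14;21),+21" for the 46-chromosome
        # translocation trisomy); canonical rendering restores the
        # consistent count
        if (residual - n_rob) % 22 == 0 and residual - n_rob >= 22:
            residual -= n_rob
            count -= n_rob
    if residual % 22 != 0 or residual < 22:
        raise KaryotypeError(
            f"chromosome count {count} inconsistent with events in {text!r}"
        )
    spec = KaryotypeSpec(
        base_ploidy=residual // 22,
        sex=sex_alts,
        gains=tuple(gains),
        losses=tuple(losses),
        events=tuple(folded),
    )
    if spec.chromosome_count != count:
        raise KaryotypeError(
            f"declared count {count} != implied {spec.chromosome_count} in {text!r}"
        )
    return spec


def render_karyotype_spec(spec: KaryotypeSpec) -> str:
    return spec.render()
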