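"""Validation workbench: packaged study fixtures and table-level checks.

The package ships the four published validation tables as TSV fixtures:
two initial validation sets of 43 and 40 specimens reported in a legacy
phrase dialect ("Trisomy 16", "+21,der t(14;21)"), and two clinical sets of
41 and 250 specimens reported in icp. nomenclature.
:func:`normalize_legacy_result` maps the phrase dialect onto the one
karyotype grammar so every record is parseable, and
:func:`validate_tables` recomputes normal/abnormal rates and (for the
41-sample clinical set) a full noise-free simulate -> extract -> call ->
assemble round trip per specimen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from .assembly import classify_abnormal, karyotype_case, parse_icp_string
from .chromcall import CallerConfig
from .karyosim import SimulationConfig, simulate_case
from .karyotype import ACROCENTRICS, KaryotypeError, KaryotypeSpec, parse_karyotype_spec
from .panel import build_full_panel

__all__ = [
    "ValidationRecord",
    "load_table",
    "load_all_tables",
    "normalize_legacy_result",
    "concrete_populations",
    "roundtrip_specimen",
    "validate_tables",
]

_TABLE_FILES = {"T1": "table1.tsv", "T2": "table2.tsv", "T3": "table3.tsv", "T4": "table4.tsv"}
#: tables whose ICP results are legacy phrases rather than icp. strings
_LEGACY_TABLES = {"T1", "T2"}


@dataclass(frozen=True)
class ValidationRecord:
    specimen_id: str
    source_table: str  # T1..T4
    cytogenetic_result: str
    icp_result: str
    concordant_label: str

    @property
    def icp_karyotype(self) -> str:
        """The ICP result as a parseable karyotype string."""
        if self.source_table in _LEGACY_TABLES:
            return normalize_legacy_result(self.icp_result)
        return self.icp_result


def load_table(table: str) -> list[ValidationRecord]:
    """Load one fixture table ("T1".."T4")."""
    fname = _TABLE_FILES[table]
    text = resources.files("icpkit.data").joinpath(fname).read_text()
    records = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "specimen_id":
            continue
        sid, cyto, icp, conc = (parts + ["", "", "", ""])[:4]
        records.append(
            ValidationRecord(
                specimen_id=sid,
                source_table=table,
                cytogenetic_result=cyto,
                icp_result=icp,
                concordant_label=conc,
            )
        )
    return records


def load_all_tables() -> dict[str, list[ValidationRecord]]:
    return {t: load_table(t) for t in _TABLE_FILES}


# ---------------------------------------------------------------------------
# legacy phrase dialect

_LEGACY_PATTERNS: list[tuple[re.Pattern, object]] = [
    (re.compile(r"^Normal male/female$", re.I), "46,XY/46,XX"),
    (re.compile(r"^Normal female$", re.I), "46,XX"),
    (re.compile(r"^Normal male$", re.I), "46,XY"),
    (re.compile(r"^Normal$", re.I), "46,XX or XY"),
    (re.compile(r"^Male trisomy (\d+)$", re.I), lambda m: f"47,XY,+{m.group(1)}"),
    (
        re.compile(r"^Trisomy (\d+)\s*\(\d+ cells\)$", re.I),
        lambda m: f"47,XX or XY,+{m.group(1)}/46,XX or XY",
    ),
    (
        re.compile(r"^Trisomy (\d+),\s*t\((\d+);(\d+)\)$", re.I),
        lambda m: f"47,XX or XY,+{m.group(1)},t({m.group(2)};{m.group(3)})(q?;q?)",
    ),
    (re.compile(r"^Trisomy (\d+)$", re.I), lambda m: f"47,XX or XY,+{m.group(1)}"),
    (
        re.compile(r"^Monosomy X,\s*del\((\w+?)([pq])\)$", re.I),
        lambda m: f"45,X,del({m.group(1)})({m.group(2)}?)",
    ),
    (re.compile(r"^Monosomy X$", re.I), "45,X"),
    (re.compile(r"^Triploid$", re.I), "69,XXX or XXY"),
    (re.compile(r"^Tetraploid \(mosaic[^)]*\)$", re.I), "92,XXXX or XXYY/46,XX or XY"),
    (re.compile(r"^Tetraploid$", re.I), "92,XXXX or XXYY"),
    (
        re.compile(r"^\+(\d+),\s*der\s*t?\s*\((\d+);(\d+)\)$", re.I),
        lambda m: f"46,XX or XY,der({m.group(2)};{m.group(3)})(q10;q10),+{m.group(1)}",
    ),
    (
        re.compile(r"^\+(\d+),\s*t\((\d+);(\d+)\)$", re.I),
        lambda m: f"46,XX or XY,+{m.group(1)},t({m.group(2)};{m.group(3)})",
    ),
    (re.compile(r"^\+(\d+)$", re.I), lambda m: f"47,XX or XY,+{m.group(1)}"),
]


def normalize_legacy_result(text: str) -> str:
    """Map an initial-validation phrase ("Trisomy 16") onto the karyotype
    grammar.  Strings already in karyotype form pass through unchanged."""
    s = text.strip()
    if re.match(r"^(icp\.|\d)", s, re.I):
        return s
    for pattern, repl in _LEGACY_PATTERNS:
        m = pattern.match(s)
        if m:
            return repl(m) if callable(repl) else repl
    raise KaryotypeError(f"unrecognized legacy result {text!r}")


# ---------------------------------------------------------------------------
# simulation scenarios from result classes


def concrete_populations(icp_result: str) -> list[tuple[KaryotypeSpec, float]]:
    """Resolve a (possibly or-sexed, possibly mosaic) result class into
    concrete simulation populations.

    "XX or XY" alternatives collapse to their first option; a two-clone
    mosaic is simulated at a 35%/65% split with the abnormal line at 35%,
    matching the one mosaic tetraploid in the initial validation set.
    """
    clones = parse_icp_string(icp_result)
    concrete = [
        KaryotypeSpec(
            base_ploidy=c.base_ploidy,
            sex=(c.sex[0],),
            gains=c.gains,
            losses=c.losses,
            events=c.events,
        )
        for c in clones
    ]
    if len(concrete) == 1:
        return [(concrete[0], 1.0)]
    if len(concrete) == 2:
        a, b = concrete
        if a.is_normal() and not b.is_normal():
            a, b = b, a
        return [(a, 0.35), (b, 0.65)]
    n = len(concrete)
    return [(c, 1.0 / n) for c in concrete]


def roundtrip_specimen(
    icp_result: str,
    seed: int,
    sim_config: SimulationConfig | None = None,
    caller_config: CallerConfig | None = None,
):
    """Simulate one result class noise-free and re-call it end to end.

    Returns ``(genome_call, printed_spec_populations)``.
    """
    sim_config = sim_config or SimulationConfig(seed=seed)
    if sim_config.seed != seed:
        from dataclasses import replace

        sim_config = replace(sim_config, seed=seed)
    caller_config = caller_config or CallerConfig(
        fusion_radius=sim_config.fusion_distance
    )
    panel = build_full_panel()
    populations = concrete_populations(icp_result)
    tables = simulate_case(populations, panel, sim_config)
    call = karyotype_case(tables, panel, caller_config, n_cells=sim_config.n_cells)
    return call, parse_icp_string(icp_result)


def _call_matches(call, printed_clones: list[KaryotypeSpec]) -> bool:
    """Class-level concordance: every called population matches a printed
    clone (count, gains/losses, event structure; sex within alternatives)."""
    called = [spec for spec, _ in call.populations]
    if len(called) != len(printed_clones):
        return False
    remaining = list(printed_clones)
    for spec in called:
        for cand in remaining:
            if spec.same_class(cand):
                remaining.remove(cand)
                break
        else:
            return False
    return True


def validate_tables(seed: int = 1, roundtrip: bool = True) -> dict:
    """Recompute per-table counts, abnormality rates, and (for the 41-sample
    clinical table) the per-specimen end-to-end round trip."""
    summary: dict = {"tables": {}}
    for table, records in load_all_tables().items():
        n = len(records)
        abnormal = sum(1 for r in records if classify_abnormal(r.icp_karyotype))
        summary["tables"][table] = {
            "n": n,
            "abnormal": abnormal,
            "abnormality_rate_percent": round(100.0 * abnormal / n) if n else 0,
        }
    if roundtrip:
        results = []
        for i, rec in enumerate(load_table("T3")):
            call, printed = roundtrip_specimen(rec.icp_karyotype, seed=seed + i)
            results.append(
                {
                    "specimen_id": rec.specimen_id,
                    "printed": rec.icp_result,
                    "called": call.icp_string,
                    "concordant": _call_matches(call, printed),
                }
            )
        summary["t3_roundtrip"] = {
            "n": len(results),
            "concordant": sum(1 for r in results if r["concordant"]),
            "specimens": results,
        }
    return summary
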