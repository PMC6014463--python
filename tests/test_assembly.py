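"""Genome-wide assembly: ploidy, sex, Robertsonians, pairing, nomenclature."""

import pytest

from icpkit import (
    CallerConfig,
    Color,
    EventKind,
    KaryotypeError,
    Ploidy,
    SimulationConfig,
    classify_abnormal,
    parse_icp_string,
    parse_karyotype_spec,
    simulate_case,
    to_icp_string,
)
from icpkit.assembly import (
    call_genome,
    detect_mcc,
    detect_robertsonian,
    infer_sex,
    karyotype_case,
    pair_translocations,
)
from icpkit.karyotype import StructuralEvent

from conftest import make_pattern, make_patterns


def uniform_case_patterns(full_panel, autosome_count=2, x=2, y=0):
    """Synthetic attached-geometry patterns for every hybridization."""
    out = {}
    for hyb in full_panel.hybridizations:
        covered = hyb.chromosomes_covered
        if covered == {"X", "Y"}:
            counts = {
                Color.GREEN: x,
                Color.AQUA: y,
                Color.YELLOW: x + y,
                Color.RED: x + y,
            }
            attached = {Color.GREEN: Color.YELLOW, Color.RED: Color.YELLOW}
            if y:
                attached[Color.AQUA] = Color.YELLOW
            out[hyb.id] = make_patterns(counts, attached=attached)
        elif len(covered) == 5:
            out[hyb.id] = make_patterns({c: autosome_count for c in Color})
        else:
            (chrom,) = covered
            cmap = {t.locus_class.value: t.color for t in hyb.targets}
            counts = {color: autosome_count for color in cmap.values()}
            attached = {
                color: cmap["CEN"]
                for cls, color in cmap.items()
                if cls != "CEN"
            }
            out[hyb.id] = make_patterns(counts, attached=attached)
    return out


class TestPloidyAndSex:
    def test_triploid_xxx(self, full_panel, caller_config):
        patterns = uniform_case_patterns(full_panel, autosome_count=3, x=3)
        call = call_genome(patterns, full_panel, caller_config)
        assert call.ploidy is Ploidy.TRIPLOID
        assert call.icp_string == "icp.69,XXX[cp20]"

    def test_tetraploid_xxyy(self, full_panel, caller_config):
        patterns = uniform_case_patterns(full_panel, autosome_count=4, x=2, y=2)
        call = call_genome(patterns, full_panel, caller_config)
        assert call.ploidy is Ploidy.TETRAPLOID
        assert call.icp_string == "icp.92,XXYY[cp20]"

    def test_diploid_baseline(self, full_panel, caller_config):
        patterns = uniform_case_patterns(full_panel)
        call = call_genome(patterns, full_panel, caller_config)
        assert call.ploidy is Ploidy.DIPLOID
        assert call.icp_string == "icp.46,XX[cp20]"

    @pytest.mark.parametrize(
        "x,y,sex", [(1, 0, "X"), (2, 1, "XXY"), (2, 0, "XX"), (1, 1, "XY")]
    )
    def test_sex_complement_from_aqua_and_shared_cen(self, caller_config, x, y, sex):
        counts = {
            Color.GREEN: x,
            Color.AQUA: y,
            Color.YELLOW: x + y,
            Color.RED: x + y,
        }
        attached = {Color.GREEN: Color.YELLOW, Color.RED: Color.YELLOW}
        if y:
            attached[Color.AQUA] = Color.YELLOW
        got, events, flags = infer_sex(
            make_patterns(counts, attached=attached), caller_config
        )
        assert got == sex
        assert not events

    def test_x_qter_deficit_becomes_a_deletion_event(self, caller_config):
        counts = {Color.GREEN: 1, Color.AQUA: 0, Color.YELLOW: 1, Color.RED: 0}
        sex, events, _ = infer_sex(
            make_patterns(counts, attached={Color.GREEN: Color.YELLOW}), caller_config
        )
        assert sex == "X"
        (ev,) = events
        assert ev.kind is EventKind.TERMINAL_DELETION
        assert ev.participants == (("X", "q"),)


class TestRobertsonian:
    def acro_patterns(self, counts, fused_pair, n_fused=20, n=20):
        pats = []
        for i in range(n):
            fusions = [frozenset(fused_pair)] if i < n_fused else []
            pats.append(make_pattern(i + 1, counts, fusions=fusions))
        return pats

    def test_unbalanced_13_14_with_extra_14(self, caller_config):
        counts = {
            Color.YELLOW: 2,
            Color.GREEN: 3,
            Color.RED: 2,
            Color.AQUA: 2,
            Color.FARRED: 2,
        }
        events, fusion_calls, totals, _ = detect_robertsonian(
            self.acro_patterns(counts, (Color.YELLOW, Color.GREEN)), caller_config
        )
        (ev,) = events
        assert ev.chromosomes == ("13", "14")
        assert ev.extra_copy_of == "14"
        assert totals["14"] == 3

    def test_unbalanced_14_21_with_extra_21(self, caller_config):
        counts = {
            Color.YELLOW: 2,
            Color.GREEN: 2,
            Color.RED: 2,
            Color.AQUA: 3,
            Color.FARRED: 2,
        }
        events, *_ = detect_robertsonian(
            self.acro_patterns(counts, (Color.GREEN, Color.AQUA)), caller_config
        )
        (ev,) = events
        assert ev.chromosomes == ("14", "21")
        assert ev.extra_copy_of == "21"

    def test_balanced_13_22(self, caller_config):
        counts = {c: 2 for c in Color}
        events, *_ = detect_robertsonian(
            self.acro_patterns(counts, (Color.YELLOW, Color.FARRED)), caller_config
        )
        (ev,) = events
        assert ev.chromosomes == ("13", "22")
        assert ev.balanced and ev.extra_copy_of is None

    def test_subthreshold_fusion_yields_no_event(self, caller_config):
        counts = {c: 2 for c in Color}
        events, *_ = detect_robertsonian(
            self.acro_patterns(counts, (Color.YELLOW, Color.GREEN), n_fused=4),
            caller_config,
        )
        assert events == []


class TestPairing:
    def test_loss_plus_extra_becomes_unbalanced_der(self):
        events, flags = pair_translocations([("18", "q")], [("7", "p")], [])
        (ev,) = events
        assert ev.kind is EventKind.UNBALANCED_DER
        assert ev.der_of == "18"
        assert ev.participants == (("7", "p"), ("18", "q"))

    def test_two_displaced_balanced_chromosomes_pair_into_translocation(self):
        events, _ = pair_translocations([], [], [("2", "q"), ("10", "q")])
        (ev,) = events
        assert ev.kind is EventKind.RECIPROCAL_TRANSLOCATION
        assert ev.participants == (("2", "q"), ("10", "q"))

    def test_unpaired_loss_stays_a_terminal_deletion(self):
        events, _ = pair_translocations([("10", "p")], [], [])
        (ev,) = events
        assert ev.kind is EventKind.TERMINAL_DELETION
        assert ev.participants == (("10", "p"),)

    def test_ambiguous_pairing_is_reported(self):
        events, flags = pair_translocations(
            [("18", "q"), ("16", "q")], [("7", "p")], []
        )
        assert any("ascending" in f for f in flags)
        # fewest events: one der + one residual deletion
        kinds = sorted(ev.kind for ev in events)
        assert kinds == sorted(
            [EventKind.TERMINAL_DELETION, EventKind.UNBALANCED_DER]
        )

    def test_odd_displaced_chromosome_is_flagged_not_invented(self):
        events, flags = pair_translocations([], [], [("5", "q")])
        assert events == []
        assert any("no partner" in f for f in flags)


class TestMcc:
    def xy_patterns(self, n_xy, n_xx):
        pats = []
        for i in range(n_xy):
            pats.append(
                make_pattern(
                    i + 1,
                    {Color.GREEN: 1, Color.AQUA: 1, Color.YELLOW: 2, Color.RED: 2},
                    attached={Color.GREEN: Color.YELLOW, Color.RED: Color.YELLOW,
                              Color.AQUA: Color.YELLOW},
                )
            )
        for i in range(n_xx):
            pats.append(
                make_pattern(
                    n_xy + i + 1,
                    {Color.GREEN: 2, Color.AQUA: 0, Color.YELLOW: 2, Color.RED: 2},
                    attached={Color.GREEN: Color.YELLOW, Color.RED: Color.YELLOW},
                )
            )
        return pats

    def test_two_sex_populations_reported(self, caller_config):
        assert detect_mcc(self.xy_patterns(5, 15), caller_config) == ("XY", 0.25)

    def test_single_population(self, caller_config):
        assert detect_mcc(self.xy_patterns(0, 20), caller_config) is None

    def test_below_mosaic_rule_is_single_population(self, caller_config):
        assert detect_mcc(self.xy_patterns(2, 18), caller_config) is None


class TestNomenclature:
    def test_robertsonian_trisomy_21_male(self):
        spec = parse_karyotype_spec("46,XY,der(14;21)(q10;q10),+21")
        assert to_icp_string(spec, cp=20) == "icp.46,XY,der(14;21)(q10;q10),+21[cp20]"

    def test_normal_female(self):
        assert to_icp_string(parse_karyotype_spec("46,XX"), cp=20) == "icp.46,XX[cp20]"

    def test_mosaic_populations_joined_with_slash(self):
        pops = [
            (parse_karyotype_spec("92,XXXX"), 0.35),
            (parse_karyotype_spec("46,XX"), 0.65),
        ]
        assert to_icp_string(pops, cp=20) == "icp.92,XXXX/46,XX[cp20]"

    @pytest.mark.parametrize(
        "text,abnormal",
        [
            ("icp.47,XX,+15", True),
            ("icp.46,XY", False),
            ("icp.46,XX", False),
            ("icp.46,XX or XY", False),
            ("icp.46,XX,t(2;18)(p?;q?)", True),
            ("icp.45,X", True),
            ("icp.92,XXXX/46,XX", True),
            ("icp.46,XY/46,XX", True),
        ],
    )
    def test_classify_abnormal(self, text, abnormal):
        assert classify_abnormal(text) is abnormal

    def test_unparseable_string_raises(self):
        with pytest.raises(KaryotypeError):
            parse_icp_string("icp.46,XX,shrug(9)")


class TestEndToEnd:
    def test_robertsonian_evidence_is_never_double_reported(self, full_panel):
        cfg = SimulationConfig(seed=21)
        tables = simulate_case("46,XY,der(13;14)(q10;q10),+14", full_panel, cfg)
        call = karyotype_case(tables, full_panel, n_cells=20)
        assert call.primary.gains == ()  # the +14 lives inside the der event
        (ev,) = call.primary.events
        assert ev.extra_copy_of == "14"
        assert call.icp_string == "icp.46,XY,der(13;14)(q10;q10),+14[cp20]"

    def test_balanced_translocation_with_free_trisomy(self, full_panel):
        cfg = SimulationConfig(seed=22)
        tables = simulate_case("47,XY,t(2;11)(q?;q?),+22", full_panel, cfg)
        call = karyotype_case(tables, full_panel, n_cells=20)
        assert call.icp_string == "icp.47,XY,t(2;11)(q?;q?),+22[cp20]"

    def test_maternal_cell_admixture_reported_as_two_populations(self, full_panel):
        cfg = SimulationConfig(seed=23)
        tables = simulate_case([("46,XY", 0.3), ("46,XX", 0.7)], full_panel, cfg)
        call = karyotype_case(tables, full_panel, n_cells=20)
        assert call.icp_string.startswith("icp.46,")
        rendered = {spec.render() for spec, _ in call.populations}
        assert rendered == {"46,XX", "46,XY"}
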