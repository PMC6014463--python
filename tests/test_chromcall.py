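"""Copy-number, fusion, and interpretation rules at the 20-cell scale."""

import pytest
from scipy import stats

from icpkit import (
    CallerConfig,
    Color,
    Interpretation,
    call_copy_number,
    call_fusion,
    estimate_cutoff,
    refine_breakpoint,
)
from icpkit.chromcall import call_chromosome, displaced_fraction, interpret_chromosome
from icpkit.spotcall import CellPattern, SpotCluster

from conftest import make_pattern, make_patterns

YG = frozenset({Color.YELLOW, Color.GREEN})


def counts_patterns(counts_per_cell, color=Color.RED):
    return [
        make_pattern(i + 1, {color: k}) for i, k in enumerate(counts_per_cell)
    ]


class TestCopyNumber:
    def test_uniform_trisomy(self, caller_config):
        call = call_copy_number(counts_patterns([3] * 20), Color.RED, caller_config)
        assert call.primary_copy_number == 3
        assert call.secondary_copy_number is None

    def test_four_of_twenty_secondary_is_mosaic(self, caller_config):
        call = call_copy_number(
            counts_patterns([1] * 16 + [2] * 4), Color.RED, caller_config
        )
        assert call.primary_copy_number == 1
        assert call.secondary_copy_number == 2
        assert call.secondary_fraction == pytest.approx(0.20)

    def test_two_of_twenty_is_below_the_mosaic_rule(self, caller_config):
        call = call_copy_number(
            counts_patterns([2] * 18 + [3] * 2), Color.RED, caller_config
        )
        assert call.primary_copy_number == 2
        assert call.secondary_copy_number is None

    def test_modal_ties_break_toward_two_then_smaller(self, caller_config):
        assert (
            call_copy_number(
                counts_patterns([2] * 10 + [4] * 10), Color.RED, caller_config
            ).primary_copy_number
            == 2
        )
        assert (
            call_copy_number(
                counts_patterns([1] * 10 + [3] * 10), Color.RED, caller_config
            ).primary_copy_number
            == 1
        )

    def test_minimum_mosaic_population_is_exactly_four_cells(self, caller_config):
        """Exhaustive sweep at n=20: the four-of-twenty rule."""
        min_mosaic = None
        for k in range(0, 21):
            call = call_copy_number(
                counts_patterns([2] * (20 - k) + [3] * k), Color.RED, caller_config
            )
            if call.secondary_copy_number is not None and min_mosaic is None:
                min_mosaic = k
        assert min_mosaic == 4

    def test_low_cell_warning_below_twenty(self, caller_config):
        call = call_copy_number(counts_patterns([2] * 10), Color.RED, caller_config)
        assert call.low_cell_warning

    def test_zero_cells_is_an_error(self, caller_config):
        with pytest.raises(ValueError):
            call_copy_number([], Color.RED, caller_config)


class TestFusion:
    def fused_patterns(self, k, n=20):
        pats = []
        for i in range(n):
            fusions = [YG] if i < k else []
            pats.append(
                make_pattern(i + 1, {Color.YELLOW: 2, Color.GREEN: 2}, fusions=fusions)
            )
        return pats

    def test_four_of_twenty_is_still_normal(self, caller_config):
        call = call_fusion(self.fused_patterns(4), YG, caller_config)
        assert call.fraction == pytest.approx(0.20)
        assert not call.abnormal

    def test_five_of_twenty_is_abnormal(self, caller_config):
        call = call_fusion(self.fused_patterns(5), YG, caller_config)
        assert call.abnormal

    def test_consistent_fusion_is_abnormal(self, caller_config):
        assert call_fusion(self.fused_patterns(20), YG, caller_config).abnormal

    def test_largest_normal_fraction_is_twenty_percent(self, caller_config):
        """Exhaustive sweep at n=20 of the strict >20% cut-off."""
        normal = [
            k
            for k in range(21)
            if not call_fusion(self.fused_patterns(k), YG, caller_config).abnormal
        ]
        assert max(normal) == 4

    def test_raising_the_cutoff_never_creates_an_abnormal_call(self):
        for k in range(21):
            was_abnormal = True
            for cutoff in (0.10, 0.20, 0.35, 0.60):
                call = call_fusion(
                    self.fused_patterns(k), YG, CallerConfig(fusion_cutoff=cutoff)
                )
                assert not (call.abnormal and not was_abnormal)
                was_abnormal = call.abnormal

    def test_identical_colors_rejected(self, caller_config):
        with pytest.raises(ValueError):
            call_fusion(self.fused_patterns(0), (Color.RED, Color.RED), caller_config)


class TestCutoffEstimation:
    def _control(self, fused, n):
        return self.patterns_with_fusions(fused, n)

    @staticmethod
    def patterns_with_fusions(fused, n):
        return [
            make_pattern(i + 1, {Color.RED: 2}, fusions=[YG] if i < fused else [])
            for i in range(n)
        ]

    def test_zero_events_gives_the_binomial_upper_bound(self):
        cutoff = estimate_cutoff([self.patterns_with_fusions(0, 100)], 0.95)
        # oracle: direct search over the binomial CDF for the smallest rate
        # that makes 0/100 a <=5% outcome
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if stats.binom.cdf(0, 100, mid) > 0.05:
                lo = mid
            else:
                hi = mid
        assert cutoff == pytest.approx(hi, abs=1e-6)

    def test_max_observed_fraction_is_a_floor(self):
        controls = [
            self.patterns_with_fusions(40, 400),  # 10%
            self.patterns_with_fusions(60, 400),  # 15%
        ]
        assert estimate_cutoff(controls, 0.95) >= 0.15

    def test_single_cell_control_is_bounded(self):
        assert estimate_cutoff([self.patterns_with_fusions(1, 1)], 0.95) <= 1.0

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            estimate_cutoff([], 0.95)


class TestInterpretation:
    def test_pter_deficit_is_a_short_arm_deletion(self, caller_config, standard_panel):
        pats = make_patterns(
            {Color.GREEN: 1, Color.YELLOW: 2, Color.RED: 2},
            attached={Color.GREEN: Color.YELLOW, Color.RED: Color.YELLOW},
        )
        call = call_chromosome(pats, standard_panel.hyb_for("9"), "9", caller_config)
        assert call.interpretation is Interpretation.TERMINAL_DEL_P
        assert call.lost_terminal == "p"

    def test_uniform_three_is_a_gain(self, caller_config, standard_panel):
        pats = make_patterns(
            {Color.GREEN: 3, Color.YELLOW: 3, Color.RED: 3},
            attached={Color.GREEN: Color.YELLOW, Color.RED: Color.YELLOW},
        )
        call = call_chromosome(pats, standard_panel.hyb_for("8"), "8", caller_config)
        assert call.interpretation is Interpretation.GAIN

    def test_uniform_one_is_a_loss(self, caller_config, standard_panel):
        pats = make_patterns(
            {Color.GREEN: 1, Color.YELLOW: 1, Color.RED: 1},
            attached={Color.GREEN: Color.YELLOW, Color.RED: Color.YELLOW},
        )
        call = call_chromosome(pats, standard_panel.hyb_for("16"), "16", caller_config)
        assert call.interpretation is Interpretation.LOSS

    def test_extra_unanchored_terminal_is_displacement(self, caller_config, standard_panel):
        pats = make_patterns(
            {Color.GREEN: 3, Color.YELLOW: 2, Color.RED: 2},
            attached={Color.GREEN: Color.YELLOW, Color.RED: Color.YELLOW},
        )
        call = call_chromosome(pats, standard_panel.hyb_for("7"), "7", caller_config)
        assert call.interpretation is Interpretation.DISPLACED_TERMINAL
        assert call.extra_terminal == "p"

    def test_normal_counts_with_displaced_qter_is_displacement(
        self, caller_config, standard_panel
    ):
        pats = []
        for i in range(20):
            clusters = [
                SpotCluster((Color.YELLOW,), (0.0, 0.0), 1),
                SpotCluster((Color.YELLOW,), (2.0, 0.0), 1),
                SpotCluster((Color.GREEN,), (0.2, 0.0), 1),
                SpotCluster((Color.GREEN,), (2.2, 0.0), 1),
                SpotCluster((Color.RED,), (0.0, 0.2), 1),
                SpotCluster((Color.RED,), (40.0, 40.0), 1),  # far from any anchor
            ]
            pats.append(
                CellPattern(
                    cell_id=i + 1,
                    color_counts={Color.GREEN: 2, Color.YELLOW: 2, Color.RED: 2},
                    fusions=__import__("collections").Counter(),
                    clusters=clusters,
                )
            )
        call = call_chromosome(pats, standard_panel.hyb_for("2"), "2", caller_config)
        assert call.interpretation is Interpretation.DISPLACED_TERMINAL
        assert call.displaced_arms == ("q",)
        assert call.extra_terminal is None

    def test_conflicting_evidence_falls_back_to_mixed(self, caller_config):
        target_calls = {
            "pter": call_copy_number(
                counts_patterns([1] * 20, Color.GREEN), Color.GREEN, caller_config
            ),
            "cen": call_copy_number(
                counts_patterns([2] * 20, Color.YELLOW), Color.YELLOW, caller_config
            ),
            "qter": call_copy_number(
                counts_patterns([3] * 20, Color.RED), Color.RED, caller_config
            ),
        }
        interp, _ = interpret_chromosome(target_calls, [], {}, caller_config)
        assert interp is Interpretation.MIXED


def test_displaced_fraction_requires_anchor_clusters():
    import collections

    pat = CellPattern(
        cell_id=1,
        color_counts={Color.RED: 1},
        fusions=collections.Counter(),
        clusters=[SpotCluster((Color.RED,), (0.0, 0.0), 1)],
    )
    assert displaced_fraction([pat], Color.RED, Color.YELLOW, 0.3) == 0.0


class TestBreakpointRefinement:
    def test_terminal_run_localizes_the_break(self):
        bands = [("12p11", True), ("12p12", True), ("12p13", True), ("12pter", False)]
        assert refine_breakpoint(bands) == ("12p13", "12pter")

    def test_all_present_means_no_breakpoint(self):
        assert refine_breakpoint([("q1", True), ("q2", True)]) is None

    def test_interval_spans_last_present_to_first_absent(self):
        bands = [("q12", True), ("q14", False), ("q21", False)]
        assert refine_breakpoint(bands) == ("q12", "q14")

    def test_whole_arm_absent(self):
        assert refine_breakpoint([("q11", False), ("q12", False)]) == (None, "q11")

    def test_empty_band_list_rejected(self):
        with pytest.raises(ValueError):
            refine_breakpoint([])
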