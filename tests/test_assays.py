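"""Assay evaluators: per-class verdicts, nesting, and cohort coverage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fusiondx.assays import (
    AGNOSTIC_IDENTIFIED,
    AGNOSTIC_UNIDENTIFIED,
    AssayError,
    AssayVerdict,
    BRIDGED_UNRESOLVED,
    CLOSE_PROXIMITY,
    FAIL_NONE,
    NOT_COVERED,
    PARTNER_NOT_IN_DESIGN,
    SPECIFIC,
    WRONG_PARTNER,
    AmpliconDesign,
    HyCaDesign,
    SPEDesign,
    capability_matrix,
    cohort_coverage,
    evaluate_amplicon,
    evaluate_ba_fish,
    evaluate_case,
    evaluate_dual_fish,
    evaluate_hyca,
    evaluate_imbalance,
    evaluate_spe,
    probe_bed,
)
from fusiondx.cohort import (
    CohortParams,
    SimulatedCase,
    GroundTruth,
    canonical_scenarios,
    simulate_cohort,
)
from fusiondx.events import (
    Breakend,
    BreakpointEvent,
    BridgeInsert,
    FusionJunction,
    JunctionSide,
    PARTNER_AMBIGUOUS,
)
from fusiondx.model import CANONICAL, GenomicInterval


def _intron17_breakend(model):
    iso = model.isoforms[CANONICAL]
    e17, e18 = iso.exons[16], iso.exons[17]
    mid = (e18.end + e17.start) // 2
    return Breakend(GenomicInterval(iso.chrom, mid, mid + 1, "+"))


def _partner_breakend(model, gene, intron=1):
    iso = model.isoforms_of(gene)[0]
    a, b = iso.exons[intron - 1], iso.exons[intron]
    pos = (a.end + b.start) // 2
    return Breakend(GenomicInterval(iso.chrom, pos, pos + 1, "+"))


class TestBaFish:
    def test_close_partner_false_negative(self, model, designs):
        ev = BreakpointEvent("e", _intron17_breakend(model),
                             _partner_breakend(model, "ATE1", 11))
        v = evaluate_ba_fish(ev, designs["BA-FISH"], model)
        assert not v.detected and v.failure_mode == CLOSE_PROXIMITY

    def test_distant_partner_detected(self, model, designs):
        ev = BreakpointEvent("e", _intron17_breakend(model),
                             _partner_breakend(model, "DBP", 2))
        v = evaluate_ba_fish(ev, designs["BA-FISH"], model)
        assert v.detected and v.partner_resolution == AGNOSTIC_UNIDENTIFIED
        assert not v.frame_determinable and not v.expression_assessed

    def test_pure_3p_deletion_not_detected(self, model, designs):
        iso = model.isoforms[CANONICAL]
        pos = iso.exons[17].start + 40
        ev = BreakpointEvent("e", _intron17_breakend(model),
                             Breakend(GenomicInterval(iso.chrom, pos, pos + 1, "+")))
        v = evaluate_ba_fish(ev, designs["BA-FISH"], model)
        assert not v.detected and v.failure_mode == NOT_COVERED


class TestDualFish:
    def test_designed_partner_specific(self, model, designs):
        ev = BreakpointEvent("e", _intron17_breakend(model),
                             _partner_breakend(model, "BICC1", 2))
        v = evaluate_dual_fish(ev, designs["Dual-FISH"], model)
        assert v.detected and v.partner_resolution == SPECIFIC

    def test_any_other_partner_missed(self, model, designs):
        ev = BreakpointEvent("e", _intron17_breakend(model),
                             _partner_breakend(model, "CCDC6", 2))
        v = evaluate_dual_fish(ev, designs["Dual-FISH"], model)
        assert not v.detected and v.failure_mode == WRONG_PARTNER

    def test_partnerless_missed(self, model, designs):
        ev = BreakpointEvent("e", _intron17_breakend(model), None,
                             partner_status=PARTNER_AMBIGUOUS)
        assert not evaluate_dual_fish(ev, designs["Dual-FISH"], model).detected


class TestImbalance:
    def test_fusion_imbalance_detected(self, designs):
        v = evaluate_imbalance(200, 60, designs["Imbalance"])
        assert v.detected and v.partner_resolution == "none" and not v.frame_determinable

    def test_wild_type_equal_counts_not_detected(self, designs):
        assert not evaluate_imbalance(200, 197, designs["Imbalance"]).detected

    def test_3p_deletion_same_verdict_shape_as_fusion(self, designs):
        # the imbalance assay cannot differentiate fusion from deletion
        assert evaluate_imbalance(200, 60, designs["Imbalance"]) == \
            evaluate_imbalance(210, 64, designs["Imbalance"])


def _jx(gene, tx, exon, ex5="17"):
    return FusionJunction("j", JunctionSide("FGFR2", CANONICAL, ex5, 0),
                          JunctionSide(gene, tx, exon, 0))


class TestAmplicon:
    def test_ccdc6_worked_example_two_of_four_missed(self, model, designs):
        # partner primers cover CCDC6 exons 1-2 only; junctions in exons 3/4
        # escape the design
        verdicts = [evaluate_amplicon(_jx("CCDC6", "NM_CCDC6.1", e), designs["Amplicon"])
                    for e in ("1", "2", "3", "4")]
        assert [v.detected for v in verdicts] == [True, True, False, False]
        assert {v.failure_mode for v in verdicts if not v.detected} == {PARTNER_NOT_IN_DESIGN}

    def test_intergenic_3p_sequence_missed(self, designs):
        v = evaluate_amplicon(_jx("(intergenic)", ".", "1"), designs["Amplicon"])
        assert not v.detected and v.failure_mode == PARTNER_NOT_IN_DESIGN


class TestSpe:
    def test_detects_regardless_of_partner(self, model, designs):
        v = evaluate_spe(_jx("ZMYM4", "NM_ZMYM4.1", "2"), designs["SPE"], model)
        assert v.detected and v.partner_resolution == AGNOSTIC_IDENTIFIED
        assert v.frame_determinable and v.expression_assessed

    def test_exon_absent_from_design_isoform_missed(self, model, designs):
        v = evaluate_spe(_jx("BICC1", "NM_BICC1.1", "2", ex5="C3only"),
                         designs["SPE"], model)
        assert not v.detected and v.failure_mode == NOT_COVERED

    def test_intergenic_readthrough_detected(self, model, designs):
        v = evaluate_spe(_jx("(intergenic)", ".", "1"), designs["SPE"], model)
        assert v.detected


class TestHyca:
    def test_bridged_event_detected_as_rearrangement(self, model, designs):
        ev = BreakpointEvent("e", _intron17_breakend(model), None,
                             partner_status=PARTNER_AMBIGUOUS,
                             insert=BridgeInsert("A" * 40, repeat_family="AluSx"))
        v = evaluate_hyca(ev, designs["HyCa-DNA"], model)
        assert v.detected
        assert v.partner_resolution == AGNOSTIC_UNIDENTIFIED
        assert v.failure_mode == BRIDGED_UNRESOLVED

    def test_same_event_at_rna_level_identifies_partner(self, model, designs):
        v = evaluate_hyca(_jx("DBP", "NM_DBP.1", "3"), designs["HyCa-RNA"], model)
        assert v.detected and v.partner_resolution == AGNOSTIC_IDENTIFIED
        assert v.frame_determinable and v.expression_assessed

    def test_breakend_outside_probe_tiling_missed(self, model, designs):
        iso = model.isoforms[CANONICAL]
        a, b = iso.exons[15], iso.exons[16]
        pos = (b.end + a.start) // 2  # intron 16, not tiled
        ev = BreakpointEvent("e", Breakend(GenomicInterval(iso.chrom, pos, pos + 1, "+")),
                             _partner_breakend(model, "BICC1", 2))
        v = evaluate_hyca(ev, designs["HyCa-DNA"], model)
        assert not v.detected and v.failure_mode == NOT_COVERED

    def test_probe_bed_export(self, designs):
        bed = probe_bed(designs["HyCa-DNA"])
        assert bed.startswith("chr10\t") and bed.count("\n") == 1


class TestVerdictInvariants:
    def test_undetected_requires_failure_mode(self):
        with pytest.raises(AssayError):
            AssayVerdict(False, failure_mode=FAIL_NONE)

    def test_soundness_over_simulated_cohort(self, model, designs):
        # failure none => detected; not detected => failure set
        cases = simulate_cohort(CohortParams(n_events=150, seed=21), model)
        for c in cases:
            for d in designs.values():
                v = evaluate_case(d, c, model)
                if v.failure_mode == FAIL_NONE:
                    assert v.detected
                if not v.detected:
                    assert v.failure_mode != FAIL_NONE


class TestNesting:
    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=15, deadline=None)
    def test_amplicon_subset_spe_subset_hyca_rna(self, model, seed):
        # shared driver-side configuration: amplicon- and SPE-detected sets
        # nest inside the RNA hybrid-capture detected set
        driver = frozenset({"17", "18"})
        amp = AmpliconDesign(driver, {"CCDC6": frozenset({"1", "2"}),
                                      "BICC1": frozenset({"2", "3"})})
        spe = SPEDesign(driver)
        hyca = HyCaDesign("RNA", captured_exons=driver)
        cases = simulate_cohort(CohortParams(n_events=60, seed=seed), model)
        for c in cases:
            a = evaluate_amplicon(c.junction, amp).detected
            s = evaluate_spe(c.junction, spe, model).detected
            h = evaluate_hyca(c.junction, hyca, model).detected
            assert (not a or s) and (not s or h)

    def test_hyca_rna_sensitivity_exactly_one_on_expressed_covered(self, model, designs):
        cases = simulate_cohort(CohortParams(n_events=200, seed=4), model)
        expressed = [c for c in cases if c.junction is not None
                     and c.junction.five_prime.exon in designs["HyCa-RNA"].captured_exons]
        assert expressed
        assert all(evaluate_hyca(c.junction, designs["HyCa-RNA"], model).detected
                   for c in expressed)

    def test_dual_fish_subset_of_ba_fish_plus_designed_close(self, model, designs):
        cases = simulate_cohort(CohortParams(n_events=200, seed=12), model)
        for c in cases:
            dual = evaluate_dual_fish(c.event, designs["Dual-FISH"], model).detected
            ba = evaluate_ba_fish(c.event, designs["BA-FISH"], model)
            if dual:
                assert ba.detected or ba.failure_mode == CLOSE_PROXIMITY


class TestCohortCoverage:
    def test_hand_enumerated_toy_cohort(self, model, designs):
        # 4 junctions, amplicon detects exactly the 2 with designed partner exons
        def case(i, gene, tx, exon):
            j = _jx(gene, tx, exon)
            return SimulatedCase(f"c{i}", None, j, 200, 60,
                                 GroundTruth("standard", gene, "in_frame",
                                             "enhanced_dimerisation", True))
        cases = [case(1, "CCDC6", "NM_CCDC6.1", "1"),
                 case(2, "CCDC6", "NM_CCDC6.1", "3"),
                 case(3, "BICC1", "NM_BICC1.1", "2"),
                 case(4, "AFF3", "NM_AFF3.1", "2")]
        fractions, matrix = cohort_coverage(cases, {"Amplicon": designs["Amplicon"],
                                                    "SPE": designs["SPE"]}, model)
        assert fractions["Amplicon"] == 0.5
        assert fractions["SPE"] == 1.0
        assert list(matrix["Amplicon"]) == [True, False, True, False]

    def test_single_undetectable_event_gives_zero(self, model, designs):
        c = SimulatedCase("c", None, None, 200, 199,
                          GroundTruth("wild_type", None, "indeterminate", "none", False))
        fractions, _ = cohort_coverage([c], designs, model)
        assert (fractions == 0.0).all()

    def test_empty_cohort_rejected(self, model, designs):
        with pytest.raises(AssayError):
            cohort_coverage([], designs, model)


class TestCapabilityMatrix:
    def test_wild_type_row_all_negative(self, model, designs):
        cap = capability_matrix(canonical_scenarios(model), designs, model)
        assert not any(v.detected for v in cap.loc["wild-type"])

    def test_close_partner_row(self, model, designs):
        cap = capability_matrix(canonical_scenarios(model), designs, model)
        row = cap.loc["close partner"]
        assert not row["BA-FISH"].detected
        assert row["BA-FISH"].failure_mode == CLOSE_PROXIMITY
        assert row["Imbalance"].detected and row["SPE"].detected
        assert row["HyCa-DNA"].detected and row["HyCa-RNA"].detected

    def test_3p_deletion_row(self, model, designs):
        cap = capability_matrix(canonical_scenarios(model), designs, model)
        row = cap.loc["3' deletion"]
        assert not row["BA-FISH"].detected and not row["Dual-FISH"].detected
        assert row["Imbalance"].detected
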