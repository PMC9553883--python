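"""Interpretive core: localization, frame, kinase retention, mechanism."""

import numpy as np
import pytest

from fusiondx.annotation import (
    C_TERMINAL_TRUNCATION,
    ENHANCED_DIMERISATION,
    EXON_CDS,
    IN_FRAME,
    INDETERMINATE,
    INTRON,
    MECH_INDETERMINATE,
    MECH_NONE,
    NO_CDS_3P,
    OUT_OF_FRAME,
    UPSTREAM,
    AnnotationError,
    annotate_event,
    classify_mechanism,
    frame_status,
    kinase_retained,
    localize,
    translate_fusion,
)
from fusiondx.cohort import KCTD1_ALT, KCTD1_CANONICAL, PARTNER_SPECS
from fusiondx.events import Breakend, BreakpointEvent, FusionJunction, JunctionSide
from fusiondx.model import CANONICAL, GenomicInterval, ProteinDomain


def _be(model, pos, chrom="chr10"):
    return Breakend(GenomicInterval(chrom, pos, pos + 1, "+"))


def _intron_pos(iso, k):
    """A genomic position in the middle of intron k (transcript order)."""
    a, b = iso.exons[k - 1], iso.exons[k]
    if iso.strand == "-":
        return (b.end + a.start) // 2
    return (a.end + b.start) // 2


class TestLocalize:
    def test_between_exons_17_and_18_is_intron_17(self, model):
        iso = model.isoforms[CANONICAL]
        loc = localize(_be(model, _intron_pos(iso, 17)), iso)
        assert (loc.region, loc.index) == (INTRON, 17)

    def test_upstream_of_transcript_start(self, model):
        iso = model.isoforms[CANONICAL]
        loc = localize(_be(model, iso.span.end + 5), iso)
        assert loc.region == UPSTREAM

    def test_inside_exon_18_cds(self, model):
        iso = model.isoforms[CANONICAL]
        # cDNA position of an exon-18 coding base
        from fusiondx.model import transcript_to_genomic
        pos = transcript_to_genomic(iso, iso.cds_end - 30)
        loc = localize(_be(model, pos), iso)
        assert (loc.region, loc.label) == (EXON_CDS, "18")

    def test_wrong_chromosome_raises(self, model):
        iso = model.isoforms[CANONICAL]
        with pytest.raises(AnnotationError):
            localize(Breakend(GenomicInterval("chrX", 5, 6, "+")), iso)


class TestKinaseRetention:
    @pytest.mark.parametrize("intron,kept", [(17, True), (16, False)])
    def test_intron_rule(self, model, intron, kept):
        iso = model.isoforms[CANONICAL]
        loc = localize(_be(model, _intron_pos(iso, intron)), iso)
        assert kinase_retained(loc, iso, model.domains[CANONICAL]) is kept

    def test_exon_18_cds_keeps_kinase(self, model):
        from fusiondx.model import transcript_to_genomic
        iso = model.isoforms[CANONICAL]
        pos = transcript_to_genomic(iso, iso.cds_end - 3)
        loc = localize(_be(model, pos), iso)
        assert kinase_retained(loc, iso, model.domains[CANONICAL])

    def test_moving_breakend_downstream_never_loses_kinase(self, model):
        # monotonicity: scanning the breakend 3'-ward along the transcript,
        # kinase_retained never flips from True back to False
        iso = model.isoforms[CANONICAL]
        positions = sorted(
            np.random.default_rng(5).integers(iso.span.start, iso.span.end, 400),
            reverse=(iso.strand == "-"),
        )
        seen_true = False
        for pos in positions:
            kept = kinase_retained(localize(_be(model, int(pos)), iso), iso,
                                   model.domains[CANONICAL])
            if seen_true:
                assert kept
            seen_true = seen_true or kept


class TestFrameStatus:
    def _junction(self, gene, tx, exon, offset=0, ex5="17", off5=0):
        return FusionJunction("j", JunctionSide("FGFR2", CANONICAL, ex5, off5),
                              JunctionSide(gene, tx, exon, offset))

    def test_junction_upstream_of_canonical_start_codon(self, model):
        # KCTD1-like: against the canonical isoform the junction precedes the
        # start codon; the same junction is intron 1 / in-frame on the
        # alternative isoform -> isoform-dependent verdict
        j = self._junction("KCTD1", KCTD1_ALT, "2")
        frames = frame_status(j, model)
        assert frames[KCTD1_ALT] == IN_FRAME

    def test_kctd1_dna_breakpoint_conflicts_across_isoforms(self, model, catalog):
        alt = model.isoforms[KCTD1_ALT]
        pos = (alt.exons[0].end + model.isoforms[KCTD1_CANONICAL].exons[0].start) // 2
        iso = model.isoforms[CANONICAL]
        ev = BreakpointEvent("kctd1", _be(model, _intron_pos(iso, 17)),
                             Breakend(GenomicInterval("chr18", pos, pos + 1, "+")))
        ann = annotate_event(ev, model, catalog)
        recs = {r.partner_isoform: r for r in ann.records
                if r.driver_isoform == CANONICAL}
        assert recs[KCTD1_CANONICAL].frame == NO_CDS_3P
        assert recs[KCTD1_CANONICAL].mechanism == C_TERMINAL_TRUNCATION
        assert recs[KCTD1_ALT].frame == IN_FRAME
        assert recs[KCTD1_ALT].mechanism == ENHANCED_DIMERISATION
        assert ann.conflict

    def test_unknown_partner_transcript_indeterminate(self, model):
        j = FusionJunction("j", JunctionSide("FGFR2", CANONICAL, "17", 0),
                           JunctionSide("NOSUCH", "NM_Z.1", "1", 0, novel=True))
        assert set(frame_status(j, model).values()) == {INDETERMINATE}

    def test_frame_agrees_with_translation_oracle_on_random_junctions(self, model):
        # independent oracle: splice the two transcript fragments, translate,
        # and ask whether the partner C-terminal peptide is produced
        rng = np.random.default_rng(11)
        single_iso_partners = [s.gene for s in PARTNER_SPECS]
        n_checked = 0
        for _ in range(1400):
            gene = single_iso_partners[rng.integers(len(single_iso_partners))]
            piso = model.isoforms_of(gene)[0]
            ex5 = "17" if rng.random() < 0.5 else "18"
            iso5 = model.isoforms[CANONICAL]
            max_off5 = len(iso5.exons[int(ex5) - 1]) - 1
            off5 = int(rng.integers(0, max_off5))
            k3 = int(rng.integers(1, piso.n_exons + 1))
            off3 = int(rng.integers(0, len(piso.exons[k3 - 1])))
            j = FusionJunction(
                "jx", JunctionSide("FGFR2", CANONICAL, ex5, off5),
                JunctionSide(gene, piso.transcript_id, str(k3), off3))
            try:
                verdict = frame_status(j, model)[piso.transcript_id]
            except AnnotationError:
                continue  # 5' junction ran out of the driver CDS
            tail = piso.protein[-15:]
            from fusiondx.annotation import _junction_cdna_3p as _r3
            if piso.cds_end - _r3(j.three_prime, piso) < 51:
                continue  # junction inside the tail probe itself
            from Bio.Seq import Seq
            from fusiondx.annotation import _junction_cdna_5p, _junction_cdna_3p
            cut5 = _junction_cdna_5p(j.five_prime, iso5)
            resume = _junction_cdna_3p(j.three_prime, piso)
            fused = iso5.sequence[:cut5] + piso.sequence[resume - 1:]
            cds = fused[iso5.cds_start - 1:]
            cds = cds[: len(cds) - len(cds) % 3]
            full = str(Seq(cds).translate())          # frame check, stops kept
            bio = str(Seq(cds).translate(to_stop=True))  # biological peptide
            if verdict == IN_FRAME:
                assert tail in full, (j, verdict)
            elif verdict == OUT_OF_FRAME:
                assert tail not in full, (j, verdict)
            elif verdict == NO_CDS_3P:
                if 0 < piso.cds_start - resume < 12:
                    # junction a few nt upstream of the start codon: the short
                    # UTR remnant may read through; the categorical rule is
                    # meant for junctions genuinely upstream of the ATG
                    continue
                # translation must terminate before the partner suffix
                assert tail not in bio, (j, verdict)
            else:
                continue  # cut inside the stop codon: genuinely ambiguous
            n_checked += 1
        assert n_checked >= 1000


class TestMechanism:
    def test_in_frame_with_coiled_coil_partner_is_enhanced_dimerisation(self):
        dom = [ProteinDomain("coiled-coil", 100, 150)]
        assert classify_mechanism(IN_FRAME, True, 765, dom, True) == ENHANCED_DIMERISATION

    def test_partnerless_truncation_after_exon_17(self):
        assert classify_mechanism(INDETERMINATE, True, 765, [], False) == \
            C_TERMINAL_TRUNCATION

    def test_no_kinase_means_no_mechanism(self):
        assert classify_mechanism(IN_FRAME, False, 722, [], True) == MECH_NONE

    def test_out_of_frame_truncation_ignores_partner(self):
        assert classify_mechanism(OUT_OF_FRAME, True, 765,
                                  [ProteinDomain("SAM", 5, 60)], True) == \
            C_TERMINAL_TRUNCATION

    def test_dna_only_unresolved_partner_is_indeterminate(self):
        assert classify_mechanism(INDETERMINATE, True, 765, [], True) == \
            MECH_INDETERMINATE


class TestAnnotateEvent:
    def test_f17a12_style_junction_competent_in_frame(self, model, catalog):
        j = FusionJunction("f17a12", JunctionSide("FGFR2", CANONICAL, "17", 0),
                           JunctionSide("ATE1", "NM_ATE1.1", "12", 0))
        ann = annotate_event(j, model, catalog)
        rec = ann.record_for(CANONICAL)
        assert rec.frame == IN_FRAME and rec.competent
        assert "YLDL" in rec.lost_motifs

    def test_event_upstream_of_exon_17_noncompetent_on_every_isoform(self, model, catalog):
        iso = model.isoforms[CANONICAL]
        bicc1 = model.isoforms_of("BICC1")[0]
        ev = BreakpointEvent("up", _be(model, _intron_pos(iso, 10)),
                             _be(model, _intron_pos(bicc1, 2), chrom=bicc1.chrom))
        ann = annotate_event(ev, model, catalog)
        assert ann.records and all(not r.competent for r in ann.records)

    def test_bridged_event_indeterminate_at_dna_level(self, model, catalog):
        from fusiondx.events import BridgeInsert, PARTNER_AMBIGUOUS
        iso = model.isoforms[CANONICAL]
        ev = BreakpointEvent("br", _be(model, _intron_pos(iso, 17)), None,
                             partner_status=PARTNER_AMBIGUOUS,
                             insert=BridgeInsert("A" * 80, repeat_family="AluSx"))
        ann = annotate_event(ev, model, catalog)
        assert ann.record_for(CANONICAL).mechanism == MECH_INDETERMINATE

    def test_mechanism_exclusivity_and_competence(self, model, catalog):
        # no record claims both mechanisms; competent records always retain
        # the kinase and carry some mechanism
        from fusiondx.cohort import CohortParams, simulate_cohort
        cases = simulate_cohort(CohortParams(n_events=120, seed=9), model)
        for c in cases:
            ann = annotate_event(c.event, model, catalog)
            for r in ann.records:
                assert r.mechanism in (ENHANCED_DIMERISATION, C_TERMINAL_TRUNCATION,
                                       MECH_NONE, MECH_INDETERMINATE)
                if r.competent:
                    assert r.kinase_retained and r.mechanism != MECH_NONE

    def test_driver_gene_absent_raises(self, model, catalog):
        from fusiondx.model import GeneModel
        with pytest.raises(AnnotationError):
            j = FusionJunction("x", JunctionSide("FGFR2", CANONICAL, "17", 0),
                               JunctionSide("ATE1", "NM_ATE1.1", "12", 0))
            annotate_event(j, GeneModel(), catalog)
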