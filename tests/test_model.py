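"""Gene-model arithmetic: fixture facts, coordinate mapping, motif scan."""

import pytest

from fusiondx.model import (
    C3,
    CANONICAL,
    IIIB,
    FlankLocation,
    GeneModelError,
    GenomicInterval,
    IntronLocation,
    ParseError,
    TranscriptIsoform,
    ValidationError,
    build_fgfr2_fixture,
    exonic_regions,
    genomic_to_transcript,
    load_gene_model,
    locate_motif,
    protein_length,
    reverse_translate,
    transcript_to_genomic,
)


class TestFixtureFacts:
    def test_canonical_isoform_has_18_exons(self, fgfr2_only):
        assert fgfr2_only.isoforms[CANONICAL].n_exons == 18

    @pytest.mark.parametrize("tx,aa", [(CANONICAL, 821), (IIIB, 822), (C3, 769)])
    def test_protein_lengths(self, fgfr2_only, tx, aa):
        assert protein_length(fgfr2_only.isoforms[tx]) == aa

    def test_c3_truncates_iiib_by_53_aa(self, fgfr2_only):
        iiib = fgfr2_only.isoforms[IIIB].protein
        c3 = fgfr2_only.isoforms[C3].protein
        assert c3 == iiib[:-53]

    def test_iiib_shares_all_exons_but_the_eighth(self, fgfr2_only):
        a = fgfr2_only.isoforms[CANONICAL].exons
        b = fgfr2_only.isoforms[IIIB].exons
        diff = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
        assert diff == [7]

    def test_c3_lacks_first_exon_and_ends_on_alternative_terminal_exon(self, fgfr2_only):
        iiib = fgfr2_only.isoforms[IIIB]
        c3 = fgfr2_only.isoforms[C3]
        assert c3.exons[:-1] == iiib.exons[1:17]
        assert c3.exons[-1] != iiib.exons[17]

    def test_yldl_motif_at_769_and_nowhere_later(self, fgfr2_only):
        hits = locate_motif(fgfr2_only.isoforms[CANONICAL], "YLDL")
        assert hits[-1] == 769

    def test_gene_on_minus_strand_of_chr10_at_printed_span(self, fgfr2_only):
        locus = fgfr2_only.genes["FGFR2"]
        assert (locus.chrom, locus.strand) == ("chr10", "-")
        # 0-based half-open internal == 1-based inclusive 123,237,844-123,357,972
        assert (locus.start + 1, locus.end) == (123_237_844, 123_357_972)

    def test_union_of_described_exonic_regions_has_26_members(self, fgfr2_only):
        assert len(exonic_regions(fgfr2_only, "FGFR2")) == 26

    def test_kinase_domain_at_printed_aa_coordinates(self, fgfr2_only):
        kin = next(d for d in fgfr2_only.domains[CANONICAL] if d.name == "kinase")
        assert (kin.aa_start, kin.aa_end) == (481, 757)


class TestCoordinateMapping:
    def test_minus_strand_convention_anchor(self):
        # minus-strand toy exon spanning genomic [1000, 1100): genomic 1099 is cDNA 1
        iso = TranscriptIsoform("toy", "TOY", [GenomicInterval("chr1", 1000, 1100, "-")])
        assert genomic_to_transcript(iso, 1099) == 1

    def test_position_between_exons_17_and_18_is_intron_17(self, fgfr2_only):
        iso = fgfr2_only.isoforms[CANONICAL]
        e17, e18 = iso.exons[16], iso.exons[17]
        mid = (e18.end + e17.start) // 2
        loc = genomic_to_transcript(iso, mid)
        assert isinstance(loc, IntronLocation) and loc.index == 17

    def test_flanks(self, fgfr2_only):
        iso = fgfr2_only.isoforms[CANONICAL]
        up = genomic_to_transcript(iso, iso.span.end + 10)
        down = genomic_to_transcript(iso, iso.span.start - 10)
        assert isinstance(up, FlankLocation) and up.side == "upstream"
        assert isinstance(down, FlankLocation) and down.side == "downstream"

    def test_wrong_chromosome_rejected(self, fgfr2_only):
        iso = fgfr2_only.isoforms[CANONICAL]
        with pytest.raises(GeneModelError):
            genomic_to_transcript(iso, 500, chrom="chr7")

    def test_round_trip_identity_over_every_exonic_base(self, fgfr2_only):
        # brute force: transcript->genomic->transcript is the identity on
        # every exonic base of every fixture isoform
        for iso in fgfr2_only.isoforms.values():
            for cdna in range(1, iso.length + 1):
                g = transcript_to_genomic(iso, cdna)
                assert genomic_to_transcript(iso, g) == cdna

    def test_strand_mirror_preserves_cdna_quantities(self, fgfr2_only):
        # mirroring the canonical isoform onto the plus strand around the
        # locus midpoint leaves protein length and motif positions unchanged
        iso = fgfr2_only.isoforms[CANONICAL]
        axis = iso.span.start + iso.span.end
        mirrored = [GenomicInterval(e.chrom, axis - e.end, axis - e.start, "+")
                    for e in iso.exons]
        flipped = TranscriptIsoform("flipped", iso.gene, mirrored,
                                    cds_start=iso.cds_start, cds_end=iso.cds_end,
                                    sequence=iso.sequence, exon_labels=iso.exon_labels)
        assert protein_length(flipped) == protein_length(iso)
        assert locate_motif(flipped, "YLDL") == locate_motif(iso, "YLDL")


class TestMotifScan:
    def test_empty_motif_rejected(self, fgfr2_only):
        with pytest.raises(GeneModelError):
            locate_motif(fgfr2_only.isoforms[CANONICAL], "")

    def test_absent_motif_gives_empty_list(self, fgfr2_only):
        assert locate_motif(fgfr2_only.isoforms[CANONICAL], "WWWWWW") == []

    def test_whole_protein_matches_at_position_one(self, fgfr2_only):
        iso = fgfr2_only.isoforms[CANONICAL]
        assert locate_motif(iso, iso.protein) == [1]

    def test_occurrences_ascending(self, fgfr2_only):
        iso = fgfr2_only.isoforms[CANONICAL]
        hits = locate_motif(iso, "A")
        assert hits == sorted(hits)


TOY_GFF = """\
chr2\ttoy\tgene\t1001\t1303\t.\t+\t.\tID=TOYG;Name=TOYG
chr2\ttoy\tmRNA\t1001\t1303\t.\t+\t.\tID=toy.t1;Parent=TOYG
chr2\ttoy\texon\t1001\t1303\t.\t+\t.\tParent=toy.t1
chr2\ttoy\tCDS\t1001\t1303\t.\t+\t0\tParent=toy.t1
"""


class TestIO:
    def test_single_exon_toy_gene_from_gff3(self):
        model = load_gene_model(TOY_GFF)
        iso = model.isoforms["toy.t1"]
        assert iso.n_exons == 1
        assert protein_length(iso) == 100  # 303 nt CDS incl. stop

    def test_mrna_without_exons_rejected(self):
        bad = "\n".join(l for l in TOY_GFF.splitlines() if "\texon\t" not in l)
        with pytest.raises(ValidationError):
            load_gene_model(bad)

    def test_cds_not_codon_multiple_rejected(self):
        bad = TOY_GFF.replace("CDS\t1001\t1303", "CDS\t1001\t1302")
        with pytest.raises(ValidationError):
            load_gene_model(bad)

    def test_orphan_feature_names_offending_line(self):
        bad = TOY_GFF.replace("Parent=TOYG", "Parent=NOSUCH")
        with pytest.raises(ParseError, match="line 2"):
            load_gene_model(bad)

    def test_fixture_json_round_trip(self, fgfr2_only):
        reloaded = load_gene_model(fgfr2_only.to_json())
        assert set(reloaded.isoforms) == {CANONICAL, IIIB, C3}
        assert reloaded.isoforms[CANONICAL].protein == fgfr2_only.isoforms[CANONICAL].protein

    def test_reverse_translate_round_trip(self):
        from Bio.Seq import Seq
        prot = "MKTAYIAKQR"
        assert str(Seq(reverse_translate(prot)).translate()) == prot + "*"
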