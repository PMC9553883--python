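"""Synthetic FGFR2 rearrangement cohorts with ground-truth labels.

Generates DNA breakpoint events and matched RNA fusion junctions whose
architecture follows what is reported for large FGFR2-rearranged
cholangiocarcinoma cohorts: breakpoints concentrated in exon 17 /
intron 17 / exon 18 (intron 17 dominant), heterogeneous 3' partner genes,
roughly 10% bridged/partnerless rearrangements at DNA level, 4.2% partners
in close genomic proximity to FGFR2 (invisible to break-apart FISH), and
occasional 3' deletions and out-of-frame events.

The partner catalog ships ~8 toy genes modelled on recurrently reported
partners (a BICC1-like distant SAM-domain gene, ATE1- and TACC2-like
close-proximity genes, a CCDC6-like multi-exon coiled-coil gene, a
KCTD1-like gene with isoform-dependent start codons, a DBP-like bridged
target) at synthetic coordinates.  Read counts are Poisson; all
randomness flows through explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .annotation import PartnerDomainCatalog
from .events import (
    Breakend,
    BreakpointEvent,
    BridgeInsert,
    FusionJunction,
    JunctionSide,
    PARTNER_AMBIGUOUS,
    PARTNER_INTERGENIC,
    ReadEvidence,
    RETAINS_LEFT,
    RETAINS_RIGHT,
)
from .model import (
    CANONICAL,
    GeneModel,
    GenomicInterval,
    ProteinDomain,
    TranscriptIsoform,
    build_fgfr2_fixture,
    build_toy_gene,
    transcript_to_genomic,
)


class CohortError(ValueError):
    pass


# event classes
CLASS_STANDARD = "standard"            # distant partner, in-frame
CLASS_BRIDGED = "bridged"              # partner obscured by inserted sequence
CLASS_CLOSE = "close_partner"          # partner within FISH resolution
CLASS_OUT_OF_FRAME = "out_of_frame"
CLASS_3P_DELETION = "p3_deletion"      # FGFR2-internal loss of the terminal exon
CLASS_UPSTREAM = "upstream_noncompetent"  # breakpoint 5' of exon 17, kinase lost


# --------------------------------------------------------------------------
# partner catalog
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PartnerSpec:
    gene: str
    chrom: str
    anchor: int          # genomic start (plus strand) of the toy gene
    exon_cds: tuple[int, ...]
    seed: int
    dimerisation_domain: Optional[str] = None   # domain type from the flagged list
    junction_introns: tuple[int, ...] = (1, 2)  # introns usable as breakpoint sites
    close: bool = False


# all exon CDS contributions are codon multiples, so any catalogued
# junction intron is frame-compatible with a breakpoint after FGFR2 exon 17
PARTNER_SPECS: tuple[PartnerSpec, ...] = (
    PartnerSpec("BICC1", "chr10", 60_500_000, (90,) + (120,) * 9, 11, "SAM", (1, 2, 3, 4)),
    PartnerSpec("ATE1", "chr10", 123_660_000, (90,) + (120,) * 11, 12, None, (11,), close=True),
    PartnerSpec("TACC2", "chr10", 123_610_000, (90,) + (120,) * 7, 13, "coiled-coil", (2, 3), close=True),
    PartnerSpec("CCDC6", "chr10", 61_500_000, (90,) + (120,) * 5, 14, "coiled-coil", (4, 5)),
    PartnerSpec("DBP", "chr19", 49_100_000, (90,) + (120,) * 3, 15, None, (2, 3)),
    PartnerSpec("AFF3", "chr2", 100_000_000, (90,) + (120,) * 7, 16, "leucine zipper", (1, 2, 3)),
    PartnerSpec("ZMYM4", "chr1", 35_800_000, (90,) + (120,) * 6, 17, "zinc finger", (1, 2)),
)

DISTANT_PARTNERS = ("BICC1", "CCDC6", "AFF3", "ZMYM4")
CLOSE_PARTNERS = ("ATE1", "TACC2")
BRIDGED_TRUE_PARTNERS = ("DBP", "BICC1")

KCTD1_CANONICAL = "NM_KCTD1.A"   # start codon downstream of the alternative TSS
KCTD1_ALT = "NM_KCTD1.B"         # upstream first exon carrying the start codon


def _build_kctd1() -> tuple[GenomicInterval, list[TranscriptIsoform], list[ProteinDomain]]:
    """KCTD1-like gene with isoform-dependent start codons.

    Isoform B transcribes an upstream first exon holding the start codon;
    isoform A starts at the shared second exon, whose first codon is the
    (engineered) methionine at B's residue 31.  A DNA breakpoint between
    the two first exons is upstream of A but intron 1 of B — annotation
    must disagree across isoforms.
    """
    chrom = "chr18"
    e1b = GenomicInterval(chrom, 9_800_000, 9_800_190, "+")   # 100 UTR + 90 CDS
    e2 = GenomicInterval(chrom, 9_806_000, 9_806_120, "+")
    e3 = GenomicInterval(chrom, 9_808_000, 9_808_120, "+")
    e4 = GenomicInterval(chrom, 9_810_000, 9_810_273, "+")    # 120 CDS + stop + 150 UTR

    from .model import random_protein, reverse_translate

    rng = np.random.default_rng(18)
    prot_b = random_protein(150, rng, forbidden=("YLDL",))
    prot_b = prot_b[:30] + "M" + prot_b[31:]   # exon 2 must open with ATG for isoform A
    cds_b = reverse_translate(prot_b)
    utr5 = ("TTAA" * 25)
    utr3 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=150))
    seq_b = utr5 + cds_b + utr3
    iso_b = TranscriptIsoform(KCTD1_ALT, "KCTD1", [e1b, e2, e3, e4],
                              cds_start=101, cds_end=100 + len(cds_b), sequence=seq_b)

    # isoform A: exon 1 extends E2 upstream by a 60 nt stop-rich UTR
    e1a = GenomicInterval(chrom, e2.start - 60, e2.end, "+")
    seq_a = ("TTAA" * 15) + cds_b[90:] + utr3
    iso_a = TranscriptIsoform(KCTD1_CANONICAL, "KCTD1", [e1a, e3, e4],
                              cds_start=61, cds_end=60 + len(cds_b) - 90, sequence=seq_a)
    locus = GenomicInterval(chrom, e1b.start, e4.end, "+")
    domains = [ProteinDomain("zinc finger", 60, 110)]  # oligomerisation module, retained 3'
    return locus, [iso_a, iso_b], domains


def build_reference_model() -> tuple[GeneModel, PartnerDomainCatalog]:
    """The FGFR2 fixture merged with the toy partner-gene catalog."""
    model = build_fgfr2_fixture()
    catalog = PartnerDomainCatalog()
    for spec in PARTNER_SPECS:
        locus, iso = build_toy_gene(
            spec.gene, spec.chrom, spec.anchor, "+",
            list(spec.exon_cds), protein_seed=spec.seed,
            extra_utr5_exon=False,
        )
        model.genes[spec.gene] = locus
        model.isoforms[iso.transcript_id] = iso
        doms = []
        if spec.dimerisation_domain:
            n_aa = sum(spec.exon_cds) // 3
            # place the dimerisation module 3' of every catalogued junction
            # intron so each simulated fusion retains it intact
            deepest = max(spec.junction_introns)
            first_kept_aa = sum(spec.exon_cds[:deepest]) // 3 + 1
            doms.append(ProteinDomain(spec.dimerisation_domain,
                                      max(first_kept_aa, n_aa - 40), n_aa - 5))
        catalog.domains[spec.gene] = doms
    locus, isos, doms = _build_kctd1()
    model.genes["KCTD1"] = locus
    for iso in isos:
        model.isoforms[iso.transcript_id] = iso
    catalog.domains["KCTD1"] = doms
    model.validate()
    return model, catalog


def partner_transcript(model: GeneModel, gene: str) -> TranscriptIsoform:
    return model.isoforms_of(gene)[0]


# --------------------------------------------------------------------------
# cohort parameters
# --------------------------------------------------------------------------

@dataclass
class CohortParams:
    n_events: int = 1000
    seed: int = 0
    p_bridged: float = 0.10
    p_close_partner: float = 0.042
    p_out_of_frame: float = 0.05
    p_3p_deletion: float = 0.03
    p_upstream_noncompetent: float = 0.02
    # driver breakpoint site distribution (intron 17 dominant)
    breakend_weights: dict = field(default_factory=lambda: {
        "exon17": 0.15, "intron17": 0.70, "exon18": 0.15,
    })
    depth: float = 200.0

    def validate(self) -> None:
        fr = [self.p_bridged, self.p_close_partner, self.p_out_of_frame,
              self.p_3p_deletion, self.p_upstream_noncompetent]
        if any(not 0 <= f <= 1 for f in fr):
            raise CohortError("class fractions must lie in [0, 1]")
        if sum(fr) > 1:
            raise CohortError(f"class fractions sum to {sum(fr):.3f} > 1")
        w = sum(self.breakend_weights.values())
        if not np.isclose(w, 1.0):
            raise CohortError("breakend weights must normalize to 1")


@dataclass
class GroundTruth:
    klass: str
    partner_gene: Optional[str]
    frame: str
    mechanism: str
    expressed: bool
    close: bool = False
    bridged: bool = False


@dataclass
class SimulatedCase:
    """One simulated tumour: DNA event, matched RNA junction, expression.

    ``event`` is None only for the wild-type control scenario."""

    id: str
    event: Optional[BreakpointEvent]
    junction: Optional[FusionJunction]
    counts_5p: int    # imbalance assay: molecules covering 5' driver exons
    counts_3p: int    # molecules covering 3' driver exons
    truth: GroundTruth


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def simulate_read_evidence(expressed: bool, depth: float,
                           rng: np.random.Generator) -> ReadEvidence:
    """Poisson split/spanning/wild-type counts at a junction.

    Fusion-read rates are proportional to depth and expression (0/1); the
    wild-type rate models the unrearranged allele plus non-tumour cells.
    """
    expr = 1.0 if expressed else 0.0
    split = int(rng.poisson(0.25 * depth * expr))
    spanning = int(rng.poisson(0.15 * depth * expr))
    wt = int(rng.poisson(0.60 * depth))
    return ReadEvidence(split, spanning, wt)


def _driver_breakend(model: GeneModel, site: str, rng: np.random.Generator,
                     frame_aligned: bool = True) -> tuple[Breakend, str, int]:
    """Driver (FGFR2) breakend at the requested site.

    Returns (breakend, junction exon label, junction offset) describing the
    predicted RNA junction on the canonical isoform.  ``frame_aligned``
    restricts exonic breakpoints to codon boundaries so the retained CDS
    stays in phase with codon-multiple partner junctions.
    """
    iso = model.isoforms[CANONICAL]
    cds0 = iso.cds_start - 1  # 150
    if site == "intron17":
        e17, e18 = iso.exons[16], iso.exons[17]
        pos = int(rng.integers(e18.end, e17.start))  # minus strand: intron below exon 17
        return Breakend(GenomicInterval(iso.chrom, pos, pos + 1, "+"), RETAINS_RIGHT), "17", 0
    if site == "exon17":
        # distal part of exon 17 (3' of the kinase end, codon-aligned)
        end17 = iso.cdna_of_exon_end(17)            # 2445
        lo_aa, hi_aa = 758, 765
        aa = int(rng.integers(lo_aa, hi_aa + 1))
        cdna = cds0 + 3 * aa
        if not frame_aligned:
            cdna += int(rng.integers(1, 3))
        pos = transcript_to_genomic(iso, cdna)
        return Breakend(GenomicInterval(iso.chrom, pos, pos + 1, "+"), RETAINS_RIGHT), \
            "17", end17 - cdna
    if site == "exon18":
        # coding part of exon 18, upstream of the YLDL motif, codon-aligned
        aa = int(rng.integers(766, 771))
        cdna = cds0 + 3 * aa
        if not frame_aligned:
            cdna += int(rng.integers(1, 3))
        pos = transcript_to_genomic(iso, cdna)
        end18 = iso.cdna_of_exon_end(18)
        return Breakend(GenomicInterval(iso.chrom, pos, pos + 1, "+"), RETAINS_RIGHT), \
            "18", end18 - cdna
    if site == "intron16":
        e16, e17 = iso.exons[15], iso.exons[16]
        pos = int(rng.integers(e17.end, e16.start))
        return Breakend(GenomicInterval(iso.chrom, pos, pos + 1, "+"), RETAINS_RIGHT), "16", 0
    raise CohortError(f"unknown breakpoint site {site!r}")


def _partner_breakend(model: GeneModel, gene: str, rng: np.random.Generator
                      ) -> tuple[Breakend, str]:
    """Breakend in a catalogued junction intron of the partner; returns the
    resulting 3' junction exon label."""
    spec = next(s for s in PARTNER_SPECS if s.gene == gene)
    iso = partner_transcript(model, gene)
    k = int(rng.choice(spec.junction_introns))
    a, b = iso.exons[k - 1], iso.exons[k]
    pos = int(rng.integers(a.end, b.start))
    return Breakend(GenomicInterval(iso.chrom, pos, pos + 1, "+"), RETAINS_LEFT), \
        iso.exon_labels[k]


def _truth_mechanism(site_label: str, junction_offset: int, partner_dim: bool,
                     in_frame: bool) -> str:
    # every simulated competent breakpoint retains the kinase; YLDL is lost
    # for all simulated sites (exon-18 breaks are placed 5' of the motif)
    if in_frame and partner_dim:
        return "enhanced_dimerisation"
    return "c_terminal_truncation"


def simulate_cohort(p: CohortParams, model: GeneModel) -> list[SimulatedCase]:
    """Draw a labelled cohort of breakpoint events and matched junctions."""
    p.validate()
    rng = np.random.default_rng(p.seed)
    classes = [CLASS_BRIDGED, CLASS_CLOSE, CLASS_OUT_OF_FRAME,
               CLASS_3P_DELETION, CLASS_UPSTREAM, CLASS_STANDARD]
    probs = [p.p_bridged, p.p_close_partner, p.p_out_of_frame,
             p.p_3p_deletion, p.p_upstream_noncompetent]
    probs.append(1.0 - sum(probs))
    sites = list(p.breakend_weights)
    site_probs = [p.breakend_weights[s] for s in sites]
    iso = model.isoforms[CANONICAL]

    cases: list[SimulatedCase] = []
    for i in range(p.n_events):
        cid = f"sim{i + 1:05d}"
        klass = str(rng.choice(classes, p=probs))
        site = str(rng.choice(sites, p=site_probs))
        expressed = True
        junction: Optional[FusionJunction] = None
        dim = False

        if klass == CLASS_UPSTREAM:
            b5, ex5, off5 = _driver_breakend(model, "intron16", rng)
            gene = str(rng.choice(DISTANT_PARTNERS))
            b3, ex3 = _partner_breakend(model, gene, rng)
            expressed = False  # unstable kinase-less product, no junction reads
            event = BreakpointEvent(cid, b5, b3)
            truth = GroundTruth(klass, gene, "in_frame", "none", expressed)
        elif klass == CLASS_3P_DELETION:
            b5, ex5, off5 = _driver_breakend(model, "intron17", rng)
            # second breakend inside the FGFR2 terminal-exon UTR: exon 18 lost
            e18 = iso.exons[17]
            pos = int(rng.integers(e18.start, e18.start + 150))
            b3 = Breakend(GenomicInterval(iso.chrom, pos, pos + 1, "+"), RETAINS_LEFT)
            event = BreakpointEvent(cid, b5, b3)
            junction = FusionJunction(
                cid, JunctionSide("FGFR2", CANONICAL, ex5, off5),
                JunctionSide("(intergenic)", ".", "1", 0, novel=True))
            truth = GroundTruth(klass, None, "indeterminate", "c_terminal_truncation", True)
        elif klass == CLASS_BRIDGED:
            b5, ex5, off5 = _driver_breakend(model, site, rng)
            gene = str(rng.choice(BRIDGED_TRUE_PARTNERS))
            _, ex3 = _partner_breakend(model, gene, rng)
            insert_seq = "".join("ACGT"[j] for j in rng.integers(0, 4, size=80))
            insert = BridgeInsert(insert_seq, repeat_family="AluSx")
            event = BreakpointEvent(cid, b5, None, partner_status=PARTNER_AMBIGUOUS,
                                    insert=insert)
            piso = partner_transcript(model, gene)
            junction = FusionJunction(
                cid, JunctionSide("FGFR2", CANONICAL, ex5, off5),
                JunctionSide(gene, piso.transcript_id, ex3, 0))
            dim = _has_dim(gene)
            truth = GroundTruth(klass, gene, "in_frame",
                                _truth_mechanism(ex5, off5, dim, True), True, bridged=True)
        else:
            if klass == CLASS_CLOSE:
                gene = str(rng.choice(CLOSE_PARTNERS))
            else:
                gene = str(rng.choice(DISTANT_PARTNERS))
            aligned = klass != CLASS_OUT_OF_FRAME
            b5, ex5, off5 = _driver_breakend(model, site if aligned else "exon18",
                                             rng, frame_aligned=aligned)
            b3, ex3 = _partner_breakend(model, gene, rng)
            event = BreakpointEvent(cid, b5, b3)
            piso = partner_transcript(model, gene)
            junction = FusionJunction(
                cid, JunctionSide("FGFR2", CANONICAL, ex5, off5),
                JunctionSide(gene, piso.transcript_id, ex3, 0))
            dim = _has_dim(gene)
            frame = "in_frame" if aligned else "out_of_frame"
            truth = GroundTruth(klass, gene, frame,
                                _truth_mechanism(ex5, off5, dim, aligned), True,
                                close=(klass == CLASS_CLOSE))

        ev = simulate_read_evidence(expressed, p.depth, rng)
        event.evidence = ev
        if junction is not None:
            junction.evidence = ev
        # imbalance molecule counts: 3' exons depleted when the rearranged
        # allele replaces them (tumour fraction ~0.65)
        depleted = truth.klass not in (CLASS_UPSTREAM,)
        lam3 = p.depth * (0.35 if depleted else 1.0)
        counts5 = int(rng.poisson(p.depth))
        counts3 = int(rng.poisson(lam3))
        cases.append(SimulatedCase(cid, event, junction, counts5, counts3, truth))
    return cases


def _has_dim(gene: str) -> bool:
    spec = next(s for s in PARTNER_SPECS if s.gene == gene)
    return spec.dimerisation_domain is not None


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------

def cohort_to_files(cases: list[SimulatedCase]) -> tuple[str, str, str]:
    """(BEDPE text, junction TSV text, ground-truth JSON text)."""
    import json

    from .events import write_bedpe, write_junctions

    bedpe = write_bedpe([c.event for c in cases])
    jx = write_junctions([c.junction for c in cases if c.junction is not None])
    truth = json.dumps({
        c.id: {
            "class": c.truth.klass, "partner_gene": c.truth.partner_gene,
            "frame": c.truth.frame, "mechanism": c.truth.mechanism,
            "expressed": c.truth.expressed, "close": c.truth.close,
            "bridged": c.truth.bridged,
            "counts_5p": c.counts_5p, "counts_3p": c.counts_3p,
        } for c in cases
    }, indent=1)
    return bedpe, jx, truth


def canonical_scenarios(model: GeneModel) -> dict[str, SimulatedCase]:
    """The canonical assay-comparison scenario set (one case per row).

    Rows: wild-type, known partner, unknown partner, out-of-frame,
    intergenic, close partner, 3' deletion.  Deterministic.
    """
    rng = np.random.default_rng(42)
    iso = model.isoforms[CANONICAL]
    e17, e18 = iso.exons[16], iso.exons[17]
    mid_i17 = (e18.end + e17.start) // 2
    b5 = Breakend(GenomicInterval(iso.chrom, mid_i17, mid_i17 + 1, "+"), RETAINS_RIGHT)

    def partner_case(cid, gene, exon3, frame_offset=0):
        piso = partner_transcript(model, gene)
        k = piso.label_to_index(exon3) - 1
        a, b = piso.exons[k - 1], piso.exons[k]
        pos = (a.end + b.start) // 2
        b3 = Breakend(GenomicInterval(piso.chrom, pos, pos + 1, "+"), RETAINS_LEFT)
        jx = FusionJunction(cid, JunctionSide("FGFR2", CANONICAL, "17", frame_offset),
                            JunctionSide(gene, piso.transcript_id, exon3, 0))
        ev = BreakpointEvent(cid, b5, b3)
        ev.evidence = jx.evidence = ReadEvidence(40, 25, 120)
        return ev, jx

    scen: dict[str, SimulatedCase] = {}
    scen["wild-type"] = SimulatedCase("wt", None, None, 200, 198,
                                      GroundTruth("wild_type", None, "indeterminate",
                                                  "none", False))
    ev, jx = partner_case("known", "BICC1", "3")
    scen["known partner"] = SimulatedCase("known", ev, jx, 200, 70,
                                          GroundTruth(CLASS_STANDARD, "BICC1",
                                                      "in_frame", "enhanced_dimerisation", True))
    ev, jx = partner_case("unknown", "AFF3", "2")
    scen["unknown partner"] = SimulatedCase("unknown", ev, jx, 200, 70,
                                            GroundTruth(CLASS_STANDARD, "AFF3",
                                                        "in_frame", "enhanced_dimerisation", True))
    ev, jx = partner_case("oof", "ZMYM4", "2", frame_offset=1)
    scen["out-of-frame"] = SimulatedCase("oof", ev, jx, 200, 70,
                                         GroundTruth(CLASS_OUT_OF_FRAME, "ZMYM4",
                                                     "out_of_frame", "c_terminal_truncation", True))
    igv = Breakend(GenomicInterval("chr4", 55_000_000, 55_000_001, "+"), RETAINS_LEFT)
    ev = BreakpointEvent("ig", b5, igv)
    ev.evidence = ReadEvidence(30, 20, 130)
    jx = FusionJunction("ig", JunctionSide("FGFR2", CANONICAL, "17", 0),
                        JunctionSide("(intergenic)", ".", "1", 0, novel=True))
    jx.evidence = ev.evidence
    scen["intergenic"] = SimulatedCase("ig", ev, jx, 200, 70,
                                       GroundTruth(CLASS_STANDARD, None, "indeterminate",
                                                   "c_terminal_truncation", True))
    ev, jx = partner_case("close", "ATE1", "12")
    scen["close partner"] = SimulatedCase("close", ev, jx, 200, 70,
                                          GroundTruth(CLASS_CLOSE, "ATE1", "in_frame",
                                                      "c_terminal_truncation", True, close=True))
    pos = iso.exons[17].start + 50
    b3 = Breakend(GenomicInterval(iso.chrom, pos, pos + 1, "+"), RETAINS_LEFT)
    ev = BreakpointEvent("del", b5, b3)
    ev.evidence = ReadEvidence(25, 15, 140)
    scen["3' deletion"] = SimulatedCase("del", ev, None, 200, 70,
                                        GroundTruth(CLASS_3P_DELETION, None, "indeterminate",
                                                    "c_terminal_truncation", True))
    return scen
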