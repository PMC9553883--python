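"""Isoform-aware interpretation of FGFR2 rearrangements.

For every isoform of the driver and partner genes this module localizes the
breakpoint, decides reading frame, kinase-domain retention and the
oncogenic mechanism, and surfaces conflicts between isoforms instead of
collapsing them into a single verdict.  The two mechanisms modelled are

* **enhanced dimerisation** — an in-frame fusion whose retained partner
  fragment contributes at least one strong dimerisation/oligomerisation
  domain, making receptor dimerisation ligand-independent; and
* **C-terminal truncation** — loss of the FGFR2 C-terminus including the
  YLDL internalisation motif (aa 769-772 on NM_000141.4), oncogenic
  regardless of reading frame or partner content.

DNA-only events with an unresolved partner are left ``indeterminate``
unless truncation is forced by the absence of any partner: frame and
partner calls from DNA alone are unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .events import (
    Breakend,
    BreakpointEvent,
    FusionJunction,
    JunctionSide,
    PARTNER_INTERGENIC,
)
from .model import (
    FlankLocation,
    GeneModel,
    GenomicInterval,
    IntronLocation,
    ProteinDomain,
    TranscriptIsoform,
    genomic_to_transcript,
    protein_length,
)


class AnnotationError(ValueError):
    pass


# region kinds
EXON_CDS = "exon_cds"
EXON_UTR = "exon_utr"
INTRON = "intron"
UPSTREAM = "upstream"
DOWNSTREAM = "downstream"

# frame values
IN_FRAME = "in_frame"
OUT_OF_FRAME = "out_of_frame"
NO_CDS_3P = "no_cds_3p"
INDETERMINATE = "indeterminate"

# mechanisms
ENHANCED_DIMERISATION = "enhanced_dimerisation"
C_TERMINAL_TRUNCATION = "c_terminal_truncation"
MECH_NONE = "none"
MECH_INDETERMINATE = "indeterminate"

# domain types the literature flags as strong dimerisation/oligomerisation
# modules when contributed by the 3' partner
DIMERISATION_DOMAIN_TYPES = frozenset({
    "AFF3", "BAG", "BAR", "coiled-coil", "FN1", "leucine zipper",
    "LIS1", "SAM", "SPHF", "zinc finger",
})

YLDL_END_AA = 772   # canonical-isoform position of the last YLDL residue
GRB2_SITE_AA = 812  # loss of the last 10 aa of the 821-aa protein impairs GRB2 binding


@dataclass(frozen=True)
class Localization:
    """Region assignment of one breakend on one isoform."""

    isoform: str
    region: str                       # EXON_CDS/EXON_UTR/INTRON/UPSTREAM/DOWNSTREAM
    index: Optional[int] = None       # 1-based exon or intron index (local)
    label: Optional[str] = None       # display exon label where applicable
    cdna_pos: Optional[int] = None    # 1-based cDNA coordinate for exonic hits

    def describe(self) -> str:
        if self.region == EXON_CDS:
            return f"exon {self.label} (CDS)"
        if self.region == EXON_UTR:
            return f"exon {self.label} (UTR)"
        if self.region == INTRON:
            return f"intron {self.index}"
        return self.region


@dataclass
class PartnerDomainCatalog:
    """Per-gene protein domains with a dimerisation flag per domain type."""

    domains: dict[str, list[ProteinDomain]] = field(default_factory=dict)

    def dimerisation_domains(self, gene: str) -> list[ProteinDomain]:
        return [d for d in self.domains.get(gene, []) if d.name in DIMERISATION_DOMAIN_TYPES]


@dataclass
class IsoformRecord:
    """Interpretation of one event against one (driver, partner) isoform pair."""

    driver_isoform: str
    partner_isoform: Optional[str]
    localization_5p: Localization
    localization_3p: Optional[Localization]
    frame: str
    kinase_retained: bool
    retained_driver_aa: Optional[int]
    mechanism: str
    competent: bool
    lost_motifs: list[str] = field(default_factory=list)
    retained_partner_domains: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    grb2_site_lost: bool = False


@dataclass
class FusionAnnotation:
    event_id: str
    level: str  # "DNA" | "RNA"
    records: list[IsoformRecord]
    conflict: bool = False  # isoforms disagree on frame or mechanism

    def record_for(self, driver_isoform: str, partner_isoform: Optional[str] = None) -> IsoformRecord:
        for r in self.records:
            if r.driver_isoform == driver_isoform and (
                partner_isoform is None or r.partner_isoform == partner_isoform
            ):
                return r
        raise KeyError((driver_isoform, partner_isoform))


# --------------------------------------------------------------------------
# localization
# --------------------------------------------------------------------------

def localize(bp: Breakend, iso: TranscriptIsoform) -> Localization:
    """Assign a breakend to exon (CDS/UTR), intron or flank of one isoform.

    A breakend given as the first base past an exon's transcript-sense end
    is intronic by the half-open convention, so junctions "after exon k"
    land in intron k.
    """
    if bp.chrom != iso.chrom:
        raise AnnotationError(f"breakend on {bp.chrom}, isoform {iso.transcript_id} on {iso.chrom}")
    tp = genomic_to_transcript(iso, bp.pos)
    if isinstance(tp, FlankLocation):
        return Localization(iso.transcript_id, tp.side)
    if isinstance(tp, IntronLocation):
        return Localization(iso.transcript_id, INTRON, index=tp.index,
                            label=iso.exon_labels[tp.index - 1])
    # exonic
    offsets = iso.exon_offsets()
    idx = next(i for i in range(len(iso.exons))
               if offsets[i] < tp <= offsets[i] + len(iso.exons[i])) + 1
    in_cds = iso.has_cds and iso.cds_start <= tp <= iso.cds_end
    return Localization(iso.transcript_id, EXON_CDS if in_cds else EXON_UTR,
                        index=idx, label=iso.exon_labels[idx - 1], cdna_pos=tp)


def _retained_driver_cds_nt(loc: Localization, iso: TranscriptIsoform) -> Optional[int]:
    """Driver CDS nt retained 5' of the breakpoint (kinase side kept)."""
    if loc.region == UPSTREAM:
        return 0
    if loc.region == DOWNSTREAM:
        return iso.cds_length - 3  # whole CDS retained, stop included separately
    if loc.region == INTRON:
        cut = iso.cdna_of_exon_end(loc.index)
    else:
        cut = loc.cdna_pos
    if not iso.has_cds:
        return None
    retained = min(cut, iso.cds_end) - (iso.cds_start - 1)
    return max(0, min(retained, iso.cds_length - 3))


def kinase_retained(loc: Localization, iso: TranscriptIsoform,
                    domains: list[ProteinDomain]) -> bool:
    """Does the retained 5' FGFR2 fragment keep the tyrosine kinase domain?

    True iff the breakpoint involves exon 17 (CDS), intron 17 or the
    protein-coding region of exon 18 — any rearrangement upstream of
    exon 17 cannot keep a functional kinase — OR the retained cDNA prefix
    translates the complete kinase domain.  The exon rule and the aa rule
    agree at intron boundaries; positions inside exon 17 upstream of the
    kinase end satisfy the exon rule only (callers may attach a
    discrepancy warning via :func:`kinase_rules_disagree`).
    """
    by_exon = _kinase_exon_rule(loc)
    by_aa = _kinase_aa_rule(loc, iso, domains)
    return by_exon or by_aa


def _kinase_exon_rule(loc: Localization) -> bool:
    lbl = loc.label
    if loc.region == EXON_CDS and lbl in ("17", "18"):
        return True
    if loc.region == INTRON and lbl == "17":
        return True
    if loc.region == DOWNSTREAM or (loc.region == EXON_UTR and lbl == "18"):
        # breakpoint past the whole CDS: kinase untouched
        return True
    return False


def _kinase_aa_rule(loc: Localization, iso: TranscriptIsoform,
                    domains: list[ProteinDomain]) -> bool:
    kin = next((d for d in domains if d.name == "kinase"), None)
    if kin is None or not iso.has_cds:
        return False
    nt = _retained_driver_cds_nt(loc, iso)
    if nt is None:
        return False
    return nt // 3 >= kin.aa_end


def kinase_rules_disagree(loc: Localization, iso: TranscriptIsoform,
                          domains: list[ProteinDomain]) -> bool:
    return _kinase_exon_rule(loc) != _kinase_aa_rule(loc, iso, domains)


# --------------------------------------------------------------------------
# reading frame
# --------------------------------------------------------------------------

def _junction_cdna_5p(side: JunctionSide, iso: TranscriptIsoform) -> int:
    """cDNA coordinate of the last retained base on the 5' side.

    ``offset`` counts nt back from the end of the named exon (0 = junction
    exactly after the full exon).
    """
    end = iso.cdna_of_exon_end(iso.label_to_index(side.exon))
    return end - side.offset


def _junction_cdna_3p(side: JunctionSide, iso: TranscriptIsoform) -> int:
    """cDNA coordinate of the first retained base on the 3' side.

    ``offset`` counts nt forward from the start of the named exon (0 = the
    partner transcript resumes at the exon's first base).
    """
    start = iso.cdna_of_exon_start(iso.label_to_index(side.exon))
    return start + side.offset


def frame_status(j: FusionJunction, model: GeneModel) -> dict[str, str]:
    """Frame verdict of an RNA junction, evaluated per 3' partner isoform.

    Let L5 be the driver CDS nt retained 5' of the junction and s the
    partner CDS nt excluded upstream of it; the partner peptide is
    translated in its own frame iff L5 ≡ s (mod 3).  A junction upstream of
    a partner isoform's start codon yields ``no_cds_3p`` for that isoform;
    unknown partner transcripts yield ``indeterminate``.
    """
    iso5 = model.isoforms.get(j.five_prime.transcript_id)
    if iso5 is None:
        raise AnnotationError(f"driver transcript {j.five_prime.transcript_id} not in model")
    cut5 = _junction_cdna_5p(j.five_prime, iso5)
    if not iso5.has_cds or cut5 < iso5.cds_start:
        raise AnnotationError("5' junction upstream of the driver CDS")
    if cut5 >= iso5.cds_end:
        # driver stop codon fully retained: the product is the wild-type
        # driver protein, no fusion ORF reaches the partner
        return {i.transcript_id: NO_CDS_3P for i in model.isoforms_of(j.three_prime.gene)} \
            or {j.three_prime.transcript_id: NO_CDS_3P}
    if cut5 > iso5.cds_end - 3:
        # cut inside the stop codon: read-through depends on the joined bases
        return {i.transcript_id: INDETERMINATE for i in model.isoforms_of(j.three_prime.gene)} \
            or {j.three_prime.transcript_id: INDETERMINATE}
    L5 = cut5 - (iso5.cds_start - 1)

    out: dict[str, str] = {}
    partner_isos = [i for i in model.isoforms_of(j.three_prime.gene)]
    if not partner_isos or j.three_prime.novel:
        return {j.three_prime.transcript_id: INDETERMINATE}
    for iso3 in partner_isos:
        try:
            resume = _junction_cdna_3p(_remap_side(j.three_prime, iso3), iso3)
        except KeyError:
            out[iso3.transcript_id] = INDETERMINATE
            continue
        if not iso3.has_cds:
            out[iso3.transcript_id] = NO_CDS_3P
            continue
        if resume > iso3.cds_end - 3:
            # junction past the partner CDS: nothing codable contributed
            out[iso3.transcript_id] = NO_CDS_3P
            continue
        if resume < iso3.cds_start:
            # junction upstream of this isoform's start codon: translation
            # from the driver runs into partner 5'UTR, no fusion ORF
            out[iso3.transcript_id] = NO_CDS_3P
            continue
        s = resume - iso3.cds_start  # partner CDS nt excluded
        out[iso3.transcript_id] = IN_FRAME if (L5 - s) % 3 == 0 else OUT_OF_FRAME
    return out


def _remap_side(side: JunctionSide, iso: TranscriptIsoform) -> JunctionSide:
    """Re-address a junction side on another isoform of the same gene (by label)."""
    if side.transcript_id == iso.transcript_id:
        return side
    iso.label_to_index(side.exon)  # KeyError if the label is absent on this isoform
    return JunctionSide(side.gene, iso.transcript_id, side.exon, side.offset)


def translate_fusion(j: FusionJunction, model: GeneModel, partner_iso: str) -> str:
    """Brute-force translation of the spliced fusion transcript.

    Concatenates the retained 5' and 3' transcript fragments and translates
    from the driver start codon to the first stop.  Used as the independent
    oracle for :func:`frame_status`.
    """
    iso5 = model.isoforms[j.five_prime.transcript_id]
    iso3 = model.isoforms[partner_iso]
    cut5 = _junction_cdna_5p(j.five_prime, iso5)
    resume = _junction_cdna_3p(_remap_side(j.three_prime, iso3), iso3)
    if iso5.sequence is None or iso3.sequence is None:
        raise AnnotationError("translation oracle needs attached sequences")
    fused = iso5.sequence[: cut5] + iso3.sequence[resume - 1 :]
    from Bio.Seq import Seq

    cds = fused[iso5.cds_start - 1 :]
    cds = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(cds).translate(to_stop=True))
    return aa


# --------------------------------------------------------------------------
# mechanism
# --------------------------------------------------------------------------

def retained_partner_domains(side: JunctionSide, iso3: TranscriptIsoform,
                             catalog: PartnerDomainCatalog) -> list[ProteinDomain]:
    """Partner domains wholly encoded 3' of the junction (retained in the fusion)."""
    try:
        resume = _junction_cdna_3p(_remap_side(side, iso3), iso3)
    except KeyError:
        return []
    if not iso3.has_cds:
        return []
    # first partner aa fully encoded at/after the junction
    s = max(0, resume - iso3.cds_start)
    first_aa = s // 3 + (1 if s % 3 == 0 else 2)
    return [d for d in catalog.domains.get(side.gene, []) if d.aa_start >= first_aa]


def classify_mechanism(
    frame: str,
    kinase_kept: bool,
    retained_driver_aa: Optional[int],
    retained_dimer_domains: list[ProteinDomain],
    partner_known: bool,
    yldl_end: int = YLDL_END_AA,
) -> str:
    """Oncogenic mechanism of one isoform record.

    Without a retained kinase there is no mechanism.  An in-frame fusion
    gaining at least one strong dimerisation domain activates by enhanced
    dimerisation.  Loss of the YLDL motif (retained driver aa < 772) with
    no in-frame dimerisation gain activates by C-terminal truncation —
    frame preservation and partner content are irrelevant for truncation.
    DNA-only events with unresolved partner content stay indeterminate
    unless truncation is forced by the absence of any partner.
    """
    if not kinase_kept:
        return MECH_NONE
    yldl_lost = retained_driver_aa is not None and retained_driver_aa < yldl_end
    if frame == IN_FRAME and retained_dimer_domains:
        return ENHANCED_DIMERISATION
    if yldl_lost and not partner_known:
        return C_TERMINAL_TRUNCATION
    if yldl_lost and frame in (OUT_OF_FRAME, NO_CDS_3P):
        return C_TERMINAL_TRUNCATION
    if yldl_lost and frame == IN_FRAME and not retained_dimer_domains:
        return C_TERMINAL_TRUNCATION
    if frame == INDETERMINATE:
        return MECH_INDETERMINATE
    return MECH_NONE


# --------------------------------------------------------------------------
# event annotation
# --------------------------------------------------------------------------

def _driver_record(
    driver_iso: TranscriptIsoform,
    model: GeneModel,
    loc5: Localization,
    frame: str,
    partner_iso_id: Optional[str],
    loc3: Optional[Localization],
    dimer_domains: list[ProteinDomain],
    partner_known: bool,
) -> IsoformRecord:
    doms = model.domains.get(driver_iso.transcript_id, [])
    kk = kinase_retained(loc5, driver_iso, doms)
    nt = _retained_driver_cds_nt(loc5, driver_iso)
    aa = None if nt is None else nt // 3
    mech = classify_mechanism(frame, kk, aa, dimer_domains, partner_known,
                              yldl_end=_yldl_end(model, driver_iso))
    lost = []
    if aa is not None and aa < _yldl_end(model, driver_iso):
        ydom = next((d for d in model.domains.get(driver_iso.transcript_id, [])
                     if d.name == "YLDL"), None)
        if ydom is not None:
            lost.append("YLDL")
    rec = IsoformRecord(
        driver_isoform=driver_iso.transcript_id,
        partner_isoform=partner_iso_id,
        localization_5p=loc5,
        localization_3p=loc3,
        frame=frame,
        kinase_retained=kk,
        retained_driver_aa=aa,
        mechanism=mech,
        competent=kk and mech not in (MECH_NONE,),
        lost_motifs=lost,
        retained_partner_domains=[d.name for d in dimer_domains],
        grb2_site_lost=(aa is not None and driver_iso.has_cds
                        and aa < protein_length(driver_iso) - 9),
    )
    if kinase_rules_disagree(loc5, driver_iso, doms):
        rec.warnings.append(
            "kinase exon rule and aa rule disagree at this position (partial kinase loss)"
        )
    return rec


def _yldl_end(model: GeneModel, iso: TranscriptIsoform) -> int:
    dom = next((d for d in model.domains.get(iso.transcript_id, []) if d.name == "YLDL"), None)
    return dom.aa_end if dom is not None else YLDL_END_AA


def annotate_junction(j: FusionJunction, model: GeneModel,
                      catalog: PartnerDomainCatalog) -> FusionAnnotation:
    """Annotate an RNA fusion junction against every relevant isoform pair."""
    driver_gene = j.five_prime.gene
    driver_isos = model.isoforms_of(driver_gene)
    if not driver_isos:
        raise AnnotationError(f"driver gene {driver_gene} absent from model")
    partner_isos = model.isoforms_of(j.three_prime.gene)
    frames = frame_status(j, model)
    records = []
    for di in driver_isos:
        try:
            side5 = _remap_side(j.five_prime, di)
            cut5 = _junction_cdna_5p(side5, di)
        except KeyError:
            continue  # junction exon absent from this driver isoform
        loc5 = Localization(di.transcript_id, INTRON if side5.offset == 0 else EXON_CDS,
                            index=di.label_to_index(side5.exon), label=side5.exon,
                            cdna_pos=cut5)
        if not partner_isos:
            rec = _driver_record(di, model, loc5, INDETERMINATE, j.three_prime.transcript_id,
                                 None, [], partner_known=False)
            records.append(rec)
            continue
        for pi in partner_isos:
            frame = frames.get(pi.transcript_id, INDETERMINATE)
            dimers = [d for d in retained_partner_domains(j.three_prime, pi, catalog)
                      if d.name in DIMERISATION_DOMAIN_TYPES] if frame == IN_FRAME else []
            loc3 = None
            try:
                resume = _junction_cdna_3p(_remap_side(j.three_prime, pi), pi)
                loc3 = Localization(pi.transcript_id, EXON_CDS, index=pi.label_to_index(j.three_prime.exon),
                                    label=j.three_prime.exon, cdna_pos=resume)
            except KeyError:
                pass
            records.append(_driver_record(di, model, loc5, frame, pi.transcript_id,
                                          loc3, dimers, partner_known=True))
    ann = FusionAnnotation(j.id, "RNA", records)
    ann.conflict = _has_conflict(records)
    return ann


def annotate_breakpoint(ev: BreakpointEvent, model: GeneModel,
                        catalog: PartnerDomainCatalog,
                        driver_gene: str = "FGFR2") -> FusionAnnotation:
    """Annotate a DNA breakpoint event against every relevant isoform pair.

    The fusion transcript predicted from a DNA breakpoint splices the last
    retained driver exon to the first partner exon 3' of the partner
    breakend; for intronic partner breakends that is the next exon in
    transcript order.  Frame is evaluated per partner isoform on that
    predicted junction; partner-unresolved events stay indeterminate.
    """
    driver_isos = model.isoforms_of(driver_gene)
    if not driver_isos:
        raise AnnotationError(f"driver gene {driver_gene} absent from model")

    partner_gene = None
    if ev.has_partner_locus:
        partner_gene = model.gene_at(ev.breakend_3p.chrom, ev.breakend_3p.pos)
    partner_isos = model.isoforms_of(partner_gene) if partner_gene and partner_gene != driver_gene else []
    # bridged: a partner exists somewhere but DNA could not resolve it ->
    # nothing can be concluded about partner content
    bridged = ev.insert is not None
    # partnerless: no partner gene contributes sequence -> if the YLDL motif
    # is lost, C-terminal truncation is forced
    partnerless = not bridged and (not ev.has_partner_locus or partner_gene is None
                                   or partner_gene == driver_gene)

    records = []
    for di in driver_isos:
        loc5 = localize(ev.breakend_5p, di)
        if bridged or partnerless:
            rec = _driver_record(di, model, loc5, INDETERMINATE, None, None, [],
                                 partner_known=bridged)
            records.append(rec)
            continue
        for pi in partner_isos:
            loc3 = localize(ev.breakend_3p, pi)
            frame, resume = _predicted_frame_from_dna(di, pi, loc5, loc3)
            dimers = []
            if frame == IN_FRAME and resume is not None:
                s = max(0, resume - pi.cds_start)
                first_aa = s // 3 + (1 if s % 3 == 0 else 2)
                dimers = [d for d in catalog.domains.get(partner_gene, [])
                          if d.name in DIMERISATION_DOMAIN_TYPES and d.aa_start >= first_aa]
            records.append(_driver_record(di, model, loc5, frame, pi.transcript_id,
                                          loc3, dimers, partner_known=True))
    ann = FusionAnnotation(ev.id, "DNA", records)
    ann.conflict = _has_conflict(records)
    return ann


def _predicted_frame_from_dna(di: TranscriptIsoform, pi: TranscriptIsoform,
                              loc5: Localization, loc3: Localization):
    """Frame of the spliced transcript predicted from DNA breakends."""
    # retained driver cDNA: through the exon preceding the break
    if loc5.region == INTRON:
        cut5 = di.cdna_of_exon_end(loc5.index)
    elif loc5.region == EXON_CDS:
        cut5 = loc5.cdna_pos
    elif loc5.region in (DOWNSTREAM,) or (loc5.region == EXON_UTR and loc5.index == di.n_exons):
        cut5 = di.length
    else:
        return INDETERMINATE, None
    if not di.has_cds or cut5 < di.cds_start:
        return NO_CDS_3P, None
    if cut5 >= di.cds_end:
        return NO_CDS_3P, None   # full driver CDS incl. stop retained
    if cut5 > di.cds_end - 3:
        return INDETERMINATE, None  # cut inside the stop codon
    L5 = cut5 - (di.cds_start - 1)

    if loc3.region == UPSTREAM:
        # partner transcribed from its own promoter downstream of the break:
        # the driver cannot splice into it upstream of the transcription start
        return NO_CDS_3P, None
    if loc3.region == DOWNSTREAM:
        return NO_CDS_3P, None
    if loc3.region == INTRON:
        resume = pi.cdna_of_exon_start(loc3.index + 1)
    else:
        resume = loc3.cdna_pos
    if not pi.has_cds:
        return NO_CDS_3P, None
    if resume < pi.cds_start:
        return NO_CDS_3P, resume
    if resume > pi.cds_end - 3:
        return NO_CDS_3P, resume
    s = resume - pi.cds_start
    return (IN_FRAME if (L5 - s) % 3 == 0 else OUT_OF_FRAME), resume


def _has_conflict(records: list[IsoformRecord]) -> bool:
    frames = {r.frame for r in records}
    mechs = {r.mechanism for r in records}
    return len(frames) > 1 or len(mechs) > 1


def annotate_event(event: Union[BreakpointEvent, FusionJunction], model: GeneModel,
                   catalog: PartnerDomainCatalog) -> FusionAnnotation:
    """Dispatch annotation by event level (DNA breakpoint vs RNA junction)."""
    if isinstance(event, FusionJunction):
        return annotate_junction(event, model, catalog)
    return annotate_breakpoint(event, model, catalog)


def annotation_rows(ann: FusionAnnotation) -> list[dict]:
    """Flat dict rows (one per isoform pair) for TSV/JSON export."""
    rows = []
    for r in ann.records:
        rows.append({
            "event_id": ann.event_id,
            "level": ann.level,
            "driver_isoform": r.driver_isoform,
            "partner_isoform": r.partner_isoform or ".",
            "localization_5p": r.localization_5p.describe(),
            "localization_3p": r.localization_3p.describe() if r.localization_3p else ".",
            "frame": r.frame,
            "kinase_retained": r.kinase_retained,
            "retained_driver_aa": r.retained_driver_aa,
            "mechanism": r.mechanism,
            "competent": r.competent,
            "lost_motifs": ",".join(r.lost_motifs) or ".",
            "retained_partner_domains": ",".join(r.retained_partner_domains) or ".",
            "conflict": ann.conflict,
            "warnings": ";".join(r.warnings) or ".",
        })
    return rows
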