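"""Clinical fusion/rearrangement report rendering and nomenclature.

A diagnostic RNA fusion report must state the supporting read counts
(split/spanning), the fusion-read ratio, both gene names with transcript
IDs, the junction exons, and whether the fusion is in-frame with the
therapeutically relevant domains intact.  A DNA translocation report must
state read counts, the translocation-read ratio, the involved genes, the
chromosomal breakpoint positions, the reference genome build, and may only
phrase frame/domain statements cautiously — mandatory wording whenever the
mechanism is indeterminate from DNA alone.

The display nomenclature is "GENE5::GENE3" plus a compact exon code built
from gene initials and junction exon numbers (FGFR2 exon 17 joined to ATE1
exon 12 -> "FGFR2::ATE1 (F17A12)"); structured transcript/exon/offset
blocks are emitted alongside for machine consumption.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional

from .annotation import (
    FusionAnnotation,
    IsoformRecord,
    MECH_INDETERMINATE,
    IN_FRAME,
)
from .events import BreakpointEvent, FusionJunction, ReadEvidence, fusion_read_ratio
from .model import CANONICAL


class ReportError(ValueError):
    """Refusal to render: a mandatory input is missing."""


# --------------------------------------------------------------------------
# nomenclature
# --------------------------------------------------------------------------

def _initials(gene5: str, gene3: str) -> tuple[str, str]:
    """Shortest distinct upper-case prefixes of the two gene symbols.

    Single first letters unless they collide, in which case both codes grow
    until they differ (documented collision rule)."""
    n = 1
    while gene5[:n].upper() == gene3[:n].upper() and n < min(len(gene5), len(gene3)):
        n += 1
    return gene5[:n].upper(), gene3[:n].upper()


def fusion_label(gene5: str, exon5: str, gene3: Optional[str], exon3: Optional[str],
                 region_phrase: Optional[str] = None) -> str:
    """Display string for a fusion or partnerless rearrangement.

    With both genes known: ``GENE5::GENE3 (F17A12)``-style.  Partnerless
    events render as a rearrangement phrase naming only the driver region.
    """
    if gene3 is None:
        where = region_phrase or f"after exon {exon5}"
        return f"{gene5} rearrangement ({where}), no partner gene identified"
    i5, i3 = _initials(gene5, gene3)
    return f"{gene5}::{gene3} ({i5}{exon5}{i3}{exon3})"


_LABEL_RE = re.compile(r"^(?P<g5>\S+)::(?P<g3>\S+) \((?P<code>[A-Za-z0-9]+)\)$")


def parse_fusion_label(label: str) -> tuple[str, str, str, str]:
    """Inverse of :func:`fusion_label` for two-gene labels."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ReportError(f"unparseable fusion label: {label!r}")
    g5, g3, code = m.group("g5"), m.group("g3"), m.group("code")
    i5, i3 = _initials(g5, g3)
    if not code.startswith(i5):
        raise ReportError(f"code {code!r} does not match gene initials {i5!r}")
    rest = code[len(i5):]
    m2 = re.match(rf"^(\d+){re.escape(i3)}(\d+)$", rest)
    if not m2:
        raise ReportError(f"code {code!r} does not decompose over {i5!r}/{i3!r}")
    return g5, m2.group(1), g3, m2.group(2)


def iscn_translocation(ev: BreakpointEvent) -> str:
    """ISCN-like translocation string, plus-strand genomic positions."""
    b5 = ev.breakend_5p
    if ev.breakend_3p is None:
        return f"rea({b5.chrom})({b5.pos + 1})"
    b3 = ev.breakend_3p
    return f"t({b5.chrom.removeprefix('chr')};{b3.chrom.removeprefix('chr')})" \
           f"({b5.pos + 1};{b3.pos + 1})"


def hgvs_genomic(ev: BreakpointEvent) -> str:
    """HGVS-style genomic description of the breakend join (1-based)."""
    b5 = ev.breakend_5p
    if ev.breakend_3p is None:
        return f"g.{b5.chrom}:{b5.pos + 1}_?"
    b3 = ev.breakend_3p
    return f"g.{b5.chrom}:{b5.pos + 1}::{b3.chrom}:{b3.pos + 1}"


def structured_junction(j: FusionJunction) -> dict:
    """Structured transcript/exon/offset block for each junction side."""
    def side(s):
        return {"gene": s.gene, "transcript": s.transcript_id,
                "exon": s.exon, "offset": s.offset}
    return {"five_prime": side(j.five_prime), "three_prime": side(j.three_prime)}


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------

@dataclass
class ReportMeta:
    """Assay and specimen description accompanying every report."""

    assay_description: str
    tumour_cell_content: float
    nucleic_acid_quality: str = "adequate"
    library_quality: str = "passed"
    build: Optional[str] = "hg19"


@dataclass
class ClinicalReport:
    level: str  # "RNA" | "DNA"
    assay_description: str
    quality: dict
    findings: list[dict]
    build: Optional[str] = None
    footer: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps({
            "level": self.level,
            "assay_description": self.assay_description,
            "quality": self.quality,
            "findings": self.findings,
            "build": self.build,
            "footer": self.footer,
        }, indent=1)

    def to_markdown(self) -> str:
        q = self.quality
        lines = [
            f"# Molecular {self.level} fusion report",
            "",
            f"**Assay:** {self.assay_description}",
            f"**Tumour cell content:** {q['tumour_cell_content']:.0%}  ",
            f"**Nucleic acid quality:** {q['nucleic_acid_quality']}  ",
            f"**Library quality:** {q['library_quality']}",
        ]
        if self.build:
            lines.append(f"**Reference build:** {self.build}")
        for f in self.findings:
            lines += ["", f"## {f['label']}", ""]
            for k, v in f.items():
                if k == "label":
                    continue
                lines.append(f"- {k.replace('_', ' ')}: {v}")
        if self.footer:
            lines += ["", f"*{self.footer}*"]
        return "\n".join(lines) + "\n"


RNA_MANDATORY = ("read_counts", "fusion_read_ratio", "gene_names_with_transcripts",
                 "junction_exons", "frame_and_domain_statement")
DNA_MANDATORY = ("read_counts", "translocation_read_ratio", "gene_names",
                 "breakpoint_positions", "reference_build", "frame_domain_estimate")
COMMON_MANDATORY = ("assay_description", "tumour_cell_content",
                    "nucleic_acid_quality", "library_quality")

_RATIO_FOOTER = ("Fusion-read ratio = (split + spanning) / "
                 "(split + spanning + wild-type reads at the junction).")
_CAUTION = ("Estimation from DNA sequencing: statements on reading-frame and "
            "protein-domain preservation are necessarily tentative and require "
            "RNA-level confirmation.")


def _pick_record(ann: FusionAnnotation) -> IsoformRecord:
    for r in ann.records:
        if r.driver_isoform == CANONICAL:
            return r
    return ann.records[0]


def _check_meta(meta: ReportMeta) -> None:
    missing = [f for f in ("assay_description", "tumour_cell_content") if not getattr(meta, f, None) and getattr(meta, f, None) != 0]
    if missing:
        raise ReportError(f"missing mandatory meta fields: {', '.join(missing)}")


def render_rna_report(ann: FusionAnnotation, junction: FusionJunction,
                      meta: ReportMeta) -> ClinicalReport:
    """Render the recommended RNA-level fusion report."""
    _check_meta(meta)
    missing = []
    j5, j3 = junction.five_prime, junction.three_prime
    if not j5.transcript_id or not j3.transcript_id:
        missing.append("transcript IDs for both fusion partners")
    ev = junction.evidence
    if ev.total_fusion_reads + ev.wildtype_reads_at_junction == 0:
        missing.append("read evidence (all counts zero, ratio undefined)")
    if missing:
        raise ReportError("cannot render RNA report; missing: " + "; ".join(missing))

    rec = _pick_record(ann)
    partner_known = j3.gene and not j3.gene.startswith("(")
    label = fusion_label(j5.gene, j5.exon, j3.gene if partner_known else None, j3.exon)
    frame_txt = "in-frame" if rec.frame == IN_FRAME else f"not in-frame ({rec.frame})"
    kin = "intact" if rec.kinase_retained else "lost"
    finding = {
        "label": label,
        "read_counts": f"{ev.split_reads} split / {ev.spanning_pairs} spanning pairs",
        "fusion_read_ratio": round(fusion_read_ratio(ev), 3),
        "gene_names_with_transcripts": f"{j5.gene} ({j5.transcript_id}) :: "
                                       f"{j3.gene} ({j3.transcript_id})",
        "junction_exons": f"{j5.gene} exon {j5.exon} (+{j5.offset} nt) :: "
                          f"{j3.gene} exon {j3.exon} (+{j3.offset} nt)",
        "frame_and_domain_statement": f"{frame_txt}; kinase domain {kin}; "
                                      f"mechanism: {rec.mechanism}"
                                      + (f"; lost motifs: {', '.join(rec.lost_motifs)}"
                                         if rec.lost_motifs else ""),
        "structured_junction": structured_junction(junction),
    }
    if ann.conflict:
        finding["isoform_note"] = ("interpretation differs between partner isoforms; "
                                   "all isoform-level calls are listed in the data supplement")
    return ClinicalReport(
        level="RNA",
        assay_description=meta.assay_description,
        quality={"tumour_cell_content": meta.tumour_cell_content,
                 "nucleic_acid_quality": meta.nucleic_acid_quality,
                 "library_quality": meta.library_quality},
        findings=[finding],
        build=meta.build,
        footer=_RATIO_FOOTER,
    )


def render_dna_report(ann: FusionAnnotation, event: BreakpointEvent,
                      meta: ReportMeta) -> ClinicalReport:
    """Render the recommended DNA-level translocation report."""
    _check_meta(meta)
    if not meta.build:
        raise ReportError("cannot render DNA report: reference build missing")
    if event.breakend_5p is None:
        raise ReportError("cannot render DNA report: driver breakpoint coordinates missing")
    ev = event.evidence
    if ev.total_fusion_reads + ev.wildtype_reads_at_junction == 0:
        raise ReportError("cannot render DNA report: read evidence all zero, ratio undefined")

    rec = _pick_record(ann)
    b5, b3 = event.breakend_5p, event.breakend_3p
    partnerless = b3 is None or event.insert is not None
    gene3 = None
    label = fusion_label("FGFR2", rec.localization_5p.label or "?", None, None,
                         region_phrase=rec.localization_5p.describe()) if partnerless \
        else f"FGFR2 rearrangement, partner locus {b3.chrom}:{b3.pos + 1}"
    positions = f"{b5.chrom}:{b5.pos + 1}" + ("" if b3 is None else f" ; {b3.chrom}:{b3.pos + 1}")
    estimate = f"{_CAUTION} Current estimate: mechanism {rec.mechanism}, " \
               f"kinase domain {'retained' if rec.kinase_retained else 'lost'}."
    finding = {
        "label": label,
        "read_counts": f"{ev.split_reads} split / {ev.spanning_pairs} spanning pairs",
        "translocation_read_ratio": round(fusion_read_ratio(ev), 3),
        "gene_names": "FGFR2" + ("" if partnerless else " :: partner at " + positions.split(" ; ")[1]),
        "breakpoint_positions": positions,
        "reference_build": meta.build,
        "iscn": iscn_translocation(event),
        "hgvs": hgvs_genomic(event),
        "frame_domain_estimate": estimate,
    }
    if event.insert is not None:
        finding["bridged_note"] = ("non-contiguous sequence inserted at the breakpoint; "
                                   "reported as rearrangement rather than fusion — "
                                   "RNA analysis recommended to identify the partner")
    return ClinicalReport(
        level="DNA",
        assay_description=meta.assay_description,
        quality={"tumour_cell_content": meta.tumour_cell_content,
                 "nucleic_acid_quality": meta.nucleic_acid_quality,
                 "library_quality": meta.library_quality},
        findings=[finding],
        build=meta.build,
        footer=_RATIO_FOOTER,
    )


def validate_report(report: ClinicalReport) -> list[str]:
    """Names of missing mandatory items (empty list = report passes).

    Checks the level-specific finding checklist, the common quality block,
    and — for DNA reports with an indeterminate mechanism — the mandatory
    cautious wording of the frame/domain estimate.
    """
    missing: list[str] = []
    if not report.assay_description:
        missing.append("assay_description")
    for k in ("tumour_cell_content", "nucleic_acid_quality", "library_quality"):
        if report.quality.get(k) in (None, ""):
            missing.append(k)
    required = RNA_MANDATORY if report.level == "RNA" else DNA_MANDATORY
    if not report.findings:
        missing.append("findings")
    for f in report.findings:
        for k in required:
            if k == "reference_build":
                if not report.build and not f.get(k):
                    missing.append(k)
                continue
            if f.get(k) in (None, ""):
                missing.append(k)
        if report.level == "DNA":
            est = str(f.get("frame_domain_estimate", ""))
            if "tentative" not in est and "cautio" not in est.lower():
                missing.append("cautious frame/domain wording")
    return missing
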