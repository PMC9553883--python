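"""DNA breakpoints, RNA fusion junctions and their tabular I/O.

Events enter pre-called: a :class:`BreakpointEvent` is a DNA-level
rearrangement with two breakends (the second possibly unmapped, intergenic
or ambiguous, and possibly separated by a bridging insert), while a
:class:`FusionJunction` is an RNA-level junction addressed by exon label
plus an offset from the exon boundary — the way junctions are named in
clinical practice ("after FGFR2 exon 17").

The driver gene (FGFR2) is always stored on the 5' side; ingestion
normalizes record order, and records where the driver would sit 3' are
rejected as unsupported rather than silently mishandled.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .model import GenomicInterval


class EventError(ValueError):
    """Malformed or inconsistent event input."""


PARTNER_UNMAPPED = "unmapped"
PARTNER_INTERGENIC = "intergenic"
PARTNER_AMBIGUOUS = "ambiguous"
_NO_PARTNER = (PARTNER_UNMAPPED, PARTNER_INTERGENIC, PARTNER_AMBIGUOUS)

RETAINS_LEFT = "retains-left"
RETAINS_RIGHT = "retains-right"


@dataclass(frozen=True)
class ReadEvidence:
    split_reads: int = 0
    spanning_pairs: int = 0
    wildtype_reads_at_junction: int = 0

    def __post_init__(self) -> None:
        if min(self.split_reads, self.spanning_pairs, self.wildtype_reads_at_junction) < 0:
            raise EventError("read counts must be non-negative")

    @property
    def total_fusion_reads(self) -> int:
        return self.split_reads + self.spanning_pairs


@dataclass(frozen=True)
class Breakend:
    """A single genomic breakpoint base with joining orientation.

    ``orientation`` records which side of the position remains joined to the
    partner: ``retains-left`` keeps the genomically left-of-position
    sequence, ``retains-right`` the right.
    """

    interval: GenomicInterval
    orientation: str = RETAINS_LEFT

    def __post_init__(self) -> None:
        if len(self.interval) != 1:
            raise EventError("a breakend is a single base (interval of length 1)")
        if self.orientation not in (RETAINS_LEFT, RETAINS_RIGHT):
            raise EventError(f"bad orientation {self.orientation!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def pos(self) -> int:
        return self.interval.start


@dataclass(frozen=True)
class BridgeInsert:
    """Non-contiguous sequence inserted at the breakpoint (a bridged fusion)."""

    sequence: str
    origin: Optional[GenomicInterval] = None  # mapped origin locus, if any
    repeat_family: Optional[str] = None       # e.g. "AluSx" when only repeat placements exist


@dataclass
class BreakpointEvent:
    """A DNA-level rearrangement; the driver (FGFR2) breakend is side 5'."""

    id: str
    breakend_5p: Breakend
    breakend_3p: Optional[Breakend] = None
    partner_status: str = "mapped"  # "mapped" or one of unmapped/intergenic/ambiguous
    insert: Optional[BridgeInsert] = None
    evidence: ReadEvidence = field(default_factory=ReadEvidence)

    def __post_init__(self) -> None:
        if self.breakend_3p is None and self.partner_status == "mapped":
            raise EventError(f"{self.id}: missing 3' breakend requires a partner_status flag")
        if self.partner_status not in ("mapped",) + _NO_PARTNER:
            raise EventError(f"{self.id}: bad partner_status {self.partner_status!r}")
        if self.insert and self.insert.origin and self.breakend_3p is not None:
            if self.insert.origin.overlaps(self.breakend_5p.interval) or \
               self.insert.origin.overlaps(self.breakend_3p.interval):
                raise EventError(f"{self.id}: bridge origin coincides with a breakend locus")

    @property
    def has_partner_locus(self) -> bool:
        return self.breakend_3p is not None


@dataclass(frozen=True)
class JunctionSide:
    gene: str
    transcript_id: str
    exon: str            # display exon label on that transcript
    offset: int = 0      # nt from the exon boundary (5': back from exon end; 3': into exon start)
    novel: bool = False  # transcript not present in the gene model

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise EventError("junction offsets must be >= 0")


@dataclass
class FusionJunction:
    """An RNA-level fusion junction, 5' driver side joined to 3' partner side."""

    id: str
    five_prime: JunctionSide
    three_prime: JunctionSide
    evidence: ReadEvidence = field(default_factory=ReadEvidence)
    warnings: list[str] = field(default_factory=list)


def fusion_read_ratio(ev: ReadEvidence) -> float:
    """Fraction of junction-covering reads supporting the fusion.

    (split + spanning) / (split + spanning + wild-type); undefined on
    all-zero evidence.
    """
    denom = ev.total_fusion_reads + ev.wildtype_reads_at_junction
    if denom == 0:
        raise EventError("fusion read ratio undefined: no reads at the junction")
    return ev.total_fusion_reads / denom


# --------------------------------------------------------------------------
# BEDPE I/O
# --------------------------------------------------------------------------
#
# Columns 1-10 are standard BEDPE (0-based half-open); optional extra
# columns: 11 insert sequence ("." = none), 12 insert origin
# "chrom:start-end" or repeat family "repeat:AluSx" ("." = none),
# 13 split reads, 14 spanning pairs, 15 wild-type reads.

def read_bedpe(stream, driver_gene_chrom: Optional[str] = None) -> list[BreakpointEvent]:
    """Parse BEDPE text into breakpoint events.

    A missing partner is encoded by ``chrom2 = "."``; events lacking a name
    get stable generated ids.  BEDPE strand columns map onto breakend
    orientation: "+" retains the genomically left side of the breakpoint,
    "-" the right (the convention used by SV callers for breakend joins).
    """
    text = stream.read() if hasattr(stream, "read") else stream
    events: list[BreakpointEvent] = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 10:
            raise EventError(f"BEDPE line {ln}: expected >= 10 columns, got {len(cols)}")
        c1, s1, e1, c2, s2, e2, name, _score, st1, st2 = cols[:10]
        try:
            b5 = Breakend(GenomicInterval(c1, int(s1), int(e1), "+"),
                          RETAINS_LEFT if st1 == "+" else RETAINS_RIGHT)
        except ValueError as exc:
            raise EventError(f"BEDPE line {ln}: {exc}") from None
        if c2 == ".":
            b3, status = None, PARTNER_UNMAPPED
        else:
            b3 = Breakend(GenomicInterval(c2, int(s2), int(e2), "+"),
                          RETAINS_RIGHT if st2 == "+" else RETAINS_LEFT)
            status = "mapped"
        insert = None
        if len(cols) > 10 and cols[10] not in (".", ""):
            origin = repeat = None
            if len(cols) > 11 and cols[11] not in (".", ""):
                tok = cols[11]
                if tok.startswith("repeat:"):
                    repeat = tok.split(":", 1)[1]
                else:
                    chrom, rng = tok.split(":")
                    lo, hi = rng.split("-")
                    origin = GenomicInterval(chrom, int(lo), int(hi), "+")
            insert = BridgeInsert(cols[10], origin=origin, repeat_family=repeat)
        counts = [int(x) for x in cols[12:15]] if len(cols) >= 15 else [0, 0, 0]
        ev = ReadEvidence(*counts)
        eid = name if name not in (".", "") else f"bp{ln:05d}"
        event = BreakpointEvent(eid, b5, b3, partner_status=status, insert=insert, evidence=ev)
        if driver_gene_chrom is not None and b5.chrom != driver_gene_chrom:
            # normalize: driver side must be 5'; swap if the partner column holds it
            if b3 is not None and b3.chrom == driver_gene_chrom:
                event = BreakpointEvent(eid, b3, b5, partner_status="mapped",
                                        insert=insert, evidence=ev)
            else:
                raise EventError(f"BEDPE line {ln}: neither breakend on driver chromosome")
        events.append(event)
    return events


def write_bedpe(events: Iterable[BreakpointEvent]) -> str:
    lines = []
    for ev in events:
        b5, b3 = ev.breakend_5p, ev.breakend_3p
        st1 = "+" if b5.orientation == RETAINS_LEFT else "-"
        if b3 is None:
            c2, s2, e2, st2 = ".", -1, -1, "."
        else:
            c2, s2, e2 = b3.chrom, b3.pos, b3.pos + 1
            st2 = "+" if b3.orientation == RETAINS_RIGHT else "-"
        ins = ev.insert.sequence if ev.insert else "."
        if ev.insert and ev.insert.origin:
            o = ev.insert.origin
            orig = f"{o.chrom}:{o.start}-{o.end}"
        elif ev.insert and ev.insert.repeat_family:
            orig = f"repeat:{ev.insert.repeat_family}"
        else:
            orig = "."
        e = ev.evidence
        lines.append("\t".join(map(str, [
            b5.chrom, b5.pos, b5.pos + 1, c2, s2, e2, ev.id, 0, st1, st2,
            ins, orig, e.split_reads, e.spanning_pairs, e.wildtype_reads_at_junction,
        ])))
    return "\n".join(lines) + ("\n" if lines else "")


# --------------------------------------------------------------------------
# junction TSV I/O
# --------------------------------------------------------------------------

JUNCTION_COLUMNS = ["gene5", "tx5", "exon5", "offset5",
                    "gene3", "tx3", "exon3", "offset3",
                    "split", "spanning", "wt"]


def read_junctions(stream, model=None) -> list[FusionJunction]:
    """Parse the documented junction TSV.

    Unknown transcript ids are flagged novel rather than rejected;
    evidence-free rows (split = spanning = 0) get a validation warning
    attached but are kept.
    """
    text = stream.read() if hasattr(stream, "read") else stream
    junctions: list[FusionJunction] = []
    header_seen = False
    n = 0
    for ln, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if not header_seen and cols[0] == "gene5":
            header_seen = True
            continue
        if len(cols) < 11:
            raise EventError(f"junction TSV line {ln}: expected 11 columns, got {len(cols)}")
        g5, t5, x5, o5, g3, t3, x3, o3, sp, pn, wt = cols[:11]
        try:
            o5i, o3i = int(o5), int(o3)
            ev = ReadEvidence(int(sp), int(pn), int(wt))
        except (ValueError, EventError) as exc:
            raise EventError(f"junction TSV line {ln}: {exc}") from None
        if o5i < 0 or o3i < 0:
            raise EventError(f"junction TSV line {ln}: negative offset")
        known = model.isoforms if model is not None else None
        side5 = JunctionSide(g5, t5, x5, o5i, novel=known is not None and t5 not in known)
        side3 = JunctionSide(g3, t3, x3, o3i, novel=known is not None and t3 not in known)
        n += 1
        j = FusionJunction(f"jx{n:05d}", side5, side3, evidence=ev)
        if ev.total_fusion_reads == 0:
            j.warnings.append("evidence-free call: no split or spanning reads")
        junctions.append(j)
    return junctions


def write_junctions(junctions: Iterable[FusionJunction]) -> str:
    lines = ["\t".join(JUNCTION_COLUMNS)]
    for j in junctions:
        a, b, e = j.five_prime, j.three_prime, j.evidence
        lines.append("\t".join(map(str, [
            a.gene, a.transcript_id, a.exon, a.offset,
            b.gene, b.transcript_id, b.exon, b.offset,
            e.split_reads, e.spanning_pairs, e.wildtype_reads_at_junction,
        ])))
    return "\n".join(lines) + "\n"


def event_to_json(ev) -> str:
    """JSON serialization of any event type (round-trippable for reports)."""
    def default(o):
        if isinstance(o, GenomicInterval):
            return {"chrom": o.chrom, "start": o.start, "end": o.end, "strand": o.strand}
        if hasattr(o, "__dataclass_fields__"):
            return {k: getattr(o, k) for k in o.__dataclass_fields__}
        raise TypeError(type(o))
    return json.dumps(ev, default=default, indent=1)
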