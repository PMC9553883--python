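"""Gene, transcript and protein-domain models for FGFR2 fusion annotation.

Coordinate conventions
----------------------
Genomic intervals are 0-based half-open on a stranded chromosome (BED-like);
GFF3 input (1-based inclusive) is converted on load.  cDNA and protein
coordinates are 1-based, matching HGVS display and the amino-acid numbering
used in the FGFR2 literature (kinase domain aa 481-757, YLDL motif aa
769-772 on NM_000141.4).

The packaged FGFR2 fixture uses synthetic genomic coordinates that are
mutually consistent (locus span, strand, exon counts, CDS lengths, domain
positions) rather than base-for-base RefSeq coordinates; every published
isoform-level fact is asserted at build time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

import numpy as np
from Bio.Seq import Seq


class GeneModelError(ValueError):
    """Base error for gene-model construction and parsing."""


class ParseError(GeneModelError):
    """Malformed input stream (GFF3 hierarchy, fixture JSON)."""


class ValidationError(GeneModelError):
    """Structurally parseable input that violates a model invariant."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class ProteinDomain:
    """A named protein feature at 1-based inclusive aa coordinates."""

    name: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.aa_start <= self.aa_end:
            raise ValidationError(f"bad domain bounds for {self.name}: {self.aa_start}-{self.aa_end}")


@dataclass(frozen=True)
class IntronLocation:
    """Descriptor for a position falling between two exons.

    ``index`` is the 1-based intron number in transcript order (intron k
    separates exon k from exon k+1); ``distance_to_splice`` is the distance
    in bp to the nearest flanking exon boundary.
    """

    index: int
    distance_to_splice: int


@dataclass(frozen=True)
class FlankLocation:
    """Position outside the transcript span: 'upstream' (5') or 'downstream' (3')."""

    side: str  # "upstream" | "downstream"


TranscriptPosition = Union[int, IntronLocation, FlankLocation]


@dataclass
class TranscriptIsoform:
    """Ordered exon structure of one transcript.

    ``exons`` are in transcript order (5'->3' of the mRNA): for a minus-strand
    gene genomic coordinates decrease along the list.  ``exon_labels`` are
    display labels, parent-relative for alternative isoforms so that shared
    exons keep their canonical names; ``cds_start``/``cds_end`` are 1-based
    inclusive transcript coordinates of the coding sequence including the
    stop codon.
    """

    transcript_id: str
    gene: str
    exons: list[GenomicInterval]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    sequence: Optional[str] = None
    exon_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: isoform has no exons")
        strands = {e.strand for e in self.exons}
        chroms = {e.chrom for e in self.exons}
        if len(strands) != 1 or len(chroms) != 1:
            raise ValidationError(f"{self.transcript_id}: exons span chromosomes/strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+" and not a.end <= b.start:
                raise ValidationError(f"{self.transcript_id}: exons out of transcript order (+)")
            if self.strand == "-" and not b.end <= a.start:
                raise ValidationError(f"{self.transcript_id}: exons out of transcript order (-)")
        if self.exon_labels is None:
            self.exon_labels = [str(i + 1) for i in range(len(self.exons))]
        if len(self.exon_labels) != len(self.exons):
            raise ValidationError(f"{self.transcript_id}: label/exon count mismatch")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError(f"{self.transcript_id}: cds_start/cds_end must both be set")
        if self.cds_start is not None:
            if not 1 <= self.cds_start <= self.cds_end <= self.length:
                raise ValidationError(f"{self.transcript_id}: CDS outside transcript bounds")
            if self.cds_length % 3 != 0:
                raise ValidationError(
                    f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
                )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(f"{self.transcript_id}: sequence length != exon span")

    # -- basic geometry ----------------------------------------------------

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    @property
    def cds_length(self) -> int:
        if not self.has_cds:
            return 0
        return self.cds_end - self.cds_start + 1

    @property
    def span(self) -> GenomicInterval:
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)

    def exon_offsets(self) -> list[int]:
        """Cumulative transcript length before each exon (0-based)."""
        offs, total = [], 0
        for e in self.exons:
            offs.append(total)
            total += len(e)
        return offs

    def label_to_index(self, label: str) -> int:
        """1-based local exon index for a display label."""
        try:
            return self.exon_labels.index(str(label)) + 1
        except ValueError:
            raise KeyError(f"{self.transcript_id}: no exon labelled {label!r}") from None

    def cdna_of_exon_end(self, exon_index: int) -> int:
        """1-based cDNA coordinate of the last base of exon ``exon_index`` (1-based)."""
        return self.exon_offsets()[exon_index - 1] + len(self.exons[exon_index - 1])

    def cdna_of_exon_start(self, exon_index: int) -> int:
        """1-based cDNA coordinate of the first base of exon ``exon_index``."""
        return self.exon_offsets()[exon_index - 1] + 1

    # -- protein -----------------------------------------------------------

    @property
    def cds_sequence(self) -> str:
        if not self.has_cds:
            raise ValidationError(f"{self.transcript_id}: non-coding isoform")
        if self.sequence is None:
            raise ValidationError(f"{self.transcript_id}: no sequence attached")
        return self.sequence[self.cds_start - 1 : self.cds_end]

    @property
    def protein(self) -> str:
        """Translated protein, stop codon stripped."""
        aa = str(Seq(self.cds_sequence).translate())
        return aa.rstrip("*") if aa.endswith("*") else aa


@dataclass
class GeneModel:
    """A bundle of gene loci, transcript isoforms and protein domains."""

    genes: dict[str, GenomicInterval] = field(default_factory=dict)
    isoforms: dict[str, TranscriptIsoform] = field(default_factory=dict)
    domains: dict[str, list[ProteinDomain]] = field(default_factory=dict)
    build: str = "hg19"
    # additional described exonic regions per gene (alternative promoters,
    # terminal exons) beyond the bundled isoforms' exons
    extra_exonic_regions: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def validate(self) -> None:
        for tx, iso in self.isoforms.items():
            locus = self.genes.get(iso.gene)
            if locus is None:
                raise ValidationError(f"{tx}: gene {iso.gene} has no locus")
            for e in iso.exons:
                if e.chrom != locus.chrom or e.start < locus.start or e.end > locus.end:
                    raise ValidationError(f"{tx}: exon {e} outside gene locus {locus}")
        for tx, doms in self.domains.items():
            if tx not in self.isoforms:
                raise ValidationError(f"domains reference unknown isoform {tx}")
            iso = self.isoforms[tx]
            if iso.has_cds:
                plen = protein_length(iso)
                for d in doms:
                    if d.aa_end > plen:
                        raise ValidationError(f"{tx}: domain {d.name} beyond protein end {plen}")

    def isoforms_of(self, gene: str) -> list[TranscriptIsoform]:
        return [i for i in self.isoforms.values() if i.gene == gene]

    def gene_at(self, chrom: str, pos: int) -> Optional[str]:
        """Gene symbol whose locus contains the position, or None."""
        for sym, locus in self.genes.items():
            if locus.chrom == chrom and locus.contains(pos):
                return sym
        return None

    def merge(self, other: "GeneModel") -> "GeneModel":
        out = GeneModel(build=self.build)
        out.genes = {**self.genes, **other.genes}
        out.isoforms = {**self.isoforms, **other.isoforms}
        out.domains = {**self.domains, **other.domains}
        out.extra_exonic_regions = {**self.extra_exonic_regions, **other.extra_exonic_regions}
        out.validate()
        return out

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        def iv(e: GenomicInterval):
            return [e.chrom, e.start, e.end, e.strand]

        doc = {
            "build": self.build,
            "genes": {g: iv(l) for g, l in self.genes.items()},
            "isoforms": {
                tx: {
                    "gene": iso.gene,
                    "exons": [iv(e) for e in iso.exons],
                    "labels": iso.exon_labels,
                    "cds_start": iso.cds_start,
                    "cds_end": iso.cds_end,
                    "sequence": iso.sequence,
                }
                for tx, iso in self.isoforms.items()
            },
            "domains": {
                tx: [{"name": d.name, "aa_start": d.aa_start, "aa_end": d.aa_end} for d in doms]
                for tx, doms in self.domains.items()
            },
            "extra_exonic_regions": {
                g: [iv(e) for e in regs] for g, regs in self.extra_exonic_regions.items()
            },
        }
        return json.dumps(doc, indent=1)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def protein_length(iso: TranscriptIsoform) -> int:
    """Amino-acid count of the encoded protein (stop codon excluded)."""
    if not iso.has_cds:
        raise ValidationError(f"{iso.transcript_id}: non-coding isoform has no protein length")
    return iso.cds_length // 3 - 1


def genomic_to_transcript(iso: TranscriptIsoform, pos: int, chrom: Optional[str] = None) -> TranscriptPosition:
    """Map a genomic position onto a transcript.

    Exonic positions return the 1-based cDNA coordinate (strand-aware);
    intronic positions return an :class:`IntronLocation`; positions outside
    the transcript span return a :class:`FlankLocation`.
    """
    if chrom is not None and chrom != iso.chrom:
        raise GeneModelError(f"position on {chrom}, transcript on {iso.chrom}")
    span = iso.span
    if not span.contains(pos):
        if iso.strand == "+":
            side = "upstream" if pos < span.start else "downstream"
        else:
            side = "upstream" if pos >= span.end else "downstream"
        return FlankLocation(side)
    offsets = iso.exon_offsets()
    for i, e in enumerate(iso.exons):
        if e.contains(pos):
            within = (pos - e.start) if iso.strand == "+" else (e.end - 1 - pos)
            return offsets[i] + within + 1
    # intronic: find flanking exon pair in transcript order
    for i in range(len(iso.exons) - 1)  :
        a, b = iso.exons[i], iso.exons[i + 1]
        if iso.strand == "+":
            lo, hi = a.end, b.start
        else:
            lo, hi = b.end, a.start
        if lo <= pos < hi:
            d5 = pos - lo + 1 if iso.strand == "+" else hi - pos
            d3 = hi - pos if iso.strand == "+" else pos - lo + 1
            return IntronLocation(index=i + 1, distance_to_splice=min(d5, d3))
    raise GeneModelError(f"position {pos} unmappable on {iso.transcript_id}")  # pragma: no cover


def transcript_to_genomic(iso: TranscriptIsoform, cdna_pos: int) -> int:
    """Inverse of :func:`genomic_to_transcript` for exonic positions."""
    if not 1 <= cdna_pos <= iso.length:
        raise GeneModelError(f"cDNA position {cdna_pos} outside 1..{iso.length}")
    off = cdna_pos - 1
    for e in iso.exons:
        if off < len(e):
            return e.start + off if iso.strand == "+" else e.end - 1 - off
        off -= len(e)
    raise GeneModelError("unreachable")  # pragma: no cover


def locate_motif(iso: TranscriptIsoform, motif: str) -> list[int]:
    """All 1-based aa start positions of ``motif`` in the translated protein."""
    if not motif:
        raise GeneModelError("empty motif")
    prot = iso.protein
    hits, start = [], 0
    while True:
        i = prot.find(motif, start)
        if i < 0:
            break
        hits.append(i + 1)
        start = i + 1
    return hits


def exonic_regions(model: GeneModel, gene: str) -> list[GenomicInterval]:
    """Distinct described exonic regions of a gene.

    Unions the exons of every bundled isoform with the gene's recorded
    additional alternative regions, merging overlapping intervals.
    """
    ivs = []
    for iso in model.isoforms_of(gene):
        ivs.extend(iso.exons)
    ivs.extend(model.extra_exonic_regions.get(gene, []))
    if not ivs:
        return []
    ivs = sorted(set((e.chrom, e.start, e.end, e.strand) for e in ivs), key=lambda t: (t[1], t[2]))
    merged = [list(ivs[0])]
    for c, s, e, st in ivs[1:]:
        if s < merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([c, s, e, st])
    return [GenomicInterval(c, s, e, st) for c, s, e, st in merged]


# --------------------------------------------------------------------------
# fixture construction
# --------------------------------------------------------------------------

# codon used when reverse-translating a designed protein (one fixed codon
# per residue keeps construction deterministic)
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTG", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT", "*": "TAA",
}
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def reverse_translate(protein: str, stop: bool = True) -> str:
    """Deterministic nucleotide sequence encoding ``protein`` (+ stop codon)."""
    nt = "".join(_CODON[a] for a in protein)
    return nt + _CODON["*"] if stop else nt


def random_protein(n: int, rng: np.random.Generator, forbidden: tuple[str, ...] = ()) -> str:
    """Pseudo-random protein of length n starting with M, avoiding given motifs."""
    aa = ["M"] + [_AA20[i] for i in rng.integers(0, 20, size=n - 1)]
    prot = "".join(aa)
    for m in forbidden:
        while m in prot:
            i = prot.index(m)
            repl = "A" if prot[i] != "A" else "G"
            prot = prot[:i] + repl + prot[i + 1 :]
    return prot


FGFR2_LOCUS = GenomicInterval("chr10", 123_237_843, 123_357_972, "-")

CANONICAL = "NM_000141.4"      # FGFR2 IIIc, 18 exons, 821 aa
IIIB = "NM_022970.3"           # FGFR2 IIIb, alternative exon 8, 822 aa
C3 = "NM_001144913"            # IIIb variant, no exon 1, short terminal exon, 769 aa

# transcript-order exon lengths of the canonical isoform; exon 1 is wholly
# 5'UTR, exon 18 carries 171 nt of CDS plus 200 nt 3'UTR.  Chosen so the
# CDS totals 2466 nt (821 aa + stop), the kinase domain (aa 481-757) ends
# inside exon 17, and the YLDL motif (aa 769-772) sits in exon 18.
_EXON_LENGTHS = [150, 260, 150, 160, 130, 140, 150, 145, 150, 140,
                 130, 120, 140, 130, 121, 100, 129, 371]
_UTR5 = 150
_UTR3 = 200
_ALT8_LEN = 148           # IIIb alternative exon 8 (3 nt longer -> +1 aa)
_C3_TERM_LEN = 162        # C3 terminal exon: 12 nt CDS (3 aa + stop) + 150 nt UTR
_INTRON17_LEN = 4000


def _layout_exons(lengths: list[int], locus: GenomicInterval) -> list[GenomicInterval]:
    """Place exons along the minus-strand locus, transcript order = descending genomic."""
    n_introns = len(lengths) - 1
    total_exonic = sum(lengths)
    total_intronic = len(locus) - total_exonic
    other = total_intronic - _INTRON17_LEN
    base, rem = divmod(other, n_introns - 1)
    introns = [base + (1 if i < rem else 0) for i in range(n_introns - 1)] + [_INTRON17_LEN]
    exons = []
    hi = locus.end
    for i, L in enumerate(lengths):
        exons.append(GenomicInterval(locus.chrom, hi - L, hi, locus.strand))
        if i < n_introns:
            hi = hi - L - introns[i]
    assert exons[-1].start == locus.start, "exon layout must span the locus exactly"
    return exons


def build_fgfr2_fixture() -> GeneModel:
    """Construct the packaged FGFR2 gene model.

    Encodes the published isoform facts on synthetic coordinates: the gene
    sits on the minus strand of chr10 spanning 123,237,844-123,357,972
    (hg19 labels); NM_000141.4 (IIIc) has 18 exons encoding 821 aa;
    NM_022970.3 (IIIb) differs only by an alternative eighth exon and
    encodes 822 aa; NM_001144913 (IIIb C3) lacks exon 1 and uses a shorter
    alternative terminal exon, truncating the IIIb protein by its last
    53 aa.  Domains are placed at the published aa coordinates and the
    canonical protein carries YLDL exactly once, at aa 769-772.
    """
    rng = np.random.default_rng(20220711)

    # canonical protein: pseudo-random, YLDL planted uniquely at aa 769
    p = random_protein(821, rng, forbidden=("YLDL",))
    prot_c = p[:768] + "YLDL" + p[772:]
    assert len(prot_c) == 821 and prot_c.find("YLDL") == 768 and prot_c.count("YLDL") == 1

    # IIIb: one extra residue inserted inside the exon-8-encoded segment
    prot_b = prot_c[:360] + "G" + prot_c[360:]
    assert len(prot_b) == 822

    cds_c = reverse_translate(prot_c)          # 2466 nt
    cds_b = reverse_translate(prot_b)          # 2469 nt
    utr5 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=_UTR5))
    utr3 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=_UTR3))

    exons = _layout_exons(_EXON_LENGTHS, FGFR2_LOCUS)
    labels = [str(i + 1) for i in range(18)]

    seq_c = utr5 + cds_c + utr3
    iso_c = TranscriptIsoform(CANONICAL, "FGFR2", exons, cds_start=_UTR5 + 1,
                              cds_end=_UTR5 + len(cds_c), sequence=seq_c, exon_labels=labels)

    # IIIb alternative exon 8: placed inside intron 8, 3 nt longer
    e8 = exons[7]
    alt8 = GenomicInterval(e8.chrom, e8.start - 3000 - _ALT8_LEN, e8.start - 3000, e8.strand)
    exons_b = exons[:7] + [alt8] + exons[8:]
    # shared exons carry identical sequence: cds_b differs from cds_c only by
    # the inserted codon at nt 1081-1083, which falls inside exon 8's CDS span
    assert cds_b[:1080] == cds_c[:1080] and cds_b[1083:] == cds_c[1080:]
    seq_b = utr5 + cds_b + utr3
    iso_b = TranscriptIsoform(IIIB, "FGFR2", exons_b, cds_start=_UTR5 + 1,
                              cds_end=_UTR5 + len(cds_b), sequence=seq_b, exon_labels=labels)

    # C3: IIIb exons 2..17 plus a short alternative terminal exon in intron 17.
    # Lacking exon 1 removes the 5'UTR, so its CDS starts at transcript nt 1.
    e17 = exons[16]
    c3term = GenomicInterval(e17.chrom, e17.start - 1000 - _C3_TERM_LEN, e17.start - 1000, e17.strand)
    exons_c3 = exons_b[1:17] + [c3term]
    prot_c3 = prot_b[:769]                    # IIIb minus its last 53 aa
    cds_c3 = reverse_translate(prot_c3)       # 2310 nt
    utr3_c3 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=_C3_TERM_LEN - 12))
    seq_c3 = cds_c3 + utr3_c3
    iso_c3 = TranscriptIsoform(C3, "FGFR2", exons_c3, cds_start=1, cds_end=len(cds_c3),
                               sequence=seq_c3,
                               exon_labels=labels[1:17] + ["18"])
    # the first 2298 nt of the C3 CDS are exactly the IIIb CDS through exon 17
    assert cds_c3[:2298] == cds_b[:2298]

    domains = {
        CANONICAL: [
            ProteinDomain("Ig-like I", 43, 115),
            ProteinDomain("heparin-binding", 162, 178),
            ProteinDomain("Ig-like II", 172, 248),
            ProteinDomain("Ig-like III", 264, 359),
            ProteinDomain("transmembrane", 371, 401),
            ProteinDomain("kinase", 481, 757),
            ProteinDomain("YLDL", 769, 772),
        ],
        IIIB: [
            ProteinDomain("Ig-like I", 43, 115),
            ProteinDomain("heparin-binding", 162, 178),
            ProteinDomain("Ig-like II", 172, 248),
            ProteinDomain("Ig-like III", 264, 360),
            ProteinDomain("transmembrane", 372, 402),
            ProteinDomain("kinase", 482, 758),
            ProteinDomain("YLDL", 770, 773),
        ],
        C3: [
            ProteinDomain("Ig-like I", 43, 115),
            ProteinDomain("heparin-binding", 162, 178),
            ProteinDomain("Ig-like II", 172, 248),
            ProteinDomain("Ig-like III", 264, 360),
            ProteinDomain("transmembrane", 372, 402),
            ProteinDomain("kinase", 482, 758),
        ],
    }

    # further described alternative exonic regions (alternative promoters,
    # internal and terminal exons) bringing the union to 26 regions
    extra = []
    def _place(below_exon: int, gap: int, length: int) -> GenomicInterval:
        e = exons[below_exon - 1]
        return GenomicInterval(e.chrom, e.start - gap - length, e.start - gap, e.strand)
    extra.append(_place(1, 1500, 180))     # alternative first exon a
    extra.append(_place(1, 3500, 140))     # alternative first exon b
    extra.append(_place(2, 2000, 110))     # alternative internal exon (intron 2)
    extra.append(_place(9, 2000, 120))     # alternative internal exon (intron 9)
    extra.append(_place(16, 2000, 100))    # alternative internal exon (intron 16)
    extra.append(_place(17, 2500, 120))    # C2 alternative terminal exon (intron 17)

    model = GeneModel(
        genes={"FGFR2": FGFR2_LOCUS},
        isoforms={CANONICAL: iso_c, IIIB: iso_b, C3: iso_c3},
        domains=domains,
        build="hg19",
        extra_exonic_regions={"FGFR2": extra},
    )
    model.validate()

    # build-time assertions of the published facts
    assert iso_c.n_exons == 18
    assert protein_length(iso_c) == 821
    assert protein_length(iso_b) == 822
    assert protein_length(iso_c3) == 822 - 53
    assert locate_motif(iso_c, "YLDL") == [769]
    assert len(exonic_regions(model, "FGFR2")) == 26
    return model


def build_toy_gene(
    gene: str,
    chrom: str,
    start: int,
    strand: str,
    exon_cds_lengths: list[int],
    protein_seed: int,
    utr5: int = 100,
    utr3: int = 150,
    intron_len: int = 2000,
    transcript_id: Optional[str] = None,
    extra_utr5_exon: bool = False,
) -> tuple[GenomicInterval, TranscriptIsoform]:
    """Build a small single-isoform coding gene at synthetic coordinates.

    ``exon_cds_lengths`` are the CDS nt contributed by each exon (must sum
    to a multiple of 3); the first exon additionally carries ``utr5`` nt of
    5'UTR and the last ``utr3`` nt of 3'UTR.  With ``extra_utr5_exon`` a
    wholly non-coding first exon of ``utr5`` nt is prepended instead and the
    CDS starts at the second exon (models genes whose canonical start codon
    sits downstream of a non-coding leader exon).
    """
    total_cds = sum(exon_cds_lengths)
    if (total_cds + 3) % 3 != 0:
        raise ValidationError("exon CDS lengths must sum to a codon multiple")
    rng = np.random.default_rng(protein_seed)
    n_aa = (total_cds + 3) // 3 - 1
    prot = random_protein(n_aa + 1, rng, forbidden=("YLDL",))[: n_aa]
    cds = reverse_translate(prot)
    assert len(cds) == total_cds + 3
    # distribute: append the stop codon to the last exon
    lens = list(exon_cds_lengths)
    lens[-1] += 3
    if extra_utr5_exon:
        exon_lengths = [utr5] + lens[:-1] + [lens[-1] + utr3]
        cds_start = utr5 + 1
    else:
        exon_lengths = [lens[0] + utr5] + lens[1:-1] + [lens[-1] + utr3]
        cds_start = utr5 + 1
    # stop-rich 5'UTR (terminators in all three frames), so read-through from
    # an upstream fusion partner into retained UTR always terminates
    seq5 = ("TTAA" * (utr5 // 4 + 1))[:utr5]
    seq3 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=utr3))
    seq = seq5 + cds + seq3

    exons = []
    if strand == "+":
        pos = start
        for L in exon_lengths:
            exons.append(GenomicInterval(chrom, pos, pos + L, strand))
            pos += L + intron_len
        lo, hi = start, exons[-1].end
    else:
        pos = start  # start == genomic end of the gene for minus strand
        for L in exon_lengths:
            exons.append(GenomicInterval(chrom, pos - L, pos, strand))
            pos -= L + intron_len
        lo, hi = exons[-1].start, start
    tx = transcript_id or f"NM_{gene}.1"
    iso = TranscriptIsoform(tx, gene, exons, cds_start=cds_start,
                            cds_end=cds_start + len(cds) - 1, sequence=seq)
    locus = GenomicInterval(chrom, lo, hi, strand)
    return locus, iso


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def load_gene_model(stream) -> GeneModel:
    """Load a gene model from fixture JSON or GFF3 text.

    Accepts a file-like object or a string.  JSON input must follow the
    schema written by :meth:`GeneModel.to_json`; GFF3 input must contain a
    gene/mRNA/exon/CDS feature hierarchy with ID/Parent attributes
    (1-based inclusive coordinates, converted on load).
    """
    text = stream.read() if hasattr(stream, "read") else stream
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return _load_fixture_json(text)
    return _load_gff3(text)


def _load_fixture_json(text: str) -> GeneModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ParseError(f"fixture JSON malformed: {e}") from None
    model = GeneModel(build=doc.get("build", "unknown"))
    for g, (c, s, e, st) in doc.get("genes", {}).items():
        model.genes[g] = GenomicInterval(c, s, e, st)
    for tx, rec in doc.get("isoforms", {}).items():
        exons = [GenomicInterval(c, s, e, st) for c, s, e, st in rec["exons"]]
        model.isoforms[tx] = TranscriptIsoform(
            tx, rec["gene"], exons, cds_start=rec.get("cds_start"),
            cds_end=rec.get("cds_end"), sequence=rec.get("sequence"),
            exon_labels=rec.get("labels"),
        )
    for tx, doms in doc.get("domains", {}).items():
        model.domains[tx] = [ProteinDomain(d["name"], d["aa_start"], d["aa_end"]) for d in doms]
    for g, regs in doc.get("extra_exonic_regions", {}).items():
        model.extra_exonic_regions[g] = [GenomicInterval(c, s, e, st) for c, s, e, st in regs]
    model.validate()
    return model


def _prescan_gff3(text: str) -> None:
    """Line-numbered sanity check of column counts and the feature hierarchy."""
    ids_seen: set[str] = set()
    for ln, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) < 9:
            raise ParseError(f"GFF3 line {ln}: expected 9 tab-separated columns")
        ftype, attr = cols[2], cols[8]
        a = dict(p.split("=", 1) for p in attr.strip().split(";") if "=" in p)
        if ftype == "gene":
            ids_seen.add(a.get("ID", ""))
        elif ftype in ("mRNA", "transcript", "exon", "CDS"):
            parent = a.get("Parent")
            if parent is None or parent not in ids_seen:
                raise ParseError(f"GFF3 line {ln}: {ftype} has unknown Parent {parent!r}")
            if ftype in ("mRNA", "transcript"):
                ids_seen.add(a.get("ID", ""))


def _load_gff3(text: str) -> GeneModel:
    import gffutils

    _prescan_gff3(text)
    try:
        db = gffutils.create_db(text, dbfn=":memory:", from_string=True,
                                merge_strategy="create_unique", keep_order=True)
    except Exception as e:  # gffutils raises assorted types on malformed input
        raise ParseError(f"GFF3 parse failed: {e}") from None

    model = GeneModel(build="unknown")
    gene_sym: dict[str, str] = {}
    for g in db.features_of_type("gene"):
        sym = (g.attributes.get("Name") or g.attributes.get("gene_name") or [g.id])[0]
        gene_sym[g.id] = sym
        model.genes[sym] = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)

    for ftype in ("mRNA", "transcript"):
        for m in db.features_of_type(ftype):
            tx = (m.attributes.get("transcript_id") or [m.id])[0]
            parent = m.attributes["Parent"][0]
            sym = gene_sym.get(parent, parent)
            ex = [GenomicInterval(c.seqid, c.start - 1, c.end, c.strand)
                  for c in db.children(m, featuretype="exon")]
            if not ex:
                raise ValidationError(f"mRNA {tx} has no exon features")
            ex.sort(key=lambda e: e.start, reverse=(m.strand == "-"))
            iso = TranscriptIsoform(tx, sym, ex)
            cds_ivs = [GenomicInterval(c.seqid, c.start - 1, c.end, c.strand)
                       for c in db.children(m, featuretype="CDS")]
            if cds_ivs:
                total = sum(len(c) for c in cds_ivs)
                if total % 3 != 0:
                    raise ValidationError(f"mRNA {tx}: CDS length {total} not divisible by 3")
                gstart = min(c.start for c in cds_ivs)
                gend = max(c.end for c in cds_ivs)
                p5 = gstart if m.strand == "+" else gend - 1
                c1 = genomic_to_transcript(iso, p5)
                if not isinstance(c1, int):
                    raise ValidationError(f"mRNA {tx}: CDS start not exonic")
                iso = TranscriptIsoform(tx, sym, ex, cds_start=c1, cds_end=c1 + total - 1,
                                        exon_labels=iso.exon_labels)
            model.isoforms[tx] = iso
    model.validate()
    return model
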