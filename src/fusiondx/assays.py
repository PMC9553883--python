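"""Declarative models of six diagnostic assay classes and their evaluators.

The assay classes compared are break-apart FISH (BA), dual-fusion FISH,
the 5'/3' transcript imbalance assay, amplicon-based RNA NGS (closed
primer pairs), single-primer-extension RNA NGS (SPE, anchored multiplex
PCR) and hybrid-capture NGS (HyCa) at DNA or RNA level.  Each evaluator
takes one event (DNA breakpoint, RNA junction, or molecule counts for the
imbalance assay) plus a design and returns an :class:`AssayVerdict`
stating whether the event is detected, how far the partner is resolved,
and whether frame and expression can be read off the assay.

Detection spectra nest by construction: with a shared driver-side primer
configuration every junction an amplicon design detects is detected by
SPE, and every junction SPE detects is detected by RNA hybrid capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import pandas as pd
from intervaltree import IntervalTree

from .cohort import SimulatedCase
from .events import BreakpointEvent, FusionJunction
from .model import CANONICAL, GeneModel, GenomicInterval


class AssayError(ValueError):
    pass


# partner resolution levels
SPECIFIC = "specific"
AGNOSTIC_IDENTIFIED = "agnostic_identified"
AGNOSTIC_UNIDENTIFIED = "agnostic_unidentified"
RESOLUTION_NONE = "none"

# failure modes
FAIL_NONE = "none"
NOT_COVERED = "not_covered"
CLOSE_PROXIMITY = "close_proximity"
PARTNER_NOT_IN_DESIGN = "partner_not_in_design"
BRIDGED_UNRESOLVED = "bridged_unresolved"
BELOW_THRESHOLD = "below_threshold"
WRONG_PARTNER = "wrong_partner"


@dataclass(frozen=True)
class AssayVerdict:
    detected: bool
    partner_resolution: str = RESOLUTION_NONE
    frame_determinable: bool = False
    expression_assessed: bool = False
    failure_mode: str = FAIL_NONE

    def __post_init__(self) -> None:
        if not self.detected and self.failure_mode == FAIL_NONE:
            raise AssayError("an undetected event must carry a failure mode")


MISSED = AssayVerdict(False, failure_mode=NOT_COVERED)


# --------------------------------------------------------------------------
# designs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BAFishDesign:
    """Break-apart FISH: two probes flanking the driver locus.

    ``resolution_bp`` is the minimum genomic separation between the
    rearranged partner locus and the probe pair needed for the two colour
    signals to split visibly (interphase-FISH scale; default 1 Mb)."""

    probe_5p: GenomicInterval
    probe_3p: GenomicInterval
    resolution_bp: int = 1_000_000
    name: str = "BA-FISH"


@dataclass(frozen=True)
class DualFishDesign:
    """Dual-fusion FISH: driver probe plus one specific partner probe."""

    partner_gene: str
    partner_probe: GenomicInterval
    driver_probe: GenomicInterval
    name: str = "Dual-FISH"


@dataclass(frozen=True)
class ImbalanceDesign:
    """5'/3' transcript-end imbalance assay on the driver transcript."""

    exons_5p: frozenset
    exons_3p: frozenset
    ratio_threshold: float = 0.5
    name: str = "Imbalance"


@dataclass(frozen=True)
class AmpliconDesign:
    """Closed amplicon panel: driver-exon primers paired with specific
    partner-exon primers; anything outside the primer table is invisible."""

    driver_primers: frozenset
    partner_primers: dict
    name: str = "Amplicon"


@dataclass(frozen=True)
class SPEDesign:
    """Anchored multiplex PCR with one driver-specific primer per exon,
    designed on one isoform; partner side is read from the sequence."""

    driver_primers: frozenset
    design_isoform: str = CANONICAL
    name: str = "SPE"


@dataclass(frozen=True)
class HyCaDesign:
    """Hybrid capture at DNA level (genomic probe tiling) or RNA level
    (captured driver exon set); captures regardless of what follows."""

    level: str                                   # "DNA" | "RNA"
    probes: tuple = ()                           # DNA: GenomicIntervals
    captured_exons: Optional[frozenset] = None   # RNA: driver exon labels
    name: str = "HyCa"

    def __post_init__(self) -> None:
        if self.level not in ("DNA", "RNA"):
            raise AssayError(f"bad HyCa level {self.level!r}")


AssayDesign = Union[BAFishDesign, DualFishDesign, ImbalanceDesign,
                    AmpliconDesign, SPEDesign, HyCaDesign]


# --------------------------------------------------------------------------
# evaluators
# --------------------------------------------------------------------------

def _gene_tree(model: GeneModel) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for sym, locus in model.genes.items():
        trees.setdefault(locus.chrom, IntervalTree()).addi(locus.start, locus.end, sym)
    return trees


def _gene_at(model: GeneModel, chrom: str, pos: int,
             trees: Optional[dict] = None) -> Optional[str]:
    if trees is None:
        return model.gene_at(chrom, pos)
    hits = trees.get(chrom, IntervalTree())[pos]
    return next(iter(hits)).data if hits else None


def evaluate_ba_fish(event: Optional[BreakpointEvent], d: BAFishDesign,
                     model: GeneModel, driver_gene: str = "FGFR2") -> AssayVerdict:
    """Break-apart FISH verdict for one DNA event.

    Detection requires the driver breakend between the probes and the
    rearranged partner locus at least ``resolution_bp`` away from the probe
    pair.  Driver-internal events (3' deletions) cannot split the signals;
    partners within the resolution distance give close-proximity false
    negatives.  An unmapped partner is assumed distant: hybridisation does
    not care whether sequencing resolved it.
    """
    if event is None:
        return MISSED
    lo = min(d.probe_5p, d.probe_3p, key=lambda p: p.start)
    hi = max(d.probe_5p, d.probe_3p, key=lambda p: p.start)
    b5 = event.breakend_5p
    if b5.chrom != lo.chrom or not (lo.end <= b5.pos < hi.start):
        return MISSED
    detected = AssayVerdict(True, AGNOSTIC_UNIDENTIFIED)
    b3 = event.breakend_3p
    if b3 is None:
        return detected
    if b3.chrom != lo.chrom:
        return detected
    dist = min(_interval_distance(b3.pos, d.probe_5p), _interval_distance(b3.pos, d.probe_3p))
    partner = model.gene_at(b3.chrom, b3.pos)
    if partner == driver_gene or (partner is None and dist < d.resolution_bp):
        # deletion or local event wholly inside the probe footprint
        return MISSED
    if dist < d.resolution_bp:
        return AssayVerdict(False, failure_mode=CLOSE_PROXIMITY)
    return detected


def _interval_distance(pos: int, iv: GenomicInterval) -> int:
    if iv.contains(pos):
        return 0
    return iv.start - pos if pos < iv.start else pos - iv.end + 1


def evaluate_dual_fish(event: Optional[BreakpointEvent], d: DualFishDesign,
                       model: GeneModel) -> AssayVerdict:
    """Dual-fusion FISH: detects only rearrangements with the designed partner."""
    if event is None:
        return MISSED
    b3 = event.breakend_3p
    if b3 is None:
        return MISSED
    if b3.chrom == d.partner_probe.chrom and d.partner_probe.contains(b3.pos):
        return AssayVerdict(True, SPECIFIC)
    return AssayVerdict(False, failure_mode=WRONG_PARTNER)


def evaluate_imbalance(counts_5p: int, counts_3p: int, d: ImbalanceDesign) -> AssayVerdict:
    """5'/3' imbalance: detects a 3'-end deficit, blind to its cause.

    Fires on fusions and on 3' deletions alike (the verdict shape is
    identical, so the two cannot be told apart), never resolves a partner
    and never determines frame.
    """
    if counts_5p <= 0:
        return AssayVerdict(False, failure_mode=BELOW_THRESHOLD)
    ratio = counts_3p / counts_5p
    if ratio < d.ratio_threshold:
        return AssayVerdict(True, RESOLUTION_NONE, expression_assessed=True)
    return AssayVerdict(False, failure_mode=BELOW_THRESHOLD)


def evaluate_amplicon(j: Optional[FusionJunction], d: AmpliconDesign) -> AssayVerdict:
    """Closed amplicon panel: both sides must carry a designed primer."""
    if j is None:
        return MISSED
    if j.five_prime.exon not in d.driver_primers:
        return MISSED
    exons = d.partner_primers.get(j.three_prime.gene)
    if exons is None or j.three_prime.exon not in exons:
        return AssayVerdict(False, failure_mode=PARTNER_NOT_IN_DESIGN)
    return AssayVerdict(True, SPECIFIC, frame_determinable=True, expression_assessed=True)


def evaluate_spe(j: Optional[FusionJunction], d: SPEDesign, model: GeneModel) -> AssayVerdict:
    """Anchored multiplex PCR: one driver primer, partner-agnostic readout.

    The driver junction exon must carry a primer and exist on the design
    isoform; the partner (known gene, novel or intergenic sequence) is then
    read from the extension product.
    """
    if j is None:
        return MISSED
    iso = model.isoforms.get(d.design_isoform)
    if iso is None:
        raise AssayError(f"design isoform {d.design_isoform} not in model")
    try:
        iso.label_to_index(j.five_prime.exon)
    except KeyError:
        return MISSED  # junction exon absent from the design isoform
    if j.five_prime.exon not in d.driver_primers:
        return MISSED
    return AssayVerdict(True, AGNOSTIC_IDENTIFIED, frame_determinable=True,
                        expression_assessed=True)


def evaluate_hyca(item: Union[BreakpointEvent, FusionJunction, None], d: HyCaDesign,
                  model: GeneModel, driver_gene: str = "FGFR2") -> AssayVerdict:
    """Hybrid capture at DNA or RNA level.

    DNA level: the driver breakend must fall inside a probe-tiled interval
    (intron 17 must be tiled wall-to-wall); the partner is identified when
    the non-driver side maps uniquely inside an annotated gene body, while
    bridged inserts (mapping to a third locus or only to repeat families)
    leave the alteration detected but reported as a rearrangement without a
    partner.  RNA level: every expressed junction whose driver exon is
    captured is detected, with frame and expression readable.
    """
    if item is None:
        return MISSED
    if d.level == "DNA":
        if not isinstance(item, BreakpointEvent):
            raise AssayError("DNA-level hybrid capture evaluates breakpoint events")
        b5 = item.breakend_5p
        if not any(p.chrom == b5.chrom and p.contains(b5.pos) for p in d.probes):
            return MISSED
        ins = item.insert
        if ins is not None and (ins.repeat_family is not None or ins.origin is not None) \
                and len(ins.sequence) >= 10:
            return AssayVerdict(True, AGNOSTIC_UNIDENTIFIED,
                                failure_mode=BRIDGED_UNRESOLVED)
        b3 = item.breakend_3p
        if b3 is None:
            return AssayVerdict(True, AGNOSTIC_UNIDENTIFIED)
        partner = model.gene_at(b3.chrom, b3.pos)
        if partner is None:
            return AssayVerdict(True, AGNOSTIC_UNIDENTIFIED)
        return AssayVerdict(True, AGNOSTIC_IDENTIFIED)
    # RNA level
    if not isinstance(item, FusionJunction):
        raise AssayError("RNA-level hybrid capture evaluates fusion junctions")
    if d.captured_exons is None or item.five_prime.exon not in d.captured_exons:
        return MISSED
    return AssayVerdict(True, AGNOSTIC_IDENTIFIED, frame_determinable=True,
                        expression_assessed=True)


# --------------------------------------------------------------------------
# bundled designs
# --------------------------------------------------------------------------

def default_designs(model: GeneModel, driver_gene: str = "FGFR2") -> dict[str, AssayDesign]:
    """The bundled assay designs used for cohort evaluation.

    BA-FISH probes flank the driver locus (~200 kb each, 1 Mb resolution);
    dual FISH targets BICC1; the imbalance assay compares driver exons 1-8
    vs 17-18 at a 0.5 ratio cutoff; the amplicon panel pairs driver exons
    17/18 with a small partner-exon table (CCDC6 exons 1-2, BICC1 2-3);
    SPE carries primers on canonical exons 16-18; DNA hybrid capture tiles
    exon 17 through exon 18 wall-to-wall; RNA hybrid capture captures all
    driver exons.
    """
    locus = model.genes[driver_gene]
    iso = model.isoforms[CANONICAL]
    e17, e18 = iso.exons[16], iso.exons[17]
    probe_5p = GenomicInterval(locus.chrom, locus.end + 1000, locus.end + 201_000, locus.strand)
    probe_3p = GenomicInterval(locus.chrom, locus.start - 201_000, locus.start - 1000, locus.strand)
    bicc1 = model.genes["BICC1"]
    return {
        "BA-FISH": BAFishDesign(probe_5p, probe_3p),
        "Dual-FISH": DualFishDesign("BICC1",
                                    GenomicInterval(bicc1.chrom, bicc1.start - 50_000,
                                                    bicc1.end + 50_000, bicc1.strand),
                                    GenomicInterval(locus.chrom, locus.start, locus.end,
                                                    locus.strand)),
        "Imbalance": ImbalanceDesign(frozenset(map(str, range(1, 9))),
                                     frozenset({"17", "18"})),
        "Amplicon": AmpliconDesign(frozenset({"17", "18"}),
                                   {"CCDC6": frozenset({"1", "2"}),
                                    "BICC1": frozenset({"2", "3"})}),
        "SPE": SPEDesign(frozenset({"16", "17", "18"})),
        "HyCa-DNA": HyCaDesign("DNA", probes=(
            GenomicInterval(locus.chrom, e18.start, e17.end, locus.strand),)),
        "HyCa-RNA": HyCaDesign("RNA", captured_exons=frozenset(iso.exon_labels)),
    }


def probe_bed(d: HyCaDesign) -> str:
    """BED export of a DNA hybrid-capture probe tiling."""
    if d.level != "DNA":
        raise AssayError("BED export applies to DNA-level designs")
    return "".join(f"{p.chrom}\t{p.start}\t{p.end}\t{d.name}\n" for p in d.probes)


# --------------------------------------------------------------------------
# cohort-level evaluation
# --------------------------------------------------------------------------

def evaluate_case(design: AssayDesign, case: SimulatedCase, model: GeneModel) -> AssayVerdict:
    """Route one simulated case to the evaluator matching the design class."""
    if isinstance(design, BAFishDesign):
        return evaluate_ba_fish(case.event, design, model)
    if isinstance(design, DualFishDesign):
        return evaluate_dual_fish(case.event, design, model)
    if isinstance(design, ImbalanceDesign):
        return evaluate_imbalance(case.counts_5p, case.counts_3p, design)
    if isinstance(design, AmpliconDesign):
        return evaluate_amplicon(case.junction, design)
    if isinstance(design, SPEDesign):
        return evaluate_spe(case.junction, design, model)
    if isinstance(design, HyCaDesign):
        return evaluate_hyca(case.event if design.level == "DNA" else case.junction,
                             design, model)
    raise AssayError(f"unknown design type {type(design).__name__}")


def cohort_coverage(cases: list[SimulatedCase], designs: dict[str, AssayDesign],
                    model: GeneModel) -> tuple[pd.Series, pd.DataFrame]:
    """Detected fraction per design plus the per-event verdict matrix."""
    if not cases:
        raise AssayError("empty cohort")
    verdicts = {
        name: [evaluate_case(d, c, model) for c in cases]
        for name, d in designs.items()
    }
    matrix = pd.DataFrame(
        {name: [v.detected for v in vs] for name, vs in verdicts.items()},
        index=[c.id for c in cases],
    )
    fractions = matrix.mean(axis=0)
    fractions.name = "detected_fraction"
    return fractions, matrix


def capability_matrix(scenarios: dict[str, SimulatedCase],
                      designs: dict[str, AssayDesign],
                      model: GeneModel) -> pd.DataFrame:
    """Scenario-by-assay verdict matrix (the assay-comparison overview).

    Rows are the canonical scenarios (wild-type first, as negative
    control); cells hold :class:`AssayVerdict` objects.
    """
    rows = {}
    for label, case in scenarios.items():
        rows[label] = {name: evaluate_case(d, case, model) for name, d in designs.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def matrix_to_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Human-readable rendering of a verdict matrix (one symbol per cell)."""
    def cell(v: AssayVerdict) -> str:
        if v.detected:
            extra = "" if v.failure_mode == FAIL_NONE else f" ({v.failure_mode})"
            return f"detected [{v.partner_resolution}]{extra}"
        return f"missed ({v.failure_mode})"
    return matrix.map(cell)
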