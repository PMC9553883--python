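"""Isoform-dependent frame ambiguity: a KCTD1-like DNA breakpoint.

The toy KCTD1 gene has two isoforms with different start codons.  The same
DNA breakpoint lies upstream of the canonical isoform's transcript (so the
fusion cannot reach a partner ORF -> C-terminal truncation) but in
intron 1 of the alternative isoform (in-frame -> enhanced dimerisation).
Without RNA data the two hypotheses cannot be separated, which is why
per-isoform records with a conflict flag are reported instead of a single
collapsed verdict.
"""

from fusiondx import annotate_event, build_reference_model
from fusiondx.cohort import KCTD1_ALT, KCTD1_CANONICAL
from fusiondx.events import Breakend, BreakpointEvent, ReadEvidence
from fusiondx.model import CANONICAL, GenomicInterval

model, catalog = build_reference_model()
iso = model.isoforms[CANONICAL]
e17, e18 = iso.exons[16], iso.exons[17]
b5 = Breakend(GenomicInterval("chr10", (e18.end + e17.start) // 2,
                              (e18.end + e17.start) // 2 + 1, "+"))
alt = model.isoforms[KCTD1_ALT]
can = model.isoforms[KCTD1_CANONICAL]
pos = (alt.exons[0].end + can.exons[0].start) // 2
b3 = Breakend(GenomicInterval("chr18", pos, pos + 1, "+"))

ev = BreakpointEvent("kctd1_case", b5, b3, evidence=ReadEvidence(22, 14, 90))
ann = annotate_event(ev, model, catalog)
for r in ann.records:
    if r.driver_isoform == CANONICAL:
        print(f"vs {r.partner_isoform}: frame={r.frame:10s} mechanism={r.mechanism}")
print("conflict flag:", ann.conflict)
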