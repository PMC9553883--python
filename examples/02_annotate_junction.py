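"""Annotate an RNA fusion junction: the FGFR2::ATE1 (F17A12) case.

An in-frame junction after FGFR2 exon 17 into ATE1 exon 12 keeps the
kinase domain but loses the C-terminal YLDL motif; because ATE1
contributes no dimerisation domain, the oncogenic mechanism is C-terminal
truncation.
"""

from fusiondx import annotate_event, build_reference_model, fusion_label
from fusiondx.events import FusionJunction, JunctionSide, ReadEvidence
from fusiondx.model import CANONICAL

model, catalog = build_reference_model()
j = FusionJunction(
    "F17A12",
    JunctionSide("FGFR2", CANONICAL, "17", 0),
    JunctionSide("ATE1", "NM_ATE1.1", "12", 0),
    evidence=ReadEvidence(40, 25, 120),
)
ann = annotate_event(j, model, catalog)
rec = ann.record_for(CANONICAL)
print(fusion_label("FGFR2", "17", "ATE1", "12"))
print("frame:", rec.frame)
print("kinase retained:", rec.kinase_retained,
      "| retained FGFR2 aa:", rec.retained_driver_aa)
print("mechanism:", rec.mechanism, "| lost motifs:", rec.lost_motifs)
print("oncogenically competent:", rec.competent)
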