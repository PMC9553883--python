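"""Render clinical RNA and DNA reports and validate the mandatory fields.

The RNA report carries read counts, the fusion-read ratio, gene names with
transcript IDs, junction exons and a frame/domain statement; the DNA
report adds breakpoint coordinates, the reference build, and the mandatory
cautious wording for frame estimates made without RNA evidence.
"""

from fusiondx import annotate_event, build_reference_model
from fusiondx.cohort import canonical_scenarios
from fusiondx.reporting import (
    ReportMeta, render_dna_report, render_rna_report, validate_report,
)

model, catalog = build_reference_model()
scen = canonical_scenarios(model)
meta = ReportMeta("RNA hybrid-capture NGS, 50 ng input", tumour_cell_content=0.45)

case = scen["known partner"]
rna = render_rna_report(annotate_event(case.junction, model, catalog),
                        case.junction, meta)
print(rna.to_markdown())
print("RNA checklist missing fields:", validate_report(rna) or "none")

bridged = scen["intergenic"]
dna = render_dna_report(annotate_event(bridged.event, model, catalog),
                        bridged.event, meta)
print("DNA checklist missing fields:", validate_report(dna) or "none")
print("DNA frame wording:", dna.findings[0]["frame_domain_estimate"][:80], "...")
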