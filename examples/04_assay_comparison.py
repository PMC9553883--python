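"""Theoretical assay performance on the canonical scenario set.

Evaluates the bundled designs of all six assay classes against seven
canonical fusion scenarios (wild-type negative control, known/unknown
partner, out-of-frame, intergenic, close-proximity partner, 3' deletion)
and prints the verdict matrix: which assay detects what, and why the
misses happen (close_proximity, partner_not_in_design, ...).
"""

import pandas as pd

from fusiondx import build_reference_model, capability_matrix, default_designs
from fusiondx.assays import matrix_to_table
from fusiondx.cohort import canonical_scenarios

pd.set_option("display.width", 200)
model, _ = build_reference_model()
designs = default_designs(model)
cap = capability_matrix(canonical_scenarios(model), designs, model)
print(matrix_to_table(cap).to_string())
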