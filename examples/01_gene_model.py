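"""FGFR2 gene model: isoform arithmetic and coordinate mapping.

Builds the packaged FGFR2 fixture (three isoforms on the minus strand of
chr10) and prints the isoform-level facts a fusion annotator depends on:
exon counts, protein lengths, the position of the YLDL internalisation
motif, and a genomic->transcript lookup for an intronic breakpoint.
"""

from fusiondx.model import (
    C3, CANONICAL, IIIB,
    build_fgfr2_fixture, exonic_regions, genomic_to_transcript,
    locate_motif, protein_length,
)

model = build_fgfr2_fixture()
for tx in (CANONICAL, IIIB, C3):
    iso = model.isoforms[tx]
    print(f"{tx:>14}: {iso.n_exons:2d} exons, {protein_length(iso)} aa")

iso = model.isoforms[CANONICAL]
print("YLDL motif at aa", locate_motif(iso, "YLDL"))
print("described exonic regions:", len(exonic_regions(model, "FGFR2")))

# a breakpoint between exons 17 and 18 lands in intron 17 — the hotspot
e17, e18 = iso.exons[16], iso.exons[17]
pos = (e18.end + e17.start) // 2
print(f"genomic {pos} ->", genomic_to_transcript(iso, pos))
# The printed intron index (17) is what makes such a breakpoint retain the
# complete kinase domain (aa 481-757) while losing the YLDL motif.
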