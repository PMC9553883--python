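# fusiondx

Isoform-aware annotation of *FGFR2* gene fusions and in-silico evaluation
of the diagnostic assays used to detect them.

*FGFR2* fusions are the key targetable alteration in intrahepatic
cholangiocarcinoma (iCCA). *FGFR2* is invariably the 5′ partner, with DNA
breakpoints concentrated in exon 17 / intron 17 / exon 18 — downstream of
the tyrosine-kinase domain (aa 481–757, NM_000141.4) — joined to a long
tail of heterogeneous 3′ partner genes. Whether such a rearrangement is
oncogenic, and whether a given assay can see it, depends on fine
transcript-level detail: which isoform is used for annotation, whether the
junction is in frame, whether the kinase domain survives, and whether the
C-terminal YLDL internalisation motif (aa 769–772) is lost. `fusiondx`
implements this interpretive logic as a library plus a thin CLI:

- **gene model** (`fusiondx.model`) — transcript isoforms with exact
  genomic↔cDNA↔protein coordinate arithmetic and a packaged *FGFR2*
  fixture encoding the published isoform facts (NM_000141.4 = IIIc,
  18 exons, 821 aa; NM_022970.3 = IIIb, alternative exon 8, 822 aa;
  NM_001144913 = IIIb C3, 769 aa) on synthetic but mutually consistent
  coordinates;
- **events** (`fusiondx.events`) — DNA breakpoints (BEDPE, including
  bridged inserts and partnerless records) and RNA junctions (exon +
  offset TSV) with read evidence;
- **annotation** (`fusiondx.annotation`) — per-isoform localization,
  reading frame, kinase retention and the oncogenic mechanism call:
  *enhanced dimerisation* (in-frame gain of a dimerisation/oligomerisation
  domain) versus *C-terminal truncation* (loss of YLDL, frame- and
  partner-independent), with explicit conflict flags when isoforms
  disagree;
- **assays** (`fusiondx.assays`) — evaluators for six assay classes
  (break-apart FISH, dual-fusion FISH, 5′/3′ imbalance, amplicon NGS,
  single-primer-extension NGS, hybrid-capture NGS at DNA and RNA level)
  returning per-event verdicts, scenario matrices and cohort coverage
  fractions;
- **cohort** (`fusiondx.cohort`) — a seeded synthetic cohort generator
  reproducing the reported fusion architecture (intron-17-dominant
  breakpoints, ~10 % bridged/partnerless events, 4.2 % close-proximity
  partners) with ground-truth labels;
- **reporting** (`fusiondx.reporting`) — clinical RNA/DNA report
  rendering (JSON + Markdown) with a mandatory-field validator and the
  compact junction nomenclature (`FGFR2::ATE1 (F17A12)`).

## Worked example

```python
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
rec = annotate_event(j, model, catalog).record_for(CANONICAL)
print(fusion_label("FGFR2", "17", "ATE1", "12"))
print(rec.frame, rec.kinase_retained, rec.mechanism, rec.lost_motifs)
```

prints

```
FGFR2::ATE1 (F17A12)
in_frame True c_terminal_truncation ['YLDL']
```

i.e. a junction after *FGFR2* exon 17 into *ATE1* exon 12 is in frame and
keeps the kinase domain (765 of 821 aa retained), but *ATE1* contributes no
dimerisation domain, so the oncogenic mechanism is loss of the C-terminal
YLDL motif. The scripts in `examples/` walk through each capability the
same way (gene-model arithmetic, isoform-conflict surfacing on a
KCTD1-like breakpoint, the scenario-by-assay capability matrix, cohort
coverage, clinical reports); `examples/05_cohort_coverage.py` ends with

```
DNA HyCa: rearrangement w/o partner: 10.0%  (bridged events)
BA-FISH: close-proximity false negatives: 2.8%
```

on a 1000-event cohort at seed 1 — bridged fusions are detected by DNA
hybrid capture but reported as rearrangements without a partner gene,
while partners lying within the 1 Mb FISH probe-separation resolution
(ATE1- and TACC2-like) are missed outright by break-apart FISH.

The CLI mirrors the library:

```bash
fusiondx simulate --n 100 --seed 7 --out cohort/
fusiondx annotate --events cohort/cohort.bedpe --out ann/
fusiondx evaluate --events cohort/cohort.bedpe --junctions cohort/junctions.tsv \
                  --sidecar cohort/truth.json --matrix --out eval/
fusiondx report --junctions cohort/junctions.tsv --out report/
fusiondx validate-report report/report.json
```

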