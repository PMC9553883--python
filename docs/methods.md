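# Methods

## Scope and model

`fusiondx` treats an *FGFR2* rearrangement as a pair of genomic breakends
(DNA level) and/or a spliced junction between two transcripts (RNA level),
and asks three questions per event: where does the breakpoint fall on each
annotated isoform, is the predicted fusion product oncogenically
competent, and which of six diagnostic assay classes would detect it and
with what informative value. Events enter pre-called: no read alignment or
fusion calling from raw sequence is performed.

### Coordinates

Genomic intervals are 0-based half-open on stranded chromosomes; GFF3
input (1-based inclusive) is converted on load. cDNA and protein
coordinates are 1-based, matching HGVS display and the amino-acid
numbering used for FGFR2 (kinase domain aa 481–757, YLDL motif aa 769–772
on NM_000141.4). Exon numbering is per-isoform in transcript order, with
display labels kept parent-relative for the alternative FGFR2 isoforms so
that shared exons keep their canonical names (the C3 isoform's exons are
labelled 2–17 plus its own terminal exon).

### The packaged FGFR2 fixture

The fixture places the gene on the minus strand of chr10 spanning
123,237,844–123,357,972 (hg19 labels). Coordinates are synthetic but
mutually consistent; what is contractual is the isoform-level arithmetic:
NM_000141.4 (IIIc) has 18 exons and a 2466-nt CDS translating to 821 aa;
NM_022970.3 (IIIb) differs only by an alternative, 3-nt-longer eighth
exon (822 aa); NM_001144913 (IIIb C3) lacks exon 1 and ends on a shorter
alternative terminal exon inside intron 17, truncating the IIIb protein
by its last 53 aa. Exon lengths were chosen so the kinase domain ends
inside exon 17 (retained cDNA through exon 17 encodes 765 aa) and the
YLDL motif falls in the coding region of exon 18 — the geometry on which
all breakpoint-interpretation rules rest. The protein sequence is
deterministic pseudo-random with YLDL planted uniquely at aa 769;
reverse-translation uses one fixed codon per residue. Six additional
described alternative exonic regions (two alternative first exons, three
internal, one C2-like terminal exon) bring the union of exonic regions
across the bundled isoform list to 26. All of these facts are asserted at
build time and again by the test suite.

### Interpretation rules

**Localization.** Breakends map to exon (CDS/UTR), intron, or flank per
isoform; with single-base breakends under the half-open convention, a
breakpoint "after exon k" is the first intronic base and localizes to
intron k.

**Kinase retention** uses two redundant rules: the exon rule (breakpoint
involves exon 17 CDS, intron 17, or exon 18 CDS) and the aa rule (the
retained cDNA prefix translates the complete kinase domain). They agree at
intron boundaries on the fixture; for breakpoints inside exon 17 upstream
of the kinase end — a case for which no categorical convention exists —
the verdict is the disjunction of both rules plus an explicit discrepancy
warning, rather than a silent guess.

**Reading frame.** With L5 = retained driver CDS nt and s = partner CDS
nt excluded upstream of the junction, the partner peptide is translated in
its own frame iff L5 ≡ s (mod 3). Junctions strictly upstream of a
partner isoform's start codon give `no_cds_3p` (translation from the
driver terminates in the retained partner 5′UTR); junctions at or after
the driver stop codon give `no_cds_3p` (the product is the wild-type
driver protein); a cut inside the stop codon itself is `indeterminate`
(read-through depends on the joined bases). The arithmetic is verified
against an independent brute-force oracle that splices the two transcript
fragments, translates, and checks whether the partner C-terminal peptide
is produced — over ≥ 1000 random junctions per run.

**Mechanism.** Without a retained kinase there is no mechanism. An
in-frame fusion whose retained partner fragment contains at least one
domain from the dimerisation/oligomerisation list (AFF3, BAG, BAR,
coiled-coil, FN1, leucine zipper, LIS1, SAM, SPHF, zinc finger) activates
by *enhanced dimerisation*. Loss of the YLDL motif (retained driver aa
< 772) with no such in-frame gain activates by *C-terminal truncation* —
deliberately indifferent to frame and partner content. DNA-only events
with an unresolved partner (bridged inserts) stay *indeterminate*;
truncation is forced only when no partner contributes sequence at all
(partnerless, intergenic, or driver-internal deletions). Loss of the last
10 aa additionally sets an informational `grb2_site_lost` flag rather
than a separate mechanism. Every event is evaluated per isoform pair and
a conflict flag is raised when isoforms disagree on frame or mechanism —
a single collapsed verdict would be wrong exactly in the cases that
matter (isoform-dependent start codons).

## Assay models

Each assay class is a small declarative design plus an evaluator
returning detected / partner-resolution / frame-determinable /
expression-assessed / failure-mode.

- **Break-apart FISH**: probes flank the driver locus;
  `resolution_bp` (default 1,000,000) is the minimum separation between
  the rearranged partner locus and the probe pair for visible signal
  splitting. No published cutoff exists; 1 Mb is a conservative
  interphase-FISH separation scale and reproduces the documented
  close-proximity misses (ATE1 ~0.3 Mb, TACC2 ~0.25 Mb from the locus).
  Driver-internal events (3′ deletions) cannot split the signals. An
  unmapped/ambiguous partner is assumed distant: hybridisation is
  sequence-agnostic, so failure to resolve a partner computationally does
  not impede FISH.
- **Dual-fusion FISH** detects only the one designed partner gene.
- **Imbalance assay**: detected iff 3′/5′ molecule-count ratio falls
  below `ratio_threshold` (default 0.5; no published cutoff). It fires on
  fusions and 3′ deletions alike and by construction cannot distinguish
  them, resolve a partner, or determine frame.
- **Amplicon NGS**: both the driver junction exon and the specific
  partner exon must carry designed primers; unknown or intergenic 3′
  sequence is undetectable by design.
- **SPE (anchored multiplex PCR)**: one driver-exon primer suffices and
  the partner is read from sequence; junction exons absent from the
  design isoform (NM_000141.4) are not covered. Primer-to-junction
  distance limits are out of scope (the primer is assumed usable anywhere
  on its exon).
- **Hybrid capture, DNA level**: the driver breakend must fall in the
  probe tiling (the bundled design tiles exon 17–intron 17–exon 18
  wall-to-wall). The partner is identified when the non-driver side maps
  inside an annotated gene body; inserts ≥ 10 nt mapping to a third locus
  or only to repeat families leave the event detected but reported as a
  rearrangement without a partner (`bridged_unresolved`).
- **Hybrid capture, RNA level**: every expressed junction whose driver
  exon is captured is detected, with frame and expression readable.

Verdict soundness holds as: `failure_mode == none` implies detected, and
not-detected implies a failure mode — a detected-with-caveat verdict
(bridged) carries both `detected = True` and a failure mode. Detection
sets nest by construction (amplicon ⊆ SPE ⊆ HyCa-RNA under a shared
driver-side configuration), which the property tests check on arbitrary
simulated cohorts.

## Synthetic cohort generator

The generator emulates the reported architecture of large
FGFR2-rearranged iCCA cohorts. Per-event class probabilities (defaults):
bridged/partnerless 0.10, close-proximity partner 0.042, out-of-frame
0.05, 3′ deletion 0.03, upstream non-competent 0.02, remainder standard
in-frame distant-partner fusions. Driver breakpoint sites are drawn from
{exon 17: 0.15, intron 17: 0.70, exon 18: 0.15} — the published
description is qualitative ("most frequently within intron 17"), so these
weights are configurable defaults, not literature facts. Exonic
breakpoints for in-frame classes are codon-aligned; the out-of-frame
class offsets the exon-18 cut by 1–2 nt. Partner toy genes (all exon CDS
lengths codon multiples, so catalogued junction introns are
frame-compatible) model the recurrent partner classes: BICC1-like distant
with a SAM domain, ATE1-like (close, no dimerisation domain) and
TACC2-like (close, coiled-coil), CCDC6-like multi-exon coiled-coil,
DBP-like bridged target, AFF3- and ZMYM4-like distant dimerisers, and a
KCTD1-like gene with isoform-dependent start codons. Bridged events carry
an 80-nt repeat-derived insert and an unresolved 3′ breakend while their
matched RNA junction reveals the true partner. Read counts are Poisson
(split 0.25·depth, spanning 0.15·depth, wild-type 0.60·depth at default
depth 200); imbalance molecule counts use a 0.35 expected 3′/5′ ratio for
3′-replacing events (~0.65 tumour fraction). All randomness flows through
explicit `numpy` generators seeded from the single cohort seed.

What the generator does *not* emulate: sequence-level reads and error
profiles, partner heterogeneity beyond eight genes, copy-number context,
subclonality, and degraded-FFPE artefacts. Passing tests therefore
demonstrate the correctness of the interpretive and assay logic under the
stated architecture, not calibrated real-world assay sensitivities.

## Reporting

RNA reports carry the five mandated items (split/spanning counts,
fusion-read ratio, gene names with transcript IDs, junction exons,
frame + domain-integrity statement); DNA reports carry counts, ratio,
genes, chromosomal breakpoint positions, the reference build, and a
frame/domain estimate that always uses cautious wording — mandatory
whenever the mechanism is indeterminate from DNA alone, and applied
uniformly here since every DNA-level frame statement is an inference.
Both validate against a checklist validator that is itself
property-tested over random simulated cohorts. The fusion-read-ratio
denominator includes spanning pairs; the report footer states the
definition. The display code uses first-letter gene initials
(`F17A12`), growing both prefixes on collision; translocations are also
rendered ISCN-like and HGVS-style, and the structured
transcript/exon/offset block is emitted as JSON rather than a string
(the consensus string nomenclature was unreleased at design time).

## Problem sizes and numerical choices

Stochastic checks run at n = 1000 events (cohort rates, accepted within
3 binomial standard deviations of the target fractions) and n = 10,000
for the law-of-large-numbers convergence test; the frame oracle samples
≥ 1000 random junctions. These sizes put every quantity's sampling noise
well inside its acceptance band while keeping the full suite in the
seconds range. Degenerate inputs are errors (empty cohort, all-zero read
evidence, empty motif) or flagged-but-kept records (unknown transcripts
→ novel, evidence-free junctions → warning), never silent defaults.

## Known limitations

- Fixture coordinates are not RefSeq base-for-base; analyses that need
  real hg19 positions must load an external GFF3.
- Frame prediction from DNA assumes canonical splicing of the retained
  exons (last retained driver exon joins the first partner exon 3′ of the
  breakend); cryptic splice sites are not modelled.
- The BA-FISH geometric model reduces probe separation to a single
  distance threshold; signal intensity, cut-off percentages of nuclei and
  tissue artefacts are out of scope.
- Junctions within ~3 nt of codon or start-codon boundaries can in
  reality read through in ways the categorical frame labels cannot
  express; these are classified conservatively (`indeterminate`) or fall
  under the documented boundary windows of the oracle tests.
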