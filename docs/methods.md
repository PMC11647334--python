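# Methods

## The problem

Inherited retinal diseases (IRDs) are Mendelian disorders of photoreceptor /
RPE degeneration with enormous locus and allelic heterogeneity: hundreds of
genes, every inheritance mode, and clinical phenotypes that overlap enough to
confound diagnosis. Targeted gene-panel sequencing is the workhorse in
resource-limited settings, but a panel pipeline must solve several problems
that generic variant annotation does not:

* phenotype-first gene restriction (to keep the false genotype rate down)
  with a gene-agnostic fallback for unresolved cases;
* rescue of exon-edge variants that annotation software mislabels — a
  synonymous change in the first or last two bases of an exon can destroy a
  splice site, so it must not be discarded by the synonymous filter;
* an explicit, rule-based resolution status per patient, honest about phase:
  an unconfirmed compound heterozygote is *very likely* resolved, not
  resolved;
* detection of alleles invisible to small-variant calling (a mobile-element
  insertion found via junction reads in raw FASTQ; published deep-intronic
  variants screened by a supplemental assay);
* defence against platform artefacts that recur across the cohort.

`irdscreen` implements this pipeline as a reusable library plus CLI, and a
synthetic cohort generator that plants known ground truth so every stage is
testable without access to patient data.

## Position classification

Transcript models carry exons in transcription order plus CDS bounds.
Positions classify into a strict partition:

* `exonic_splice_junction` — exonic, within the first or last 2 bases of an
  exon;
* `canonical_splice_site` — intronic, ≤ 2 bases from an exon (donor GT /
  acceptor AG);
* `near_intronic` — intronic, 3–100 bp from the nearest exon (introduced so
  the partition is exhaustive);
* `deep_intronic` — intronic, > 100 bp from both flanking exons;
* `coding_exonic` / `noncoding_exonic` / `intergenic`.

Coordinates are 1-based inclusive at every file boundary (VCF/GFF3) and
0-based half-open internally. Intronic distance counts bases into the intron
(the base adjacent to an exon has distance 1); exonic distance is the offset
from the nearest exon end (an edge base has distance 0). When a position maps
to several transcripts, the class with the smallest boundary distance wins;
ties go to the more splice-proximal label, because the boundary list exists
precisely to avoid discarding edge variants. Indels classify by their
leftmost affected base and are assumed left-normalised on input.

The nonsense codon check is plain codon arithmetic,
`codon = floor((cds_position − 1) / 3) + 1`, used to report the location of a
premature termination codon (e.g. c.10888G>T → codon 3630).

## The tiered filter

Stage order (fixed; each stage logs input/output counts to an audit trail):

1. phenotype gene subset — genes associated with the clinical class; an
   unclear diagnosis (`Unclear:STGD|BEST`) takes the union of its candidate
   classes;
2. registry flag — variants seen in ≥ 2 families of the registry are flagged
   and bypass *every* later exclusion;
3. global MAF filter — retain MAF ≤ 6%. The boundary is inclusive and a
   missing MAF is retained: absence of frequency evidence cannot justify
   exclusion. The 6% ceiling is deliberately lenient, set against the
   frequency of the most common pathogenic recessive alleles (ABCA4);
4. splice-junction flag — exonic variants in the boundary table's
   first/last-two-base positions are flagged;
5. synonymous exclusion — junction- and registry-flagged synonymous
   variants survive (the order of stages 4 and 5 is load-bearing and is
   asserted by a test);
6. prioritisation — splice-site variants, indels and nonsense variants pass
   automatically; missense variants need pathogenic calls from ≥ 3 of the 5
   predictors (SIFT, PolyPhen-2, Grantham, FATHMM, PhyloP). Predictor
   binarisation happens upstream; the five calls are inputs, since per-tool
   thresholds are tool-version-specific. Missing calls count as
   non-pathogenic;
7. artefact elimination list — only listed variants are removed, mirroring
   manual curation; cohort recurrence alone never auto-excludes.

SpliceAI scores > 0.1 are recorded as splicing pathogenicity *evidence*,
never used as a filter. If the patient is unresolved after resolution
calling, the filter re-runs once over all panel genes (gene-agnostic pass);
this pass can only widen the candidate set.

## Resolution status

Per gene, candidates with ACMG class P or LP (interchangeable throughout)
and VUS are evaluated against fixed-precedence clauses:

| status | clause |
|---|---|
| genetically resolved | (i) single het/hemi P/LP in an AD or XL gene; (ii) hom P/LP in an AR gene; (iii) two het P/LP in an AR gene with trans configuration confirmed by familial testing |
| very likely resolved | unconfirmed compound het P/LP in an AR gene (no familial samples, or phase untested) |
| potential diagnosis | (i) het P/LP + het VUS in an AR gene; (ii) two het VUS in an AR gene; (iii) single het VUS in an AD/XL gene |
| unresolved | everything else — including a single het P/LP in an AR gene (monoallelic) |

Design choices where the rules were genuinely open:

* a homozygous P/LP resolves without phase information — clause (ii) has no
  phase requirement; the very-likely downgrade applies only to compound
  heterozygotes;
* a homozygous VUS in an AR gene supplies two uncertain alleles and is
  accepted under potential clause (ii), with a note on the call;
* hemizygous male XL variants fall under clause (i); heterozygous female XL
  calls also satisfy clause (i) as written but carry a carrier-caution note;
* if two genes tie at the highest status the call is flagged
  `needs_review` rather than auto-picked, since such cases need manual
  adjudication;
* candidates in genes with unknown inheritance are excluded from clause
  evaluation and logged.

The classifier is verified exhaustively against an independent hand-built
truth table over all ≤ 2-variant (zygosity × ACMG class × inheritance ×
phase) combinations.

### Deep-intronic supplemental screen

The packaged catalogue holds seven published deep-intronic variants in
ABCA4, CEP290 and USH2A with functional splicing evidence (pseudoexon
inclusion or exon skipping). Supplemental-assay genotypes at catalogue loci
merge into the candidate set as pathogenic het/hom observations before
classification; this can convert a monoallelic recessive case into a
resolvable compound heterozygote. A genotype at a locus absent from the
catalogue is an error, never silently ignored.

## Alu junction-read screen

The 353-bp Alu insertion in MAK is invisible to small-variant calling but
detectable from raw reads: 23-bp junction motifs differ between the
wild-type allele (`AGGAAAAAAGATTCTCCATTTCG`) and the insertion allele
(`GAAAAAAGGAGGCCGGGCGCGGT`). A read counts for a category if it contains the
motif or its reverse complement — the only orientation information
computable from FASTQ alone. Matching is exact (the screen is a grep-style
search); quality values are ignored; reads matching both motifs are counted
as conflicting and excluded from the mutant percentage, which is displayed
rounded to the nearest integer with raw counts always reported. No zygosity
is inferred from the mutant fraction. The screen generalises to any
same-length motif pair ≥ 10 bp.

## Artefact registry

The recurrence scanner reports, per variant, the fraction of probands
carrying it (one proband per family when family ids are supplied, since
founder variants legitimately recur). Fractions ≥ 5% are flagged for review;
a fraction of exactly 1.0 is additionally labelled a probable artefact — the
canonical case being a 1-bp deletion present in every sample yet listed as
likely pathogenic in public databases. Exclusion always requires membership
of the manually curated elimination list, which round-trips losslessly
through a TSV and merges idempotently.

## Synthetic cohort generator

The generator is first-class, tested code, not a fixture. What it emulates:

* **Gene models** — one transcript per gene on a private random contig
  (no genome download; coordinates are contig-local): 2–10 exons of
  60–240 bp, introns of 250–600 bp (long enough to contain deep-intronic
  positions), a valid CDS (ATG…stop, divisible by 3, no internal stops),
  100-bp flanks, random strand. The first four genes are pinned to modes
  AD, AR, AR, XL so every category is realisable for n ≥ 4; the remainder
  draw AR/AD/XL at 60/25/15%, roughly the mode balance of IRD panels. Each
  gene associates with 1–3 clinical classes.
* **Cohort composition** (defaults) — 135 patients; class mix BEST 2, CRD 4,
  LCA 5, RP 50, RPA 1, RS 3, STGD 11, USH 10, Unclear 13 (%, normalised);
  population mix 50% indigenous African, 27% Caucasian, 17% mixed ancestry,
  6% Indian. Only the class marginals and the ~50% indigenous-African share
  are reported for the emulated registry; the remaining population split is
  this package's choice, as is the independence of class and population
  (only marginals are known). Labels are apportioned by largest remainder
  and shuffled, so realised counts match the design exactly.
* **Resolution categories** — the default mix plants
  20 AD + 25 hom-AR + 12 phase-confirmed comphet + 14 phase-unknown comphet
  + 4 DIV-resolvable resolved patients (75 = 56%), 19 potential-diagnosis
  (7/6/6 across clauses i–iii), 12 monoallelic-AR and 29 plain unresolved.
  The per-mechanism split of the emulated cohort's 75 resolved patients is
  not published; this apportionment reproduces the reported totals (56%
  overall, 53% before the DIV screen, 19 potential, 12 monoallelic) and is
  otherwise the package's choice. Every category maps deterministically to
  an expected status; truth-recovery tests demand 100% agreement because the
  rule system is exact and the generator adds no label noise.
* **Variant content** — causal alleles are drawn from a deterministic
  per-gene site catalogue (pathogenic missense with 3–4 predictor calls,
  nonsense, frameshift, canonical-splice, exon-edge synonymous,
  high-MAF registry synonymous, deep-intronic locus); benign background
  variants carry MAFs on both sides of the 6% cut-off so the filter is
  exercised in both directions, and classes B/LB so they can never trigger a
  clause. Every tenth resolved patient is planted discordantly (causal gene
  not associated with the clinical class) to exercise the gene-agnostic pass
  and discordance reporting; every fourth hom-AR patient uses the registry
  synonymous allele to exercise the registry bypass end-to-end; every fifth
  AD-category patient uses a hemizygous XL nonsense allele. A cohort-wide
  1-bp-deletion artefact is planted in `artefact_rate` of patients
  (default 1.0) and ships on the elimination list. VCF REF alleles are cut
  from the emitted reference contigs, files are sorted and 1-based, and
  identical (design, seed) inputs give byte-identical outputs.
* **FASTQ** — reads of requested length with exact planted counts of mutant
  and wild-type junction motifs in random orientation at random offsets;
  background reads are rejection-sampled until they contain neither motif in
  either orientation.

What it does **not** emulate — and hence what passing tests do not show
about real data: sequencing error, coverage/depth variation, genotype-call
noise, annotation disagreement between tools, multi-transcript genes,
structural variation beyond the fixed-motif insertion, and linkage between
clinical class and population. Truth-recovery at 100% demonstrates the rule
system and plumbing are correct, not that real cohorts resolve at these
rates.

## Reporting

A patient counts as resolved for rate purposes if genetically or very likely
resolved. Percentages are rounded half-up to integers for display (so 75/135
prints as 56%), with raw fractions retained in machine output. Recurrent
causal variants are those causal in ≥ 2 probands, with per-population
counts; novelty is relative to a user-supplied known-variant catalogue (no
quantitative novelty source exists — published literature plus an in-house
database is the practical definition). A resolved patient is discordant when
the resolving gene's associated disease set does not contain the clinical
class; for unclear diagnoses a match with any candidate class is concordant,
and genes absent from the map are flagged unmappable rather than silently
counted.

## Problem sizes and numerical conventions

The shipped tests run the full pipeline on cohorts of 40–200 patients over
10–20 synthetic genes, and the acceptance script uses the default
135-patient design plus 1,000-read FASTQ screens — sizes chosen as the
package's desk-scale working set; the whole suite completes in seconds.
Thresholds: MAF ≤ 0.06 (inclusive), SpliceAI > 0.1 (strict), ≥ 3 of 5
predictors, ≥ 2 registry families, recurrence review at ≥ 5%. Degenerate
inputs: empty FASTQ → zero counts; empty candidate set → unresolved; zero
denominators → percentage undefined-with-note, never NaN.

## Known limitations

* One transcript per gene; no UTR-aware consequence re-annotation.
* No zygosity call from the Alu mutant fraction (the field has no published
  threshold for het vs hom from junction-read ratios).
* The artefact compendium ships as a format plus a single example entry; the
  full production list is site-specific curation.
* Novelty and registry membership are exact-key lookups; no normalisation
  across representations beyond left-alignment is attempted.
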