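# irdscreen

Tiered, phenotype-aware variant prioritisation and diagnostic reporting for
inherited retinal disease (IRD) gene panels.

IRDs are Mendelian disorders of photoreceptor/RPE degeneration with causal
variants in hundreds of genes across every inheritance mode. Panel
sequencing pipelines for them must restrict analysis to phenotype-relevant
genes (to control the false genotype rate), rescue splice-relevant variants
at exon edges that generic annotation discards, call an explicit resolution
status per patient, and catch alleles that small-variant calling misses
entirely. `irdscreen` packages that workflow for analysts running IRD (or
similar Mendelian) panels:

* **Boundary-aware position classification** — a curated exon/intron
  boundary table flags variants in the first/last two bases of each exon
  (`exonic_splice_junction`) and distinguishes canonical splice sites,
  near-intronic and deep-intronic positions (> 100 bp into the intron);
  codon arithmetic locates premature termination codons.
* **Tiered per-patient filter** — phenotype gene subset → known-variant
  registry flag (≥ 2 families; bypasses all later exclusions) → global MAF
  filter (retain ≤ 6%) → splice-junction flag → synonymous exclusion →
  prioritisation (splice/indel/nonsense automatic; missense needs ≥ 3 of 5
  pathogenic predictor calls) → artefact elimination list, with a
  gene-agnostic re-run for unresolved patients and a full audit trail.
* **Resolution-status engine** — genetically resolved / very likely
  resolved / potential diagnosis / unresolved, from ACMG classes, zygosity,
  inheritance mode and compound-het phase, e.g. an unconfirmed compound
  heterozygote is *very likely* resolved, and a monoallelic pathogenic
  variant in a recessive gene stays unresolved.
* **Deep-intronic supplemental screen** — merges assay genotypes at seven
  packaged, functionally verified deep-intronic loci (ABCA4, CEP290, USH2A)
  into the candidate set before classification.
* **MAK-Alu FASTQ screen** — counts reads carrying the 23-bp wild-type vs
  mutant junction motifs (either orientation) to detect a 353-bp Alu
  insertion invisible to variant calling; generalises to any motif pair.
* **Artefact registry** — cohort recurrence scan (≥ 5% flags for review;
  100% marks a probable artefact) feeding a manually curated elimination
  list.
* **Cohort reporting** — resolution rates overall / per clinical class /
  per population group, recurrent causal variants (≥ 2 probands), novel
  variants relative to a known-variant catalogue, and clinical–molecular
  discordance flagging.
* **Synthetic cohort generator** — gene models on synthetic contigs,
  per-patient VCFs realising every resolution category, manifests,
  catalogues and FASTQs with planted ground truth, so the full pipeline is
  testable and demonstrable without patient data.

## Worked example

Simulate a registry-scale cohort, run the pipeline, and report:

```bash
irdscreen simulate --out demo --seed 5 --n-genes 12
irdscreen filter --cohort-dir demo --out demo/calls.tsv
irdscreen report --cohort-dir demo --resolutions demo/calls.tsv --out demo/report
```

which prints (abridged):

```
Cohort diagnostic summary
=========================
Patients: 135
Resolved (genetically or very likely): 75 (56%)

By clinical classification:
  RP          41/68  (60%)  causal genes: 9
  STGD         9/15  (60%)  causal genes: 3
  USH         10/14  (71%)  causal genes: 5
  Unclear      7/18  (39%)  causal genes: 4
  ...

By population group:
  Caucasian             22/36  (61%)
  Indigenous African    36/68  (53%)
  ...
```

75 of 135 patients receive a probable genetic diagnosis (56%): the planted
design resolves 71 patients from panel variants alone and the supplemental
deep-intronic screen converts 4 monoallelic recessive patients into
compound heterozygotes. Per-class lines show resolved/total with the number
of distinct causal genes in that class.

The Alu screen on a FASTQ with planted junction reads:

```bash
alu-screen --fastq reads.fastq
# 13 mutant, 23 wild-type, 0 conflicting (36% mutant)
```

and the recurrence scan plus elimination-list maintenance:

```bash
irdscreen artefacts scan --cohort-dir demo --out recurrence.tsv
irdscreen artefacts merge listA.tsv listB.tsv --out merged.tsv
```

From Python, the same pipeline is three calls:

```python
from irdscreen import CohortDesign, generate_gene_models, generate_cohort, run_cohort
from irdscreen.report import make_summary

bundle = generate_gene_models(20, seed=7)
cohort = generate_cohort(CohortDesign(n_patients=135, seed=4), bundle)
results = run_cohort(cohort.patients, cohort.models, cohort.catalogues)
summary = make_summary(results, cohort.manifest,
                       known_catalogue=cohort.catalogues.known_variants,
                       gene_disease_map=cohort.catalogues.gene_disease_map)
print(summary.overall_resolution_percent)   # 56
```

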