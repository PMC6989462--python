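# cgdm — a clinical genome data model with provenance-aware variant storage

`cgdm` is a small relational data model and toolchain for storing NGS-derived
variant results in a form a clinician (or a decision-support rule) can trust:
every stored variant is normalized to a canonical spelling, linked to the
pipeline provenance that produced it (tool, step, parameters, reference data
source with assembly build and version), and guarded by per-test quality
metrics.  On top of the store it provides semantic variant query (fragmented
search terms like `V600E` resolve without silent guessing) and a worked
pharmacogenomic decision-support function: IWPC warfarin dosing from stored
CYP2C9/VKORC1 genotypes.

It is aimed at people building clinico-genomic databases or CDS prototypes
who need clinical-grade bookkeeping — not another variant caller.

## The model

**Schema.** Eight entities carrying 46 domain attributes: linkage identifiers
to the clinical record, experiment description, bioinformatics protocol
(pipeline provenance), the genomic alteration itself, quality checks,
clinical annotations, and the sample-level biomarkers MSI and TMB (stored,
not computed).  `cgdm init-db` emits and executes the DDL; introspection of
the live catalog reports the same 8/46 shape.

**Minimal representation.** The same indel can be spelled many ways in VCF —
`chr10:11805838 C>CT` and `chr10:11805838 CG>CTG` describe one inserted `T`.
Before storage every record is (1) *trimmed*: shared allele suffix then
prefix removed, keeping the VCF anchor base, and (2) *left-aligned*: shifted
to the smallest position `p` such that applying the edit to the reference
yields the same sequence.  Equivalent spellings become byte-identical and
deduplicate on load.  Without reference context only the trim runs and the
record is flagged `trim_only` in provenance.

**Nomenclature completeness.** A protein-level variant name must pin its
reference sequence: `NP_004324.2:p.V600E` is complete, while the versionless
`NP_004324:p.V599E` (the same BRAF variant numbered against an older
sequence) is flagged incomplete with failure category `reference`
(categories: `origin` / `reference` / `symbol`).  Incomplete names are stored
verbatim with their flag, never silently "corrected".

**Warfarin dosing.** The IWPC models are linear in the square root of the
weekly dose; the pharmacogenetic predictor is

```
sqrt(mg/week) = 5.6044 − 0.2614·age(dec) + 0.0087·height(cm) + 0.0128·weight(kg)
                + β_VKORC1(-1639 G>A genotype) + β_CYP2C9(diplotype)
                + β_race + 1.1816·inducer − 0.5503·amiodarone
```

with the weekly dose its square.  Coefficients live in a versioned YAML
knowledge table (`src/cgdm/knowledge/iwpc_warfarin.yaml`) alongside the
clinical (non-genetic) fallback, which is dispatched — and marked in the
audit trail — whenever the stored genotype is unknown.

## Worked example

Generate a synthetic dataset (reference window with tandem repeats, VCF in
which every variant appears under two equivalent spellings), load it, and
query:

```
$ cgdm fixtures --seed 3 --subjects 3 --variants-per-subject 4 \
      --fraction-nonminimal 1.0 --out fx
fixtures written to fx (12 truth records, 7 pharmacogene subjects)

$ cgdm --db d.sqlite init-db
{
  "entity_count": 8,
  "attribute_total": 46,
  ...
}

$ cgdm --db d.sqlite load fx/variants.vcf --format vcf --test-id T1 \
      --build FIXTURE1 --mode full --fasta fx/reference.fa --depth 100
{
  "records_read": 24,
  "records_loaded": 24,
  "records_rejected": 0,
  "duplicates_merged": 12,
  ...
  "table_counts": { "CLINICAL_IDENTIFIER": 3, ..., "GENOMIC_ALTERATION": 12, ... }
}
```

24 input records (12 true variants × 2 spellings) normalize and collapse to
exactly the 12 truth records; 3 subjects produce 3 linkage-identifier rows.
Normalizing one of the published spellings directly:

```
$ cgdm normalize --chrom chr10 --pos 11805838 --ref CG --alt CTG --build GRCh37
{"chromosome": "10", "position": 11805838, "ref_allele": "C", "alt_allele": "CT",
 "genome_build": "GRCh37", "mode": "trim_only"}
```

`cgdm dose --subject P003 --alleles alleles.yaml --age-decades 6 ...` derives
the subject's CYP2C9/VKORC1 genotype from the store and prints the weekly and
daily dose with a per-term audit trail.

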