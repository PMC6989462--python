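# Methods

## Scope and shape

The package models the *storage and use* of clinical NGS results: everything
upstream of the variant file (base calling, alignment, variant calling) is
outside it and enters only as provenance metadata and quality summaries.
Structural variants are stored descriptively but never normalized; symbolic
VCF alleles (`<DEL>`, breakends) are rejected at ingestion with a recorded
reason.  Genome-build liftover is out of scope by design: the build is
recorded and compared, never converted, because silently remapped coordinates
are precisely the failure mode the model exists to prevent.

## The entity model and the 8/46 count

The schema is a logical model of 8 entities and 46 domain attributes.  The
counting convention is part of the model's contract and is implemented, not
asserted: `introspect_schema()` derives both numbers from the live type
registry, and `introspect_database()` re-derives them from the SQL catalog by
classifying each physical column through the registry.

* Surrogate primary keys and foreign-key columns are not domain attributes.
* `BIOINFORMATICS_PROTOCOL.stage` is the workflow discriminator (which
  pipeline stage a row describes) and is classified *structural*, like a key.
* Conceptually bundled identifier sets are one composite attribute stored as
  one JSON column: the gene triple (HGNC symbol, Entrez, Ensembl), the
  variant name set (HGVS g./c./p., dbSNP, dbVar), the ClinVar/COSMIC pair,
  and the reference-data *origin* triple (source, version, build).  The
  dataclass layer exposes every individual field and (de)serialises through
  the composite columns.
* `GenomicAlteration.genome_build` is not a column of GENOMIC_ALTERATION.
  The build belongs to the reference data source of the pipeline stage that
  assigned the coordinates, so the stored row reaches it through the
  `provenance_id` foreign key; readers populate the dataclass field via the
  join.  This is deliberate normalisation, not an omission — a build stored
  twice can disagree.

Allocation: CLINICAL_IDENTIFIER 5, EXPERIMENT_RELATED_INFORMATION 7,
BIOINFORMATICS_PROTOCOL 8, GENOMIC_ALTERATION 16, QUALITY_CHECK 3,
CLINICAL_ANNOTATION 3, MICROSATELLITE_INSTABILITY 2, TUMOR_MUTATION_BURDEN 2.
TUMOR_MUTATION_BURDEN is the eighth entity: TMB is a sample-level predictive
biomarker parallel to MSI and needs its panel size (in Mb) to be
interpretable.  Enumerated attributes (sequence type, zygosity, variant type,
annotation class, MSI status, pipeline stage) are closed but configurable
vocabularies seeded with the standard values.

Actor attribution is role-level: an actor reference is an
(institution, person-role) text pair, not a person registry — the model
records *who in which capacity*, not HR data.  Dates are ISO 8601 text for
portability across dialects.

## Variant normalization

`normalize` = trim, then left-align when reference context is available.

*Trim* removes the longest shared allele suffix, then the longest shared
prefix (advancing the 1-based position), always keeping at least one base per
allele — the VCF anchor-base convention.  Suffix-before-prefix matters: it is
what maps `CG>CTG` onto the anchored `C>CT` rather than an unanchored form.

*Left alignment* uses the standard extend-left loop: while the alleles share
a final base, drop it; when either allele empties, prepend the reference base
to the left and decrement the position; finally re-trim the shared prefix.
The result is the unique representation that (a) ends in differing bases and
(b) starts with differing bases unless one allele is the single anchor base.
Idempotence and edit-semantics preservation (equality of edited sequences)
are property-tested on every generated case, and the implementation is
cross-checked against two independent routes: an exhaustive enumeration
oracle that lists *all* equivalent representations inside the window, and
`bcftools norm` on the same fixtures.

Numerical/degenerate choices: multi-allelic sites are split per alt allele
before normalization; identity alleles (ref = alt) are rejected as
non-variants; alleles containing `N` trim normally but are never shifted (an
ambiguous base makes the equal-sequence comparison unsound) and fall back to
`trim_only`; a window that lacks the left context a shift needs raises a
context error naming the required span rather than guessing.  When no
reference is available at all (MAF-only ingestion), the record is stored
trim-only and the degradation is written into the load's provenance
parameters — the store records degraded normalization rather than faking
completeness.  Variants on different genome builds are never equivalent.

## Nomenclature

The HGVS parser is a deliberate pragmatic subset (substitutions, indels,
duplications, frameshifts at g./c./p. level) with accession-class/level
consistency checking; three-letter amino-acid codes are accepted and
normalised to one-letter for comparison, which is case-sensitive on the
letters and whitespace-insensitive.  Completeness failures are categorised as
`origin` (reference source class unrecognised), `reference` (accession not
version-pinned) or `symbol` (malformed change text).  Historical renumberings
(V599E→V600E) are *detected* via the missing version and stored verbatim with
the flag; auto-correction would require the historical RefSeq sequences and
is explicitly not attempted.  The alias index maps `GENE:change`, dbSNP ids
and full HGVS strings to stored rows; fragmented queries return all
candidates with an ambiguity flag (stably ordered by gene symbol, then row
id) — never a silent single guess.

## ETL accounting

One "record" is one candidate observation: a (site, alt, carrying sample)
triple for VCF, a row for MAF.  `records_read = records_loaded +
records_rejected` holds on every load; loads are transactional per source
file, so an injected mid-load crash leaves all counts at zero.  Two accepted
records that normalize to the same (subject, build, chrom, pos, ref, alt)
merge into one stored row, with the merge count written into the
coordinate-assigning provenance row — so loaded-record and stored-row counts
legitimately differ.  The VCF reader is line-level on purpose: the contract
is per-record rejection of malformed lines, which htslib-backed readers
cannot offer; htslib (`bcftools`) instead serves as the independent oracle in
tests.  MAF `-` alleles get a synthesised `N` anchor (flagged): the package
never invents reference sequence.  Rejected records can be written to a
tab-delimited sidecar.

## Pharmacogenomics and decision support

Genotype derivation reads stored normalized alterations plus zygosity at the
defining positions (CYP2C9 \*2/\*3 tag SNVs, VKORC1 −1639 G>A).  The central
rule: absence of a defining variant implies the reference allele *only* when
the subject's test has coverage evidence (a QUALITY_CHECK row with positive
depth); absence of evidence is never evidence of reference, so an uncovered
subject derives `unknown`.  A diplotype whose two alleles are both directly
observed (e.g. \*2/\*3) needs no such inference.  Conflicting zygosity
evidence across rows is an error naming the rows, not a vote.

Dosing uses the IWPC linear models on sqrt(weekly dose), shipped as a
versioned YAML knowledge table so the coefficients are data with provenance,
not code.  Dispatch is strict: the pharmacogenetic model requires both
genotypes known; otherwise the clinical model runs and the audit trail says
so (or, on request, the call refuses with that instruction).  Every result
carries a per-term audit trail (coefficient × value = contribution) whose sum
reproduces the predictor exactly.  Rule evaluation is a pure function of
(database state, rules); dose rules must name a registered dosing function at
validation time, and every triggered action cites the alteration rows and
knowledge reference that fired.

## Synthetic data

The generators emulate exactly the failure surface the package addresses:
windows with tandem-repeat tracts (unit length 1–3, tract length
configurable, tracts kept clear of window edges so left alignment never runs
out of context), variants spelled non-minimally by *inverting* the
normalization operators (padding shared bases, right-shifting within the
tract) so equivalence holds by construction, and pharmacogene cohorts tiling
every CYP2C9 diplotype and VKORC1 state, with one deliberately uncovered
subject.  Everything is deterministic under the seed, and the synthetic build
is labelled `FIXTURE1` so fixture coordinates cannot join real assemblies.
What the generator does **not** emulate: real allele-frequency spectra,
mutation signatures, sequencing error, multi-sample missingness patterns, or
genuine transcript annotation — passing tests demonstrate correctness of the
bookkeeping and normalization algebra, not calling accuracy on real genomes.

Problem sizes used by the default test run: corpora of a few hundred variants
for module tests and a 1,000-spelling indel corpus for the normalization
property check, one covariate grid of 96 points × 18 genotypes for dosing —
sizes chosen so the whole suite exercises every path in seconds on one core.

## Known limitations

* The HGVS grammar is a subset; exotic descriptions (complex rearrangements,
  mosaicism, uncertain ranges) fail parsing rather than mis-parse.
* Left alignment requires local reference context; there is no right-align
  mode and no normalization of symbolic/structural alleles.
* No external knowledge-base clients (ClinVar/CPIC) and no transcript-version
  coordinate remapping; knowledge tables are local files with versions.
* The embedded dialect is sqlite; the "ansi" DDL is generic and untested
  against any specific server.
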