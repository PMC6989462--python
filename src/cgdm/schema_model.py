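"""Clinical genome data model: entities, validation, DDL and introspection.

The model stores one genomic test result per patient together with enough
procedural context — who sequenced, which pipeline stages ran with which tools
and reference data sources, and what the quality metrics were — for a clinician
to judge how much weight the result deserves.  It is a logical schema of eight
entities carrying 46 domain attributes in total:

========================================  ==================
entity (table)                            domain attributes
========================================  ==================
CLINICAL_IDENTIFIER                       5
EXPERIMENT_RELATED_INFORMATION            7
BIOINFORMATICS_PROTOCOL                   8
GENOMIC_ALTERATION                        16
QUALITY_CHECK                             3
CLINICAL_ANNOTATION                       3
MICROSATELLITE_INSTABILITY                2
TUMOR_MUTATION_BURDEN                     2
========================================  ==================

Counting convention: surrogate primary keys, foreign-key columns and the one
structural workflow discriminator (``BIOINFORMATICS_PROTOCOL.stage``) are not
domain attributes.  Identifier bundles that belong together conceptually — the
gene identifier triple (HGNC symbol / Entrez / Ensembl), the variant name set
(HGVS g./c./p., dbSNP, dbVar), the ClinVar/COSMIC pair and the reference data
source (origin) triple (source / version / build) — are each one composite
attribute, stored as one JSON text column.  The Python dataclasses expose every
individual field; serialisation through the composite columns is handled by
``entity_to_row`` / ``entity_from_row``.

``GenomicAlteration.genome_build`` is not a column of GENOMIC_ALTERATION: the
build is owned by the reference data source of the pipeline stage that assigned
the coordinates, and reached through the ``provenance_id`` foreign key.  The
dataclass still carries the build (it is required), and readers populate it via
the join.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field, fields as dc_fields
from typing import Any, Iterable, Optional

from .errors import ConfigurationError, DataError

# --------------------------------------------------------------------------
# Controlled vocabularies
# --------------------------------------------------------------------------

#: Seed vocabularies.  Closed but configurable: ``Vocabulary.update`` extends
#: them from a config file without code changes.
DEFAULT_VOCABULARY: dict[str, tuple[str, ...]] = {
    "sequence_type": ("WGS", "WES", "panel", "targeted"),
    "pipeline_stage": (
        "alignment",
        "realignment_recalibration",
        "variant_calling",
        "sequence_annotation",
        "clinical_annotation",
    ),
    "zygosity": ("heterozygous", "homozygous", "hemizygous", "unknown"),
    "phasing": ("phased", "unphased", "unknown"),
    "variant_type": ("SNV", "InDel", "CNV", "translocation_fusion"),
    "annotation_class": (
        "acmg_actionable",
        "fda_qualified_biomarker",
        "user_defined_biomarker",
    ),
    "msi_status": ("MSI-H", "MSI-L", "MSS", "unknown"),
}


class Vocabulary:
    """Configurable closed vocabularies for enumerated attributes."""

    def __init__(self, seed: dict[str, tuple[str, ...]] | None = None):
        self._terms: dict[str, tuple[str, ...]] = dict(seed or DEFAULT_VOCABULARY)

    def terms(self, name: str) -> tuple[str, ...]:
        try:
            return self._terms[name]
        except KeyError:
            raise ConfigurationError(f"unknown vocabulary {name!r}") from None

    def contains(self, name: str, value: str) -> bool:
        return value in self.terms(name)

    def update(self, name: str, terms: Iterable[str]) -> None:
        merged = list(self._terms.get(name, ()))
        for t in terms:
            if t not in merged:
                merged.append(t)
        self._terms[name] = tuple(merged)


# --------------------------------------------------------------------------
# Shared value types
# --------------------------------------------------------------------------

_ALLELE_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class Actor:
    """Role-level attribution: which institution, acting in which capacity.

    The model attributes each workflow step to an (institution, person-role)
    pair rather than to a registry of named individuals.
    """

    institution: str
    role: str

    def __str__(self) -> str:  # storage form
        return f"{self.institution}|{self.role}"

    @classmethod
    def parse(cls, text: str) -> "Actor":
        institution, _, role = text.partition("|")
        return cls(institution, role)


def _is_iso8601(value: Any) -> bool:
    if not isinstance(value, str) or not value:
        return False
    try:
        _dt.datetime.fromisoformat(value.replace("Z", "+00:00"))
        return True
    except ValueError:
        try:
            _dt.date.fromisoformat(value)
            return True
        except ValueError:
            return False


# --------------------------------------------------------------------------
# Entity dataclasses
# --------------------------------------------------------------------------


@dataclass
class ClinicalIdentifier:
    """Minimal linkage of one genomic test to the clinical record."""

    institution_id: Optional[str] = None
    subject_id: Optional[str] = None
    test_id: Optional[str] = None
    submission_date: Optional[str] = None  # ISO 8601
    ordering_clinician: Optional[Actor] = None


@dataclass
class ExperimentInfo:
    """Wet-lab context of the sequencing experiment."""

    test_id: Optional[str] = None
    test_description: Optional[str] = None
    sequence_type: Optional[str] = None
    platform_technology: Optional[str] = None
    sequencer: Optional[str] = None
    collection_date: Optional[str] = None
    sequencing_institution: Optional[Actor] = None
    experimenter: Optional[Actor] = None


@dataclass
class PipelineProvenance:
    """One processing stage: tool, step, parameters and the reference data
    source (origin) it consumed, with actor and timeline attribution.

    ``origin_build`` is the genome assembly label; it is mandatory for any
    stage that assigns genomic coordinates, because a coordinate without its
    assembly is ambiguous.
    """

    test_id: Optional[str] = None
    stage: Optional[str] = None
    tool_name: Optional[str] = None
    tool_version: Optional[str] = None
    step: Optional[str] = None
    parameters: dict[str, str] = field(default_factory=dict)
    origin_source: Optional[str] = None
    origin_version: Optional[str] = None
    origin_build: Optional[str] = None
    analytics_institution: Optional[Actor] = None
    bioinformatician: Optional[Actor] = None
    received_date: Optional[str] = None

    #: stages that place variants on genomic coordinates and therefore must
    #: name the assembly they used
    COORDINATE_STAGES = ("alignment", "realignment_recalibration", "variant_calling")


@dataclass
class GenomicAlteration:
    """One normalized variant observation with its descriptive and functional
    annotation.  Records are stored in minimal representation (see the
    normalization module); equal variants are byte-equal here."""

    chromosome: Optional[str] = None  # without "chr" prefix
    position: Optional[int] = None  # 1-based
    ref_allele: Optional[str] = None
    alt_allele: Optional[str] = None
    genome_build: Optional[str] = None  # reached via provenance in storage
    zygosity: Optional[str] = None
    phasing: Optional[str] = None
    missing_flag: bool = False
    gene_symbol: Optional[str] = None
    entrez_id: Optional[int] = None
    ensembl_id: Optional[str] = None
    hgvs_g: Optional[str] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    dbsnp_id: Optional[str] = None
    dbvar_id: Optional[str] = None
    clinvar_id: Optional[str] = None
    cosmic_id: Optional[str] = None
    cytogenetic_location: Optional[str] = None
    codon: Optional[int] = None
    exon: Optional[int] = None
    molecular_effect: Optional[str] = None
    variant_type: Optional[str] = None
    functional_domain: Optional[str] = None


@dataclass
class QualityCheck:
    """Per-test sequencing quality summary."""

    test_id: Optional[str] = None
    base_quality: Optional[float] = None  # Phred
    depth_of_coverage: Optional[float] = None  # average fold
    mapping_quality: Optional[float] = None  # % mapped reads


@dataclass
class ClinicalAnnotation:
    """Clinical-knowledge annotation attached to a stored alteration."""

    alteration_id: Optional[int] = None
    annotation_class: Optional[str] = None
    annotation_value: Optional[str] = None
    documentation_date: Optional[str] = None


@dataclass
class MicrosatelliteInstability:
    test_id: Optional[str] = None
    msi_status: Optional[str] = None
    msi_score: Optional[float] = None  # fraction of unstable loci


@dataclass
class TumorMutationBurden:
    test_id: Optional[str] = None
    tmb_value: Optional[float] = None  # mutations per megabase
    panel_size: Optional[float] = None  # megabases assessed


# --------------------------------------------------------------------------
# Schema registry
# --------------------------------------------------------------------------

DOMAIN = "domain"
KEY = "key"  # surrogate primary key
FOREIGN_KEY = "foreign_key"
STRUCTURAL = "structural"


@dataclass(frozen=True)
class Attribute:
    """One physical column and the dataclass fields it serialises.

    ``fields`` has more than one entry only for composite (JSON) columns.
    """

    name: str
    role: str
    sql_type: str  # text | integer | real | boolean | timestamp | json
    fields: tuple[str, ...] = ()
    required: bool = False

    @property
    def dataclass_fields(self) -> tuple[str, ...]:
        return self.fields or (self.name,)

    @property
    def composite(self) -> bool:
        return len(self.dataclass_fields) > 1


@dataclass(frozen=True)
class EntitySpec:
    name: str
    dataclass_: type
    attributes: tuple[Attribute, ...]
    primary_key: tuple[str, ...]
    foreign_keys: tuple[tuple[tuple[str, ...], str, tuple[str, ...]], ...] = ()
    unique: tuple[tuple[str, ...], ...] = ()

    def domain_attributes(self) -> tuple[Attribute, ...]:
        return tuple(a for a in self.attributes if a.role == DOMAIN)

    def column(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)


def _attr(name, sql_type="text", *, role=DOMAIN, fields=(), required=False):
    return Attribute(name, role, sql_type, tuple(fields), required)


_ENTITY_SPECS: tuple[EntitySpec, ...] = (
    EntitySpec(
        name="CLINICAL_IDENTIFIER",
        dataclass_=ClinicalIdentifier,
        attributes=(
            _attr("institution_id", required=True),
            _attr("subject_id", required=True),
            _attr("test_id", required=True),
            _attr("submission_date", "timestamp", required=True),
            _attr("ordering_clinician"),
        ),
        primary_key=("subject_id", "test_id"),
    ),
    EntitySpec(
        name="EXPERIMENT_RELATED_INFORMATION",
        dataclass_=ExperimentInfo,
        attributes=(
            _attr("test_id", role=FOREIGN_KEY, required=True),
            _attr("test_description"),
            _attr("sequence_type", required=True),
            _attr("platform_technology"),
            _attr("sequencer"),
            _attr("collection_date", "timestamp"),
            _attr("sequencing_institution"),
            _attr("experimenter"),
        ),
        primary_key=("test_id",),
    ),
    EntitySpec(
        name="BIOINFORMATICS_PROTOCOL",
        dataclass_=PipelineProvenance,
        attributes=(
            _attr("protocol_id", "integer", role=KEY),
            _attr("test_id", role=FOREIGN_KEY, required=True),
            _attr("stage", role=STRUCTURAL, required=True),
            _attr("tool_name", required=True),
            _attr("tool_version"),
            _attr("step"),
            _attr("parameters", "json"),
            _attr(
                "origin",
                "json",
                fields=("origin_source", "origin_version", "origin_build"),
            ),
            _attr("analytics_institution"),
            _attr("bioinformatician"),
            _attr("received_date", "timestamp"),
        ),
        primary_key=("protocol_id",),
        foreign_keys=((("test_id",), "EXPERIMENT_RELATED_INFORMATION", ("test_id",)),),
    ),
    EntitySpec(
        name="GENOMIC_ALTERATION",
        dataclass_=GenomicAlteration,
        attributes=(
            _attr("alteration_id", "integer", role=KEY),
            _attr("subject_id", role=FOREIGN_KEY, required=True),
            _attr("test_id", role=FOREIGN_KEY, required=True),
            _attr("provenance_id", "integer", role=FOREIGN_KEY, required=True),
            _attr("chromosome", required=True),
            _attr("position", "integer", required=True),
            _attr("ref_allele", required=True),
            _attr("alt_allele", required=True),
            _attr("zygosity"),
            _attr("phasing"),
            _attr("missing_flag", "boolean"),
            _attr("gene", "json", fields=("gene_symbol", "entrez_id", "ensembl_id")),
            _attr(
                "variant_names",
                "json",
                fields=("hgvs_g", "hgvs_c", "hgvs_p", "dbsnp_id", "dbvar_id"),
            ),
            _attr("functional_refs", "json", fields=("clinvar_id", "cosmic_id")),
            _attr("cytogenetic_location"),
            _attr("codon", "integer"),
            _attr("exon", "integer"),
            _attr("molecular_effect"),
            _attr("variant_type"),
            _attr("functional_domain"),
        ),
        primary_key=("alteration_id",),
        foreign_keys=(
            (("subject_id", "test_id"), "CLINICAL_IDENTIFIER", ("subject_id", "test_id")),
            (("provenance_id",), "BIOINFORMATICS_PROTOCOL", ("protocol_id",)),
        ),
        unique=(("subject_id", "test_id", "chromosome", "position", "ref_allele", "alt_allele"),),
    ),
    EntitySpec(
        name="QUALITY_CHECK",
        dataclass_=QualityCheck,
        attributes=(
            _attr("test_id", role=FOREIGN_KEY, required=True),
            _attr("base_quality", "real"),
            _attr("depth_of_coverage", "real"),
            _attr("mapping_quality", "real"),
        ),
        primary_key=("test_id",),
        foreign_keys=((("test_id",), "EXPERIMENT_RELATED_INFORMATION", ("test_id",)),),
    ),
    EntitySpec(
        name="CLINICAL_ANNOTATION",
        dataclass_=ClinicalAnnotation,
        attributes=(
            _attr("annotation_id", "integer", role=KEY),
            _attr("alteration_id", "integer", role=FOREIGN_KEY, required=True),
            _attr("annotation_class", required=True),
            _attr("annotation_value"),
            _attr("documentation_date", "timestamp"),
        ),
        primary_key=("annotation_id",),
        foreign_keys=((("alteration_id",), "GENOMIC_ALTERATION", ("alteration_id",)),),
    ),
    EntitySpec(
        name="MICROSATELLITE_INSTABILITY",
        dataclass_=MicrosatelliteInstability,
        attributes=(
            _attr("test_id", role=FOREIGN_KEY, required=True),
            _attr("msi_status", required=True),
            _attr("msi_score", "real"),
        ),
        primary_key=("test_id",),
        foreign_keys=((("test_id",), "EXPERIMENT_RELATED_INFORMATION", ("test_id",)),),
    ),
    EntitySpec(
        name="TUMOR_MUTATION_BURDEN",
        dataclass_=TumorMutationBurden,
        attributes=(
            _attr("test_id", role=FOREIGN_KEY, required=True),
            _attr("tmb_value", "real", required=True),
            _attr("panel_size", "real"),
        ),
        primary_key=("test_id",),
        foreign_keys=((("test_id",), "EXPERIMENT_RELATED_INFORMATION", ("test_id",)),),
    ),
)


class SchemaRegistry:
    """Live registry of entity specs; the single source of truth for
    validation, DDL emission and introspection.  User extensions register
    additional entities at run time."""

    def __init__(self, specs: Iterable[EntitySpec] = _ENTITY_SPECS,
                 vocabulary: Vocabulary | None = None):
        self._specs: dict[str, EntitySpec] = {}
        self.vocabulary = vocabulary or Vocabulary()
        for s in specs:
            self.register(s)

    def register(self, spec: EntitySpec) -> None:
        if spec.name in self._specs:
            raise ConfigurationError(f"entity {spec.name} already registered")
        self._specs[spec.name] = spec

    @property
    def entities(self) -> tuple[EntitySpec, ...]:
        return tuple(self._specs.values())

    def entity(self, name: str) -> EntitySpec:
        try:
            return self._specs[name]
        except KeyError:
            raise ConfigurationError(f"unknown entity {name!r}") from None

    def entity_for(self, record: Any) -> EntitySpec:
        for s in self._specs.values():
            if isinstance(record, s.dataclass_):
                return s
        raise TypeError(f"unknown entity type {type(record).__name__}")


#: default registry with the eight model entities
REGISTRY = SchemaRegistry()


# --------------------------------------------------------------------------
# Record validation
# --------------------------------------------------------------------------


@dataclass
class Violation:
    field: str
    message: str


@dataclass
class ValidationReport:
    entity: str
    ok: bool
    violations: list[Violation]

    def __bool__(self) -> bool:
        return self.ok


def _check_vocab(violations, vocab, name, value, fieldname, allow_none=True):
    if value is None:
        if not allow_none:
            violations.append(Violation(fieldname, "value required"))
        return
    if not vocab.contains(name, value):
        violations.append(
            Violation(fieldname, f"{value!r} not in vocabulary {name!r}")
        )


def validate_record(record: Any, registry: SchemaRegistry = REGISTRY) -> ValidationReport:
    """Validate one entity instance against the model's invariants.

    Total over well-typed inputs: always returns a report, never mutates the
    record.  Unknown entity types raise ``TypeError`` (the one contract
    violation that is a caller bug, not a data problem).
    """
    spec = registry.entity_for(record)  # raises TypeError for unknown types
    v: list[Violation] = []
    vocab = registry.vocabulary

    # generic requiredness from the registry
    record_fields = {f.name for f in dc_fields(record)}
    for attr in spec.attributes:
        if attr.role == KEY:
            continue
        for fname in attr.dataclass_fields:
            if fname not in record_fields:
                continue  # storage-only column (surrogate/FK) with no field
            if attr.required and getattr(record, fname, None) in (None, ""):
                # composite columns: requiredness applies to the column, so
                # only flag when every member field is missing
                if attr.composite and any(
                    getattr(record, f, None) not in (None, "")
                    for f in attr.dataclass_fields
                ):
                    continue
                v.append(Violation(fname, "value required"))

    # per-entity rules
    if isinstance(record, ClinicalIdentifier):
        if record.submission_date is not None and not _is_iso8601(record.submission_date):
            v.append(Violation("submission_date", "not ISO 8601"))
    elif isinstance(record, ExperimentInfo):
        _check_vocab(v, vocab, "sequence_type", record.sequence_type, "sequence_type")
        if record.collection_date is not None and not _is_iso8601(record.collection_date):
            v.append(Violation("collection_date", "not ISO 8601"))
    elif isinstance(record, PipelineProvenance):
        _check_vocab(v, vocab, "pipeline_stage", record.stage, "stage")
        if (
            record.stage in PipelineProvenance.COORDINATE_STAGES
            and not record.origin_build
        ):
            v.append(
                Violation(
                    "origin_build",
                    f"genome build required for coordinate-assigning stage {record.stage!r}",
                )
            )
        if record.received_date is not None and not _is_iso8601(record.received_date):
            v.append(Violation("received_date", "not ISO 8601"))
    elif isinstance(record, GenomicAlteration):
        for fname in ("ref_allele", "alt_allele"):
            allele = getattr(record, fname)
            if allele is not None and not _ALLELE_RE.match(allele):
                v.append(
                    Violation(fname, f"{allele!r} not [ACGTN]+ (symbolic alleles rejected)")
                )
        if (
            record.ref_allele is not None
            and record.ref_allele == record.alt_allele
        ):
            v.append(Violation("alt_allele", "ref equals alt"))
        if record.position is not None and record.position < 1:
            v.append(Violation("position", "position must be >= 1"))
        if not record.genome_build:
            v.append(Violation("genome_build", "value required"))
        if record.chromosome is not None and record.chromosome.lower().startswith("chr"):
            v.append(Violation("chromosome", "stored without 'chr' prefix"))
        _check_vocab(v, vocab, "zygosity", record.zygosity, "zygosity")
        _check_vocab(v, vocab, "phasing", record.phasing, "phasing")
        _check_vocab(v, vocab, "variant_type", record.variant_type, "variant_type")
    elif isinstance(record, QualityCheck):
        if record.base_quality is not None and record.base_quality < 0:
            v.append(Violation("base_quality", "must be >= 0"))
        if record.depth_of_coverage is not None and record.depth_of_coverage < 0:
            v.append(Violation("depth_of_coverage", "must be >= 0"))
        if record.mapping_quality is not None and not (0 <= record.mapping_quality <= 100):
            v.append(Violation("mapping_quality", "must be in [0, 100]"))
    elif isinstance(record, ClinicalAnnotation):
        _check_vocab(
            v, vocab, "annotation_class", record.annotation_class, "annotation_class",
            allow_none=False,
        )
    elif isinstance(record, MicrosatelliteInstability):
        _check_vocab(v, vocab, "msi_status", record.msi_status, "msi_status")
        if record.msi_score is not None and not (0 <= record.msi_score <= 1):
            v.append(Violation("msi_score", "must be in [0, 1]"))
    elif isinstance(record, TumorMutationBurden):
        if record.tmb_value is not None and record.tmb_value < 0:
            v.append(Violation("tmb_value", "must be >= 0"))

    return ValidationReport(spec.name, ok=not v, violations=v)


# --------------------------------------------------------------------------
# Row (de)serialisation
# --------------------------------------------------------------------------


def _to_storage(value: Any) -> Any:
    if isinstance(value, Actor):
        return str(value)
    return value


def entity_to_row(record: Any, registry: SchemaRegistry = REGISTRY) -> dict[str, Any]:
    """Flatten a dataclass instance to a column -> value dict.

    Composite attributes become JSON text; ``Actor`` values their pipe form.
    Key columns absent from the dataclass (surrogate ids) are omitted.
    """
    spec = registry.entity_for(record)
    fieldnames = {f.name for f in dc_fields(record)}
    row: dict[str, Any] = {}
    for attr in spec.attributes:
        if attr.composite:
            payload = {
                f: _to_storage(getattr(record, f))
                for f in attr.dataclass_fields
                if f in fieldnames and getattr(record, f) is not None
            }
            if attr.name == "parameters":
                payload = getattr(record, "parameters", {}) or {}
            row[attr.name] = json.dumps(payload, sort_keys=True) if payload else None
        elif attr.name == "parameters":
            params = getattr(record, "parameters", {}) or {}
            row[attr.name] = json.dumps(params, sort_keys=True) if params else None
        elif attr.name in fieldnames:
            value = _to_storage(getattr(record, attr.name))
            if attr.sql_type == "boolean" and value is not None:
                value = int(bool(value))
            row[attr.name] = value
    return row


_ACTOR_FIELDS = {
    "ordering_clinician",
    "sequencing_institution",
    "experimenter",
    "analytics_institution",
    "bioinformatician",
}


def entity_from_row(entity_name: str, row: dict[str, Any],
                    registry: SchemaRegistry = REGISTRY) -> Any:
    """Inverse of :func:`entity_to_row` for one catalog row."""
    spec = registry.entity(entity_name)
    fieldnames = {f.name for f in dc_fields(spec.dataclass_)}
    kwargs: dict[str, Any] = {}
    for attr in spec.attributes:
        if attr.name not in row:
            continue
        raw = row[attr.name]
        if attr.name == "parameters":
            kwargs["parameters"] = json.loads(raw) if raw else {}
        elif attr.composite:
            payload = json.loads(raw) if raw else {}
            for f in attr.dataclass_fields:
                if f in fieldnames:
                    kwargs[f] = payload.get(f)
        elif attr.name in fieldnames:
            value = raw
            if attr.sql_type == "boolean" and value is not None:
                value = bool(value)
            if attr.name in _ACTOR_FIELDS and isinstance(value, str):
                value = Actor.parse(value)
            kwargs[attr.name] = value
    return spec.dataclass_(**kwargs)


# --------------------------------------------------------------------------
# DDL emission
# --------------------------------------------------------------------------

_SQL_TYPES = {
    "ansi": {
        "text": "VARCHAR(255)",
        "integer": "INTEGER",
        "real": "DOUBLE PRECISION",
        "boolean": "SMALLINT",
        "timestamp": "VARCHAR(64)",
        "json": "VARCHAR(2000)",
    },
    "sqlite": {
        "text": "TEXT",
        "integer": "INTEGER",
        "real": "REAL",
        "boolean": "INTEGER",
        "timestamp": "TEXT",
        "json": "TEXT",
    },
}

SUPPORTED_DIALECTS = tuple(_SQL_TYPES)


def emit_ddl(dialect: str = "sqlite", *, idempotent: bool = False,
             registry: SchemaRegistry = REGISTRY) -> str:
    """Emit the relational DDL for every registered entity.

    With ``idempotent=True`` tables are created with ``IF NOT EXISTS`` so the
    script can run twice; otherwise a second run on the same database fails on
    the first existing table.
    """
    if dialect not in _SQL_TYPES:
        raise ConfigurationError(
            f"unsupported dialect {dialect!r}; supported: {', '.join(SUPPORTED_DIALECTS)}"
        )
    types = _SQL_TYPES[dialect]
    exists = "IF NOT EXISTS " if idempotent else ""
    statements: list[str] = []
    for spec in registry.entities:
        cols: list[str] = []
        for attr in spec.attributes:
            col = f"    {attr.name} {types[attr.sql_type]}"
            if attr.role == KEY and len(spec.primary_key) == 1 and spec.primary_key[0] == attr.name:
                col += " PRIMARY KEY"
            elif attr.required:
                col += " NOT NULL"
            cols.append(col)
        constraints: list[str] = []
        if not any(a.role == KEY for a in spec.attributes):
            constraints.append(f"    PRIMARY KEY ({', '.join(spec.primary_key)})")
        for local, table, remote in spec.foreign_keys:
            constraints.append(
                f"    FOREIGN KEY ({', '.join(local)}) REFERENCES {table} ({', '.join(remote)})"
            )
        for uniq in spec.unique:
            constraints.append(f"    UNIQUE ({', '.join(uniq)})")
        body = ",\n".join(cols + constraints)
        statements.append(f"CREATE TABLE {exists}{spec.name} (\n{body}\n);")
    return "\n\n".join(statements) + "\n"


# --------------------------------------------------------------------------
# Introspection
# --------------------------------------------------------------------------


@dataclass
class SchemaSummary:
    entity_count: int
    attribute_total: int
    attributes_per_entity: dict[str, int]

    def as_dict(self) -> dict[str, Any]:
        return {
            "entity_count": self.entity_count,
            "attribute_total": self.attribute_total,
            "attributes_per_entity": dict(self.attributes_per_entity),
        }


def introspect_schema(registry: SchemaRegistry = REGISTRY) -> SchemaSummary:
    """Entity and domain-attribute counts derived from the live registry."""
    per_entity = {
        spec.name: len(spec.domain_attributes()) for spec in registry.entities
    }
    return SchemaSummary(
        entity_count=len(per_entity),
        attribute_total=sum(per_entity.values()),
        attributes_per_entity=per_entity,
    )


def introspect_database(connection, registry: SchemaRegistry = REGISTRY) -> SchemaSummary:
    """Same counts read back from a live database catalog.

    Catalog columns are classified through the registry (surrogate keys,
    foreign keys and structural discriminators are not domain attributes), so
    a correct deployment reports exactly the registry's counts.
    """
    cur = connection.execute(
        "SELECT name FROM sqlite_master WHERE type = 'table'"
    )
    tables = {r[0] for r in cur.fetchall()}
    per_entity: dict[str, int] = {}
    for spec in registry.entities:
        if spec.name not in tables:
            continue
        cols = [r[1] for r in connection.execute(f"PRAGMA table_info({spec.name})")]
        n = 0
        for c in cols:
            try:
                attr = spec.column(c)
            except KeyError:
                continue  # column unknown to the model: not a domain attribute
            if attr.role == DOMAIN:
                n += 1
        per_entity[spec.name] = n
    return SchemaSummary(
        entity_count=len(per_entity),
        attribute_total=sum(per_entity.values()),
        attributes_per_entity=per_entity,
    )


def create_schema(connection, *, idempotent: bool = False,
                  registry: SchemaRegistry = REGISTRY) -> SchemaSummary:
    """Execute the embedded-database DDL plus auxiliary structures (the alias
    index table, which is infrastructure, not a model entity)."""
    connection.executescript(emit_ddl("sqlite", idempotent=idempotent, registry=registry))
    connection.executescript(AUX_DDL)
    connection.commit()
    return introspect_database(connection, registry)


#: auxiliary (non-entity) structures: the persisted variant alias index
AUX_DDL = """
CREATE TABLE IF NOT EXISTS VARIANT_ALIAS (
    alias_key TEXT NOT NULL,
    alias_kind TEXT NOT NULL,
    alteration_id INTEGER NOT NULL,
    FOREIGN KEY (alteration_id) REFERENCES GENOMIC_ALTERATION (alteration_id)
);
CREATE INDEX IF NOT EXISTS idx_variant_alias_key ON VARIANT_ALIAS (alias_key);
"""
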