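"""Entity model: validation contracts, DDL shape, registry introspection."""

import copy
import sqlite3

import pytest

from cgdm.errors import ConfigurationError
from cgdm.schema_model import (
    REGISTRY,
    Actor,
    Attribute,
    ClinicalAnnotation,
    ClinicalIdentifier,
    EntitySpec,
    GenomicAlteration,
    MicrosatelliteInstability,
    PipelineProvenance,
    QualityCheck,
    SchemaRegistry,
    TumorMutationBurden,
    create_schema,
    emit_ddl,
    entity_from_row,
    entity_to_row,
    introspect_database,
    introspect_schema,
    validate_record,
)


def _alteration(**kw):
    base = dict(
        chromosome="7", position=140453136, ref_allele="A", alt_allele="T",
        genome_build="GRCh37", zygosity="heterozygous", phasing="unphased",
        gene_symbol="BRAF", variant_type="SNV",
    )
    base.update(kw)
    return GenomicAlteration(**base)


class TestValidateRecord:
    def test_identity_alleles_fail(self):
        report = validate_record(_alteration(ref_allele="C", alt_allele="C"))
        assert not report.ok
        assert any("ref equals alt" in v.message for v in report.violations)

    def test_mapping_quality_range(self):
        report = validate_record(QualityCheck(test_id="T", mapping_quality=101))
        assert not report.ok
        assert any(v.field == "mapping_quality" for v in report.violations)

    def test_valid_clinical_annotation_passes(self):
        record = ClinicalAnnotation(
            alteration_id=1, annotation_class="fda_qualified_biomarker",
            annotation_value="BRAF V600E", documentation_date="2024-01-01",
        )
        assert validate_record(record).ok

    @pytest.mark.parametrize(
        "record, bad_field",
        [
            (_alteration(ref_allele="<DEL>"), "ref_allele"),
            (_alteration(position=0), "position"),
            (_alteration(genome_build=None), "genome_build"),
            (_alteration(zygosity="both"), "zygosity"),
            (QualityCheck(test_id="T", depth_of_coverage=-2), "depth_of_coverage"),
            (MicrosatelliteInstability(test_id="T", msi_status="MSI-H",
                                       msi_score=1.5), "msi_score"),
            (TumorMutationBurden(test_id="T", tmb_value=-1), "tmb_value"),
            (ClinicalIdentifier(institution_id="I", subject_id="S", test_id="T",
                                submission_date="not-a-date"), "submission_date"),
        ],
    )
    def test_invariant_violations_reported(self, record, bad_field):
        report = validate_record(record)
        assert not report.ok
        assert any(v.field == bad_field for v in report.violations)

    def test_validation_never_mutates(self):
        record = _alteration(zygosity="nonsense")
        before = copy.deepcopy(record)
        validate_record(record)
        assert record == before

    def test_unknown_entity_type_raises(self):
        with pytest.raises(TypeError):
            validate_record(object())

    def test_valid_alteration_passes(self):
        assert validate_record(_alteration()).ok


class TestDdl:
    def test_table_count_is_eight(self):
        ddl = emit_ddl("ansi")
        assert ddl.count("CREATE TABLE") == 8

    def test_domain_column_count_is_46(self):
        """Parsed columns, excluding surrogate keys, foreign keys and the
        stage discriminator, total the model's 46 domain attributes."""
        total = 0
        for spec in REGISTRY.entities:
            non_domain = {
                a.name for a in spec.attributes if a.role != "domain"
            }
            ddl = emit_ddl("sqlite")
            block = ddl.split(f"CREATE TABLE {spec.name} (")[1].split(");")[0]
            for line in block.splitlines():
                line = line.strip().rstrip(",")
                if not line or line.startswith(("PRIMARY KEY", "FOREIGN KEY", "UNIQUE")):
                    continue
                name = line.split()[0]
                if name not in non_domain:
                    total += 1
        assert total == 46

    def test_unsupported_dialect(self):
        with pytest.raises(ConfigurationError):
            emit_ddl("nosuch")

    def test_ddl_round_trip_counts(self):
        conn = sqlite3.connect(":memory:")
        summary = create_schema(conn)
        assert summary.entity_count == 8
        assert summary.attribute_total == 46
        assert summary.as_dict() == introspect_schema().as_dict()

    def test_second_run_rejected_unless_idempotent(self):
        conn = sqlite3.connect(":memory:")
        conn.executescript(emit_ddl("sqlite"))
        with pytest.raises(sqlite3.OperationalError):
            conn.executescript(emit_ddl("sqlite"))
        conn.executescript(emit_ddl("sqlite", idempotent=True))  # no error


class TestIntrospection:
    def test_counts_match_model_shape(self):
        summary = introspect_schema()
        assert summary.entity_count == 8
        assert summary.attribute_total == 46

    def test_counts_come_from_live_registry(self):
        registry = SchemaRegistry()
        registry.register(
            EntitySpec(
                name="USER_EXTENSION",
                dataclass_=type("UserExtension", (), {}),
                attributes=(Attribute("payload", "domain", "text"),),
                primary_key=("payload",),
            )
        )
        summary = introspect_schema(registry)
        assert summary.entity_count == 9
        assert summary.attribute_total == 47

    def test_database_catalog_agrees(self, connection):
        assert introspect_database(connection).as_dict() == introspect_schema().as_dict()


class TestRowSerialisation:
    def test_composite_columns_round_trip(self):
        record = _alteration(
            entrez_id=673, ensembl_id="ENSG00000157764",
            hgvs_p="NP_004324.2:p.V600E", dbsnp_id="rs113488022",
            clinvar_id="VCV000013961", cosmic_id="COSV56056643",
        )
        row = entity_to_row(record)
        assert set(row) <= {a.name for a in REGISTRY.entity("GENOMIC_ALTERATION").attributes}
        back = entity_from_row("GENOMIC_ALTERATION", row)
        back.genome_build = record.genome_build  # build travels via provenance
        assert back == record

    def test_actor_round_trip(self):
        record = ClinicalIdentifier(
            institution_id="INST", subject_id="S1", test_id="T1",
            submission_date="2024-05-01",
            ordering_clinician=Actor("General Hospital", "clinician"),
        )
        back = entity_from_row("CLINICAL_IDENTIFIER", entity_to_row(record))
        assert back == record

    def test_provenance_parameters_round_trip(self):
        record = PipelineProvenance(
            test_id="T1", stage="variant_calling", tool_name="caller",
            tool_version="4.2", step="calling", parameters={"min_qual": "30"},
            origin_source="assembly", origin_version="p13", origin_build="GRCh37",
        )
        back = entity_from_row("BIOINFORMATICS_PROTOCOL", entity_to_row(record))
        assert back == record
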