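"""Filtered queries with provenance, pharmacogenotype derivation, IWPC dosing
against the arithmetic oracle, and the rule engine."""

import itertools

import pytest
import yaml

from conftest import make_manifest

from cgdm.errors import ConfigurationError, DataError, GenotypeUnknownError, UsageError
from cgdm.io_etl import load_dataset
from cgdm.query_cds import (
    CYP2C9_DIPLOTYPES,
    VKORC1_STATES,
    AlleleDefinitions,
    CdsRule,
    DosingInput,
    DosingKnowledge,
    PgxGenotype,
    QueryFilter,
    clinical_warfarin_dose,
    derive_pgx_genotype,
    evaluate_rules,
    iwpc_warfarin_dose,
    query_variants,
    validate_rules,
)
from cgdm.schema_model import ClinicalAnnotation

from oracles import oracle_weekly_dose

MAF_HEADER = ("Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\t"
              "Tumor_Seq_Allele2\tVariant_Classification\tNCBI_Build\t"
              "HGVSp_Short\tdbSNP_RS\tTumor_Sample_Barcode\n")
BRAF_ROW = ("BRAF\t7\t140453136\tA\tT\tMissense_Mutation\tGRCh37\t"
            "p.V600E\trs113488022\tMEL01\n")


@pytest.fixture
def melanoma_db(connection, tmp_path):
    """One melanoma-style subject carrying the canonical BRAF substitution."""
    path = tmp_path / "mel.maf"
    path.write_text(MAF_HEADER + BRAF_ROW, encoding="utf-8")
    manifest = make_manifest(path, test_id="MEL-T1", build="GRCh37", mode="trim_only")
    manifest.source_format = "MAF"
    load_dataset(manifest, connection)
    return connection


class TestQueryVariants:
    def test_gene_filter_returns_record_with_context(self, melanoma_db):
        results = query_variants(QueryFilter(gene_symbol="BRAF"), melanoma_db)
        assert len(results) == 1
        r = results[0]
        assert r.alteration.position == 140453136
        assert r.alteration.genome_build == "GRCh37"
        assert len(r.provenance) >= 1
        assert all(p.origin_build for p in r.provenance
                   if p.stage in ("alignment", "variant_calling"))
        assert r.quality is not None

    def test_provenance_complete_on_every_result(self, loaded_db):
        conn, _, _ = loaded_db
        results = query_variants(QueryFilter(genome_build="FIXTURE1"), conn)
        assert results
        for r in results:
            assert r.provenance and r.alteration.genome_build == "FIXTURE1"
        positions = [(r.alteration.chromosome, r.alteration.position) for r in results]
        assert positions == sorted(positions)

    def test_depth_threshold_excludes_all(self, melanoma_db):
        results = query_variants(QueryFilter(min_depth=10_000.0), melanoma_db)
        assert results == []

    def test_empty_filter_is_usage_error(self, melanoma_db):
        with pytest.raises(UsageError):
            query_variants(QueryFilter(), melanoma_db)

    def test_annotation_filter_matches_annotated_set_only(self, melanoma_db):
        before = query_variants(
            QueryFilter(annotation_class="fda_qualified_biomarker"), melanoma_db
        )
        assert before == []
        alteration_id = melanoma_db.execute(
            "SELECT alteration_id FROM GENOMIC_ALTERATION"
        ).fetchone()[0]
        melanoma_db.execute(
            "INSERT INTO CLINICAL_ANNOTATION (alteration_id, annotation_class, "
            "annotation_value, documentation_date) VALUES (?, ?, ?, ?)",
            (alteration_id, "fda_qualified_biomarker", "BRAF V600E", "2024-01-01"),
        )
        after = query_variants(
            QueryFilter(annotation_class="fda_qualified_biomarker"), melanoma_db
        )
        assert [r.alteration_id for r in after] == [alteration_id]

    def test_reannotation_leaves_alteration_rows_untouched(self, melanoma_db):
        count = lambda: melanoma_db.execute(
            "SELECT COUNT(*) FROM GENOMIC_ALTERATION").fetchone()[0]
        before = count()
        alteration_id = melanoma_db.execute(
            "SELECT alteration_id FROM GENOMIC_ALTERATION").fetchone()[0]
        melanoma_db.execute(
            "INSERT INTO CLINICAL_ANNOTATION (alteration_id, annotation_class) "
            "VALUES (?, 'acmg_actionable')", (alteration_id,))
        assert count() == before


class TestDerivePgxGenotype:
    def test_recovers_every_constructed_genotype(self, pgx_db):
        conn, cohort = pgx_db
        for subject in cohort.subjects:
            genotype = derive_pgx_genotype(subject.subject_id, conn,
                                           cohort.allele_definitions)
            assert (genotype.cyp2c9_star, genotype.vkorc1_1639) == \
                cohort.expected[subject.subject_id], subject.subject_id

    def test_uncovered_subject_is_unknown(self, pgx_db):
        conn, cohort = pgx_db
        uncovered = [s for s in cohort.subjects if not s.covered]
        assert uncovered
        for subject in uncovered:
            genotype = derive_pgx_genotype(subject.subject_id, conn,
                                           cohort.allele_definitions)
            assert genotype.cyp2c9_star == "unknown"
            assert genotype.vkorc1_1639 == "unknown"

    def test_absent_subject_is_unknown(self, pgx_db):
        conn, cohort = pgx_db
        genotype = derive_pgx_genotype("NOBODY", conn, cohort.allele_definitions)
        assert genotype == PgxGenotype("unknown", "unknown")

    def test_conflicting_zygosity_evidence_raises(self, pgx_db):
        conn, cohort = pgx_db
        defn = cohort.allele_definitions.vkorc1_1639
        carrier = conn.execute(
            "SELECT subject_id, test_id, provenance_id FROM GENOMIC_ALTERATION "
            "WHERE position = ? AND zygosity = 'heterozygous' LIMIT 1",
            (defn["position"],),
        ).fetchone()
        assert carrier is not None
        subject, test_id, prov = carrier
        conn.execute(
            "INSERT INTO CLINICAL_IDENTIFIER (institution_id, subject_id, "
            "test_id, submission_date) VALUES ('INST', ?, ?, '2024-01-01')",
            (subject, test_id + "x"),
        )
        conn.execute(
            "INSERT INTO GENOMIC_ALTERATION (subject_id, test_id, provenance_id, "
            "chromosome, position, ref_allele, alt_allele, zygosity) "
            "VALUES (?, ?, ?, ?, ?, ?, ?, 'homozygous')",
            (subject, test_id + "x", prov, defn["chromosome"],
             defn["position"], defn["ref"], defn["alt"]),
        )
        with pytest.raises(DataError) as err:
            derive_pgx_genotype(subject, conn, cohort.allele_definitions)
        assert "zygosity" in str(err.value)


GRID_COVARIATES = list(itertools.product(
    (4, 7), (160.0, 182.5), (60.0, 95.0),
    ("white", "asian", "black_or_african_american", "mixed_or_missing"),
    (False, True), (False, True),
))


@pytest.fixture(scope="module")
def coeffs():
    import importlib.resources as resources

    text = resources.files("cgdm.knowledge").joinpath(
        "iwpc_warfarin.yaml").read_text()
    return yaml.safe_load(text)


class TestIwpcDose:

    def test_matches_arithmetic_oracle_on_full_grid(self, coeffs):
        genotypes = [
            (c, v) for c in CYP2C9_DIPLOTYPES for v in VKORC1_STATES
            if c != "unknown" and v != "unknown"
        ]
        for age, height, weight, race, inducer, amio in GRID_COVARIATES:
            for cyp, vk in genotypes:
                result = iwpc_warfarin_dose(DosingInput(
                    age, height, weight, race, inducer, amio,
                    PgxGenotype(cyp, vk)))
                expected = oracle_weekly_dose(
                    coeffs["pharmacogenetic"], age_decades=age, height_cm=height,
                    weight_kg=weight, race_group=race, enzyme_inducer=inducer,
                    amiodarone=amio, cyp2c9=cyp, vkorc1=vk)
                assert result.weekly_dose_mg == pytest.approx(expected, rel=1e-12)
                assert result.weekly_dose_mg > 0

    def test_monotone_in_variant_allele_burden(self):
        cyp_order = ["*1/*1", "*1/*2", "*1/*3", "*2/*2", "*2/*3", "*3/*3"]
        for age, height, weight, race, inducer, amio in GRID_COVARIATES:
            for vk in ("GG", "GA", "AA"):
                doses = [
                    iwpc_warfarin_dose(DosingInput(
                        age, height, weight, race, inducer, amio,
                        PgxGenotype(c, vk))).weekly_dose_mg
                    for c in cyp_order
                ]
                assert all(a > b for a, b in zip(doses, doses[1:])), (vk, doses)
            for cyp in ("*1/*1", "*2/*3"):
                doses = [
                    iwpc_warfarin_dose(DosingInput(
                        age, height, weight, race, inducer, amio,
                        PgxGenotype(cyp, v))).weekly_dose_mg
                    for v in ("GG", "GA", "AA")
                ]
                assert doses[0] > doses[1] > doses[2]

    def test_vkorc1_gg_dose_exceeds_aa(self):
        base = dict(age_decades=6, height_cm=170.0, weight_kg=75.0,
                    race_group="white", enzyme_inducer=False, amiodarone=False)
        gg = iwpc_warfarin_dose(DosingInput(**base, genotype=PgxGenotype("*1/*1", "GG")))
        aa = iwpc_warfarin_dose(DosingInput(**base, genotype=PgxGenotype("*1/*1", "AA")))
        assert gg.weekly_dose_mg > aa.weekly_dose_mg

    def test_age_effect_within_analytic_bound(self, coeffs):
        # doubling age from a to 2a moves sqrt(dose) by exactly beta_age*a
        base = dict(height_cm=170.0, weight_kg=75.0, race_group="white",
                    enzyme_inducer=False, amiodarone=False,
                    genotype=PgxGenotype("*1/*1", "GG"))
        young = iwpc_warfarin_dose(DosingInput(age_decades=4, **base))
        old = iwpc_warfarin_dose(DosingInput(age_decades=8, **base))
        beta = coeffs["pharmacogenetic"]["age_decades"]
        delta = old.sqrt_weekly_dose - young.sqrt_weekly_dose
        assert delta == pytest.approx(beta * 4, rel=1e-12)

    def test_unknown_genotype_falls_back_to_clinical(self):
        result = iwpc_warfarin_dose(DosingInput(
            6, 170.0, 75.0, "white", False, False, PgxGenotype()))
        assert result.model == "clinical"
        assert not any("cyp2c9" in t.name for t in result.terms)

    def test_unknown_genotype_refusal_names_fallback(self):
        with pytest.raises(GenotypeUnknownError) as err:
            iwpc_warfarin_dose(
                DosingInput(6, 170.0, 75.0, "white", False, False, PgxGenotype()),
                allow_clinical_fallback=False)
        assert "clinical" in str(err.value)

    def test_missing_covariate_refused(self):
        with pytest.raises(UsageError):
            iwpc_warfarin_dose(DosingInput(
                6, 170.0, None, "white", False, False, PgxGenotype("*1/*1", "GG")))

    def test_audit_trail_sums_to_predictor(self):
        result = iwpc_warfarin_dose(DosingInput(
            5, 165.0, 70.0, "asian", False, True, PgxGenotype("*1/*3", "GA")))
        total = sum(t.contribution for t in result.terms)
        assert total == pytest.approx(result.sqrt_weekly_dose)
        assert result.weekly_dose_mg == pytest.approx(total * total)
        assert result.daily_dose_mg == pytest.approx(result.weekly_dose_mg / 7)


class TestRuleEngine:
    def _warfarin_rule(self):
        return CdsRule(
            rule_id="warfarin-dose", trigger={"genotype": "pgx"},
            action="dose_calculation",
            knowledge_ref="IWPC warfarin dosing algorithm",
            parameters={"dosing_function": "iwpc_warfarin"},
        )

    def test_alias_rule_fires_one_alert(self, melanoma_db):
        rules = [CdsRule("braf-alert", {"alias": "BRAF:V600E"}, "alert",
                         "melanoma biomarker list",
                         {"message": "BRAF V600E detected"})]
        actions = evaluate_rules("MEL01", rules, melanoma_db)
        assert len(actions) == 1
        assert actions[0].action == "alert"
        assert actions[0].alteration_ids
        assert actions[0].knowledge_ref == "melanoma biomarker list"

    def test_empty_subject_triggers_nothing(self, melanoma_db):
        rules = [CdsRule("braf-alert", {"alias": "BRAF:V600E"}, "alert", "kb")]
        assert evaluate_rules("NOBODY", rules, melanoma_db) == []

    def test_unregistered_dosing_function_fails_validation(self):
        rule = self._warfarin_rule()
        rule.parameters["dosing_function"] = "nosuch"
        with pytest.raises(ConfigurationError):
            validate_rules([rule])

    def test_dose_action_matches_standalone_dose(self, pgx_db):
        conn, cohort = pgx_db
        # a subject that carries defining variant alleles, so the action can
        # cite evidence rows
        subject = next(s for s in cohort.subjects
                       if s.covered and s.cyp2c9 != "*1/*1")
        covariates = DosingInput(genotype=PgxGenotype(), **subject.covariates)
        actions = evaluate_rules(
            subject.subject_id, [self._warfarin_rule()], conn,
            allele_definitions=cohort.allele_definitions, covariates=covariates)
        assert len(actions) == 1
        dose = actions[0].dose
        genotype = derive_pgx_genotype(subject.subject_id, conn,
                                       cohort.allele_definitions)
        standalone = iwpc_warfarin_dose(
            DosingInput(genotype=genotype, **subject.covariates))
        assert dose.weekly_dose_mg == pytest.approx(standalone.weekly_dose_mg)
        assert actions[0].alteration_ids  # evidence rows cited

    def test_evaluation_is_deterministic(self, melanoma_db):
        rules = [CdsRule("braf-alert", {"alias": "BRAF:V600E"}, "alert", "kb")]
        first = evaluate_rules("MEL01", rules, melanoma_db)
        second = evaluate_rules("MEL01", rules, melanoma_db)
        assert [(a.rule_id, a.alteration_ids) for a in first] == \
            [(a.rule_id, a.alteration_ids) for a in second]
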