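import sqlite3
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from cgdm import create_schema
from cgdm.fixtures import (
    FixtureSpec,
    make_fixture_allele_definitions,
    make_pgx_cohort,
    make_reference_window,
    make_vcf,
)
from cgdm.io_etl import EtlManifest, ReferenceProvider, load_dataset
from cgdm.schema_model import PipelineProvenance, QualityCheck


@pytest.fixture
def connection():
    conn = sqlite3.connect(":memory:")
    conn.execute("PRAGMA foreign_keys = ON")
    create_schema(conn)
    yield conn
    conn.close()


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=11, n_subjects=5, n_variants_per_subject=6,
                       fraction_nonminimal=1.0)


@pytest.fixture(scope="session")
def window(fixture_spec):
    return make_reference_window(fixture_spec)


@pytest.fixture(scope="session")
def corpus_vcf(fixture_spec, window, tmp_path_factory):
    path = tmp_path_factory.mktemp("corpus") / "variants.vcf"
    text, truth = make_vcf(fixture_spec, window, path)
    return path, truth


def make_provenance(build="FIXTURE1"):
    return [
        PipelineProvenance(
            stage="alignment", tool_name="fix-aln", tool_version="1",
            step="read alignment", origin_source="synthetic assembly",
            origin_version="1", origin_build=build,
        ),
        PipelineProvenance(
            stage="variant_calling", tool_name="fix-call", tool_version="1",
            step="variant calling", origin_source="synthetic assembly",
            origin_version="1", origin_build=build,
        ),
    ]


def make_manifest(path, test_id="T1", build="FIXTURE1", mode="full", **kw):
    defaults = dict(
        source_path=str(path), source_format="VCF", test_id=test_id,
        pipeline_provenance=make_provenance(build), genome_build=build,
        normalization_mode=mode,
        quality=QualityCheck(base_quality=32.0, depth_of_coverage=120.0,
                             mapping_quality=98.5),
    )
    defaults.update(kw)
    return EtlManifest(**defaults)


@pytest.fixture
def loaded_db(connection, corpus_vcf, window):
    path, truth = corpus_vcf
    manifest = make_manifest(path)
    report = load_dataset(manifest, connection,
                          reference=ReferenceProvider(windows=[window]))
    return connection, truth, report


@pytest.fixture(scope="session")
def pgx_cohort():
    return make_pgx_cohort(FixtureSpec(seed=23))


@pytest.fixture
def pgx_db(connection, pgx_cohort, tmp_path):
    path = tmp_path / "pgx.vcf"
    path.write_text(pgx_cohort.vcf_text, encoding="utf-8")
    manifest = make_manifest(path, test_id="PGX1", mode="trim_only")
    load_dataset(manifest, connection)
    return connection, pgx_cohort
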