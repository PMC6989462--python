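#!/usr/bin/env python
"""Optional reproduction of the public demo databases.

The two public demo datasets (1000 Genomes Phase 3 CEU whole-genome VCFs,
n = 99 subjects, ~47.67 GB; TCGA PAAD somatic MAF, n = 155) are far beyond
desk scale and are therefore *not* downloaded or asserted by the test suite.
When you have obtained them yourself, point this script at the directory:

    python scripts/demo_databases.py --data-dir /path/to/demo --db demo.sqlite

Expected layout::

    <data-dir>/ceu/*.vcf[.gz]   per-chromosome 1000 Genomes Phase 3 CEU VCFs
    <data-dir>/paad/*.maf       TCGA PAAD somatic mutation file

After loading the CEU set the script asserts CLINICAL_IDENTIFIER = 99 (one
row per CEU subject).  TCGA row counts drift with GDC data releases and are
reported, not asserted.  Without the data the script reports a clean skip.
"""

import argparse
import glob
import sys


CEU_EXPECTED_SUBJECTS = 99


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", required=True)
    parser.add_argument("--db", required=True)
    args = parser.parse_args()

    ceu = sorted(glob.glob(f"{args.data_dir}/ceu/*.vcf*"))
    paad = sorted(glob.glob(f"{args.data_dir}/paad/*.maf*"))
    if not ceu and not paad:
        print(f"demo data not present under {args.data_dir}: skipping "
              "(see the docstring for the expected layout)")
        return 0
    return load_demo(args, ceu, paad)


def _provenance(build, tool):
    from cgdm.schema_model import PipelineProvenance

    return [PipelineProvenance(
        stage="variant_calling", tool_name=tool, tool_version="demo",
        step="variant calling", origin_source="public release",
        origin_version="phase3", origin_build=build)]


def load_demo(args, ceu, paad) -> int:
    from cgdm.config import AppConfig, init_db, open_connection
    from cgdm.io_etl import EtlManifest, load_dataset, table_counts

    config = AppConfig(database_url=args.db)
    init_db(config, force=True)
    connection = open_connection(args.db)
    for path in ceu:
        manifest = EtlManifest(
            source_path=path, source_format="VCF", test_id="CEU-P3",
            pipeline_provenance=_provenance("GRCh37", "1000g-phase3"),
            genome_build="GRCh37", normalization_mode="trim_only")
        load_dataset(manifest, connection)
    for path in paad:
        manifest = EtlManifest(
            source_path=path, source_format="MAF", test_id="TCGA-PAAD",
            pipeline_provenance=_provenance("GRCh38", "gdc-maf"),
            genome_build="GRCh38", normalization_mode="trim_only")
        load_dataset(manifest, connection)
    counts = table_counts(connection)
    print(counts)
    if ceu:
        subjects = connection.execute(
            "SELECT COUNT(*) FROM CLINICAL_IDENTIFIER WHERE test_id = 'CEU-P3'"
        ).fetchone()[0]
        assert subjects == CEU_EXPECTED_SUBJECTS, (
            f"expected {CEU_EXPECTED_SUBJECTS} CEU subjects, found {subjects}")
        print(f"CEU subjects: {subjects} (expected {CEU_EXPECTED_SUBJECTS})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
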