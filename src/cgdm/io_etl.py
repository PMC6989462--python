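"""Extract-transform-load: VCF and MAF into the relational model.

Records are normalized to minimal representation on the way in, attributed to
pipeline provenance, deduplicated per subject, alias-indexed and loaded inside
one transaction per source file (all-or-nothing).  Rejected records are
counted by reason and optionally written to a tab-delimited sidecar — never
silently dropped.

Reading is line-level rather than htslib-backed on purpose: a malformed data
line must reject that record (with a reason) and keep going, not abort the
file.  Well-formed output remains valid VCF 4.2 and is cross-checked against
htslib tools in the test suite.

Accounting convention: one "record" is one candidate variant observation —
a (site, alt allele, carrying sample) triple for VCF, a row for MAF.  Reads
always satisfy ``records_read = records_loaded + records_rejected``; loaded
records that normalize to an already-stored variant for the same subject are
merged into the existing row (the merge is noted in provenance parameters),
so loaded record count and stored row count may differ.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import json
import os
import sqlite3
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Optional, Union

import pandas as pd

from .errors import ConfigurationError, DataError, FormatError
from .normalization import (
    FULL,
    TRIM_ONLY,
    NormalizedVariant,
    RawVariant,
    ReferenceWindow,
    normalize,
    strip_chr,
)
from .nomenclature import register_aliases
from .schema_model import (
    REGISTRY,
    ClinicalAnnotation,
    ClinicalIdentifier,
    ExperimentInfo,
    GenomicAlteration,
    PipelineProvenance,
    QualityCheck,
    SchemaRegistry,
    entity_to_row,
    validate_record,
)

# --------------------------------------------------------------------------
# Manifest and report
# --------------------------------------------------------------------------

FORMAT_VCF = "VCF"
FORMAT_MAF = "MAF"


@dataclass
class EtlManifest:
    """Everything a load needs to be reproducible and attributable."""

    source_path: str
    source_format: str  # VCF | MAF
    test_id: str
    pipeline_provenance: list[PipelineProvenance]
    genome_build: str
    normalization_mode: str = FULL  # full | trim_only
    institution_id: str = "UNKNOWN"
    subject_map: dict[str, str] = field(default_factory=dict)
    experiment: Optional[ExperimentInfo] = None
    quality: Optional[QualityCheck] = None

    def validate(self) -> None:
        if not self.genome_build:
            raise ConfigurationError("manifest genome_build must be non-empty")
        if self.source_format not in (FORMAT_VCF, FORMAT_MAF):
            raise ConfigurationError(
                f"unsupported source format {self.source_format!r}"
            )
        if self.normalization_mode not in (FULL, TRIM_ONLY):
            raise ConfigurationError(
                f"normalization_mode must be '{FULL}' or '{TRIM_ONLY}'"
            )
        stages = {p.stage for p in self.pipeline_provenance}
        if "variant_calling" not in stages:
            raise ConfigurationError(
                "pipeline provenance must cover at least the variant_calling stage"
            )


@dataclass
class LoadReport:
    records_read: int = 0
    records_loaded: int = 0
    records_rejected: int = 0
    duplicates_merged: int = 0
    rejection_reasons: dict[str, int] = field(default_factory=dict)
    table_counts: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.records_rejected += 1
        self.rejection_reasons[reason] = self.rejection_reasons.get(reason, 0) + 1

    def consistent(self) -> bool:
        return self.records_read == self.records_loaded + self.records_rejected


# --------------------------------------------------------------------------
# VCF reading
# --------------------------------------------------------------------------

_ZYGOSITY_FROM_GT = {
    frozenset({"het"}): "heterozygous",
    frozenset({"hom"}): "homozygous",
}


@dataclass
class VcfObservation:
    """One candidate observation: a site/alt pair carried by one sample."""

    variant: RawVariant
    sample_id: str
    zygosity: str
    phasing: str
    missing_flag: bool
    site_info: dict[str, Any] = field(default_factory=dict)


@dataclass
class RejectedRecord:
    source_line: int
    reason: str
    payload: str


def _parse_gt(gt: str, alt_index: int) -> Optional[tuple[str, str, bool]]:
    """Map a GT string to (zygosity, phasing, missing) for one alt allele.

    Returns None when the sample does not carry this alt (and is not missing):
    that is no observation, not a rejection.
    """
    if gt == "":  # sites-only VCF: the site is observed, genotype unknown
        return "unknown", "unknown", False
    phased = "|" in gt
    sep = "|" if phased else "/"
    alleles = gt.split(sep)
    if all(a in (".", "") for a in alleles):
        return "unknown", "unknown", True
    calls = [a for a in alleles if a not in (".", "")]
    carried = [a for a in calls if a == str(alt_index)]
    if not carried:
        return None
    if len(alleles) == 1:
        zygosity = "hemizygous"
    elif len(carried) == len(alleles):
        zygosity = "homozygous"
    else:
        zygosity = "heterozygous"
    return zygosity, ("phased" if phased else "unphased"), False


def read_vcf(
    path_or_text: Union[str, os.PathLike, io.TextIOBase],
    *,
    genome_build: str,
    sample: Optional[str] = None,
) -> Iterator[Union[VcfObservation, RejectedRecord]]:
    """Stream observations from a VCF, one per (site, alt, carrying sample).

    Multi-allelic sites are split into biallelic records before downstream
    normalization.  ``sample`` restricts reading to one sample column; by
    default every sample is read.  Malformed data lines and symbolic alleles
    are yielded as :class:`RejectedRecord` rather than aborting the file.
    A missing ``#CHROM`` header line is a :class:`FormatError`.
    """
    if isinstance(path_or_text, io.TextIOBase):
        handle = path_or_text
        close = False
    else:
        handle = open(path_or_text, "rt", encoding="utf-8")
        close = True
    try:
        samples: Optional[list[str]] = None
        saw_fileformat = False
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                saw_fileformat = saw_fileformat or line.startswith("##fileformat")
                continue
            if line.startswith("#CHROM"):
                header = line.lstrip("#").split("\t")
                samples = header[9:] if len(header) > 9 else []
                continue
            if samples is None:
                raise FormatError(
                    "VCF data encountered before the #CHROM header line"
                )
            fields = line.split("\t")
            if len(fields) < 8:
                yield RejectedRecord(lineno, "malformed line", line)
                continue
            chrom, pos_s, vid, ref, alt_field = fields[0], fields[1], fields[2], fields[3], fields[4]
            try:
                pos = int(pos_s)
            except ValueError:
                yield RejectedRecord(lineno, "malformed line", line)
                continue
            gt_by_sample: dict[str, str] = {}
            if samples and len(fields) >= 10:
                fmt = fields[8].split(":")
                try:
                    gt_i = fmt.index("GT")
                except ValueError:
                    gt_i = None
                for s_name, s_field in zip(samples, fields[9:]):
                    if sample is not None and s_name != sample:
                        continue
                    gt_by_sample[s_name] = (
                        s_field.split(":")[gt_i] if gt_i is not None else "."
                    )
            elif sample is None:
                gt_by_sample = {"SAMPLE": ""}  # sites-only VCF: no genotype
            site_info = {"id": vid, "filter": fields[6] if len(fields) > 6 else ".",
                         "info": fields[7] if len(fields) > 7 else "."}
            for alt_index, alt in enumerate(alt_field.split(","), start=1):
                alt = alt.strip()
                symbolic = alt.startswith("<") or any(c in alt for c in "[]")
                for s_name, gt in gt_by_sample.items():
                    mapped = _parse_gt(gt, alt_index)
                    if mapped is None:
                        continue
                    zygosity, phasing, missing = mapped
                    if symbolic:
                        yield RejectedRecord(lineno, "symbolic allele", line)
                        continue
                    try:
                        variant = RawVariant(chrom, pos, ref.upper(), alt.upper(), genome_build)
                    except DataError as exc:
                        yield RejectedRecord(lineno, str(exc), line)
                        continue
                    yield VcfObservation(variant, s_name, zygosity, phasing,
                                         missing, site_info)
        if samples is None:
            raise FormatError("no #CHROM header line found: not a VCF")
    finally:
        if close:
            handle.close()


# --------------------------------------------------------------------------
# MAF reading
# --------------------------------------------------------------------------

#: canonical name -> accepted synonyms (GDC dialect)
_MAF_COLUMNS = {
    "chromosome": ("Chromosome",),
    "start": ("Start_Position", "Start_position"),
    "ref": ("Reference_Allele",),
    "alt": ("Tumor_Seq_Allele2", "Tumor_Allele", "Tumor_Seq_Allele1"),
    "gene": ("Hugo_Symbol",),
    "classification": ("Variant_Classification",),
    "build": ("NCBI_Build", "Build"),
}


@dataclass
class MafRecord:
    variant: RawVariant
    annotations: dict[str, Any]
    anchor_synthesized: bool  # True when an 'N' anchor replaced MAF's '-'


def _resolve_maf_columns(columns: Iterable[str]) -> dict[str, str]:
    resolved: dict[str, str] = {}
    cols = list(columns)
    missing: list[str] = []
    for canonical, synonyms in _MAF_COLUMNS.items():
        found = next((s for s in synonyms if s in cols), None)
        if found is None:
            missing.append(synonyms[0])
        else:
            resolved[canonical] = found
    if missing:
        raise FormatError(f"MAF is missing required columns: {', '.join(missing)}")
    return resolved


def read_maf(path: Union[str, os.PathLike]) -> Iterator[Union[MafRecord, RejectedRecord]]:
    """Stream records from a tab-delimited MAF.

    MAF writes pure insertions/deletions with ``-`` for the absent allele and
    no anchor base.  Without reference sequence the anchor cannot be known, so
    a placeholder ``N`` is synthesized and the record flagged — downstream
    normalization then runs trim-only (never invent sequence).
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    names = _resolve_maf_columns(frame.columns)
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        rec = {canonical: getattr(row, col) for canonical, col in names.items()}
        chrom = strip_chr(str(rec["chromosome"]))
        try:
            pos = int(rec["start"])
        except (TypeError, ValueError):
            yield RejectedRecord(i, "malformed start position", str(rec))
            continue
        ref, alt = str(rec["ref"]).upper(), str(rec["alt"]).upper()
        anchor = False
        if ref == "-" and alt == "-":
            yield RejectedRecord(i, "no alleles", str(rec))
            continue
        if ref == "-":  # pure insertion: MAF start is the base before the insert
            ref, alt, anchor = "N", "N" + alt, True
        elif alt == "-":  # pure deletion: anchor one base left of the deleted run
            ref, alt, anchor = "N" + ref, "N", True
            pos -= 1
        try:
            variant = RawVariant(chrom, pos, ref, alt, str(rec["build"]))
        except DataError as exc:
            yield RejectedRecord(i, str(exc), str(rec))
            continue
        annotations = {
            "gene_symbol": rec["gene"] or None,
            "variant_classification": rec["classification"] or None,
        }
        for extra in ("dbSNP_RS", "HGVSp_Short", "HGVSc", "Entrez_Gene_Id",
                      "Tumor_Sample_Barcode"):
            if extra in frame.columns:
                annotations[extra] = getattr(row, extra) or None
        yield MafRecord(variant, annotations, anchor)


# --------------------------------------------------------------------------
# Reference context provider
# --------------------------------------------------------------------------


class ReferenceProvider:
    """Serves :class:`ReferenceWindow` context around a variant, from either
    an indexed FASTA (via pyfaidx) or pre-built in-memory windows."""

    def __init__(self, *, fasta_path: Optional[str] = None,
                 windows: Optional[Iterable[ReferenceWindow]] = None,
                 genome_build: str = "", flank: int = 200):
        self._fasta = None
        self._flank = flank
        self._build = genome_build
        if fasta_path:
            from pyfaidx import Fasta

            self._fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
        self._windows = {(w.chromosome, w.genome_build): w for w in windows or ()}

    def window_for(self, v: RawVariant) -> Optional[ReferenceWindow]:
        key = (v.chromosome, v.genome_build)
        if key in self._windows:
            return self._windows[key]
        if self._fasta is not None:
            name = v.chromosome if v.chromosome in self._fasta else f"chr{v.chromosome}"
            if name not in self._fasta:
                return None
            start = max(1, v.position - self._flank)
            end = v.end + self._flank
            seq = str(self._fasta[name][start - 1 : end])
            return ReferenceWindow(v.chromosome, start, seq, self._build or v.genome_build)
        return None


# --------------------------------------------------------------------------
# Loader
# --------------------------------------------------------------------------


def _require_schema(connection: sqlite3.Connection, registry: SchemaRegistry) -> None:
    tables = {
        r[0] for r in connection.execute(
            "SELECT name FROM sqlite_master WHERE type = 'table'"
        )
    }
    missing = [s.name for s in registry.entities if s.name not in tables]
    if missing:
        raise DataError(
            "target database does not match the model schema version: "
            f"missing tables {', '.join(missing)} (run init-db first)"
        )


def _insert(connection: sqlite3.Connection, table: str, row: dict[str, Any]) -> int:
    cols = [c for c in row if row[c] is not None]
    sql = (
        f"INSERT INTO {table} ({', '.join(cols)}) "
        f"VALUES ({', '.join('?' for _ in cols)})"
    )
    cur = connection.execute(sql, [row[c] for c in cols])
    return cur.lastrowid


def _today() -> str:
    return _dt.date.today().isoformat()


def load_dataset(
    manifest: EtlManifest,
    connection: sqlite3.Connection,
    *,
    reference: Optional[ReferenceProvider] = None,
    annotations: Optional[list[ClinicalAnnotation]] = None,
    reject_path: Optional[str] = None,
    registry: SchemaRegistry = REGISTRY,
    dry_run: bool = False,
) -> LoadReport:
    """Load one VCF or MAF source into the model, transactionally.

    Every accepted record is normalized (full, or trim-only when the manifest
    says so or reference context is missing), validated, deduplicated per
    subject and alias-indexed.  The whole file commits or nothing does.
    """
    manifest.validate()
    _require_schema(connection, registry)
    if manifest.normalization_mode == FULL and reference is None:
        raise ConfigurationError(
            "normalization_mode 'full' requires a reference provider; "
            "use 'trim_only' when no reference sequence is available"
        )

    report = LoadReport()
    rejects: list[RejectedRecord] = []
    try:
        connection.execute("BEGIN")
    except sqlite3.OperationalError:
        pass  # driver already opened the transaction implicitly
    try:
        observations = _iter_observations(manifest)
        seen_subjects: set[str] = set()
        provenance_ids: list[int] = []
        coord_provenance_id: Optional[int] = None
        experiment = manifest.experiment or ExperimentInfo(
            test_id=manifest.test_id,
            test_description=f"loaded from {os.path.basename(str(manifest.source_path))}",
            sequence_type="WGS",
        )
        experiment.test_id = manifest.test_id
        _insert(connection, "EXPERIMENT_RELATED_INFORMATION",
                entity_to_row(experiment, registry))

        for prov in manifest.pipeline_provenance:
            prov.test_id = manifest.test_id
            prov_report = validate_record(prov, registry)
            if not prov_report:
                raise DataError(
                    f"invalid provenance for stage {prov.stage}: "
                    + "; ".join(f"{x.field}: {x.message}" for x in prov_report.violations)
                )
            pid = _insert(connection, "BIOINFORMATICS_PROTOCOL",
                          entity_to_row(prov, registry))
            provenance_ids.append(pid)
            if prov.stage in PipelineProvenance.COORDINATE_STAGES and coord_provenance_id is None:
                if prov.origin_build != manifest.genome_build:
                    raise DataError(
                        f"provenance build {prov.origin_build!r} disagrees with "
                        f"manifest genome_build {manifest.genome_build!r}"
                    )
                coord_provenance_id = pid
        if coord_provenance_id is None:  # manifest.validate guarantees variant_calling
            raise DataError("no coordinate-assigning provenance stage found")

        dedup: dict[tuple, int] = {}
        for obs in observations:
            if isinstance(obs, RejectedRecord):
                report.records_read += 1
                report.reject(obs.reason)
                rejects.append(obs)
                continue
            report.records_read += 1
            subject_id = manifest.subject_map.get(obs.sample_id, obs.sample_id)
            if subject_id not in seen_subjects:
                seen_subjects.add(subject_id)
                ident = ClinicalIdentifier(
                    institution_id=manifest.institution_id,
                    subject_id=subject_id,
                    test_id=manifest.test_id,
                    submission_date=_today(),
                )
                _insert(connection, "CLINICAL_IDENTIFIER", entity_to_row(ident, registry))

            window = None
            if manifest.normalization_mode == FULL and reference is not None:
                window = reference.window_for(obs.variant)
            try:
                normalized = normalize(obs.variant, window)
            except DataError as exc:
                report.reject(f"normalization failed: {exc}")
                rejects.append(RejectedRecord(0, f"normalization failed: {exc}",
                                              repr(obs.variant)))
                continue

            key = (subject_id, normalized.genome_build, normalized.chromosome,
                   normalized.position, normalized.ref_allele, normalized.alt_allele)
            if key in dedup:
                report.records_loaded += 1
                report.duplicates_merged += 1
                continue

            alteration = _build_alteration(obs, normalized)
            val = validate_record(alteration, registry)
            if not val:
                reason = "; ".join(f"{x.field}: {x.message}" for x in val.violations)
                report.reject(f"invalid record: {reason}")
                rejects.append(RejectedRecord(0, reason, repr(alteration)))
                continue
            row = entity_to_row(alteration, registry)
            row.update(subject_id=subject_id, test_id=manifest.test_id,
                       provenance_id=coord_provenance_id)
            alt_id = _insert(connection, "GENOMIC_ALTERATION", row)
            dedup[key] = alt_id
            report.records_loaded += 1

            for alias in register_aliases(alteration).keys:
                connection.execute(
                    "INSERT INTO VARIANT_ALIAS (alias_key, alias_kind, alteration_id)"
                    " VALUES (?, ?, ?)",
                    (alias.key, alias.kind, alt_id),
                )

        # normalization degradations and merges belong in provenance
        merge_note: dict[str, Any] = {}
        if report.duplicates_merged:
            merge_note["normalization_merged_records"] = report.duplicates_merged
        trim_only_load = manifest.normalization_mode == TRIM_ONLY
        if trim_only_load:
            merge_note["normalization_mode"] = TRIM_ONLY
        if merge_note:
            connection.execute(
                "UPDATE BIOINFORMATICS_PROTOCOL SET parameters = "
                "COALESCE(parameters, '{}') WHERE protocol_id = ?",
                (coord_provenance_id,),
            )
            old = connection.execute(
                "SELECT parameters FROM BIOINFORMATICS_PROTOCOL WHERE protocol_id = ?",
                (coord_provenance_id,),
            ).fetchone()[0]
            params = json.loads(old or "{}")
            params.update({k: str(v) for k, v in merge_note.items()})
            connection.execute(
                "UPDATE BIOINFORMATICS_PROTOCOL SET parameters = ? WHERE protocol_id = ?",
                (json.dumps(params, sort_keys=True), coord_provenance_id),
            )

        if manifest.quality is not None:
            manifest.quality.test_id = manifest.test_id
            _insert(connection, "QUALITY_CHECK", entity_to_row(manifest.quality, registry))
        for ann in annotations or ():
            _insert(connection, "CLINICAL_ANNOTATION", entity_to_row(ann, registry))

        report.table_counts = table_counts(connection, registry)
        if dry_run:
            connection.rollback()
        else:
            connection.commit()
    except BaseException:
        connection.rollback()
        raise

    if reject_path and rejects:
        with open(reject_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["source_line", "reason", "payload"])
            for r in rejects:
                writer.writerow([r.source_line, r.reason, r.payload])
    return report


def _iter_observations(manifest: EtlManifest) -> Iterator[Union[VcfObservation, RejectedRecord]]:
    if manifest.source_format == FORMAT_VCF:
        yield from read_vcf(manifest.source_path, genome_build=manifest.genome_build)
        return
    for rec in read_maf(manifest.source_path):
        if isinstance(rec, RejectedRecord):
            yield rec
            continue
        sample = rec.annotations.get("Tumor_Sample_Barcode") or "MAF_SAMPLE"
        obs = VcfObservation(
            rec.variant, sample, zygosity="unknown", phasing="unknown",
            missing_flag=False, site_info=rec.annotations,
        )
        yield obs


def _build_alteration(obs: VcfObservation, normalized: NormalizedVariant) -> GenomicAlteration:
    info = obs.site_info or {}
    ref_len, alt_len = len(normalized.ref_allele), len(normalized.alt_allele)
    variant_type = "SNV" if ref_len == alt_len == 1 else "InDel"
    dbsnp = info.get("id") if str(info.get("id", "")).startswith("rs") else info.get("dbSNP_RS")
    if isinstance(dbsnp, str) and not dbsnp.startswith("rs"):
        dbsnp = None
    hgvs_p = info.get("HGVSp_Short")
    try:
        entrez = int(info.get("Entrez_Gene_Id")) or None
    except (TypeError, ValueError):
        entrez = None
    return GenomicAlteration(
        chromosome=normalized.chromosome,
        position=normalized.position,
        ref_allele=normalized.ref_allele,
        alt_allele=normalized.alt_allele,
        genome_build=normalized.genome_build,
        zygosity=obs.zygosity,
        phasing=obs.phasing,
        missing_flag=obs.missing_flag,
        gene_symbol=info.get("gene_symbol"),
        entrez_id=entrez,
        hgvs_p=hgvs_p,
        hgvs_c=info.get("HGVSc"),
        dbsnp_id=dbsnp,
        molecular_effect=info.get("variant_classification"),
        variant_type=variant_type,
    )


def table_counts(connection: sqlite3.Connection,
                 registry: SchemaRegistry = REGISTRY) -> dict[str, int]:
    counts = {}
    for spec in registry.entities:
        counts[spec.name] = connection.execute(
            f"SELECT COUNT(*) FROM {spec.name}"
        ).fetchone()[0]
    return counts


# --------------------------------------------------------------------------
# Export (round trip)
# --------------------------------------------------------------------------


def export_vcf(connection: sqlite3.Connection, path: Union[str, os.PathLike],
               *, test_id: Optional[str] = None) -> int:
    """Write stored alterations back out as a multi-sample VCF.

    The written records are the stored minimal representations; re-loading the
    export into an empty database reproduces identical normalized rows.
    Returns the number of data lines written.
    """
    where, params = "", []
    if test_id is not None:
        where = "WHERE g.test_id = ?"
        params.append(test_id)
    rows = connection.execute(
        f"""SELECT g.chromosome, g.position, g.ref_allele, g.alt_allele,
                   g.subject_id, g.zygosity, g.phasing, g.missing_flag,
                   json_extract(b.origin, '$.origin_build')
            FROM GENOMIC_ALTERATION g
            JOIN BIOINFORMATICS_PROTOCOL b ON b.protocol_id = g.provenance_id
            {where}
            ORDER BY g.chromosome, g.position, g.ref_allele, g.alt_allele""",
        params,
    ).fetchall()
    samples = sorted({r[4] for r in rows})
    sample_index = {s: i for i, s in enumerate(samples)}
    build = rows[0][8] if rows else ""

    sites: dict[tuple, list] = {}
    for chrom, pos, ref, alt, subject, zygosity, phasing, missing, _b in rows:
        site = sites.setdefault((chrom, pos, ref, alt), [None] * len(samples))
        sep = "|" if phasing == "phased" else "/"
        if missing:
            gt = f".{sep}."
        elif zygosity == "homozygous":
            gt = f"1{sep}1"
        elif zygosity == "hemizygous":
            gt = "1"
        else:
            gt = f"0{sep}1"
        site[sample_index[subject]] = gt

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if build:
            fh.write(f"##reference={build}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        n = 0
        for (chrom, pos, ref, alt), gts in sites.items():
            gts = [g if g is not None else "0/0" for g in gts]
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
            n += 1
    return n
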