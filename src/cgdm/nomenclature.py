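"""Variant nomenclature: HGVS parsing, completeness validation, alias index.

A protein-level variant name is only unambiguous when it pins the reference
sequence it is numbered against: ``NP_004324.2:p.V600E`` names the famous BRAF
substitution, while the version-less ``NP_004324:p.V599E`` is the *same*
variant numbered against an older sequence missing a codon — and has been
mis-read as a distinct mutation.  This module enforces that completeness rule
(accession **and** version required) and classifies incomplete names into the
failure meta-categories used throughout the model:

* ``origin``    — the reference data source itself is unidentified,
* ``reference`` — the source is named but not pinned (missing/invalid version),
* ``symbol``    — the change description is malformed for its level.

It also builds the alias index that lets a clinician's fragmented query
("V600E") reach stored records without guessing silently when several genes
share the shorthand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .errors import ParseError
from .schema_model import GenomicAlteration

# --------------------------------------------------------------------------
# HGVS expressions
# --------------------------------------------------------------------------

#: accession prefix -> molecule class; determines the HGVS level it may carry
_ACCESSION_CLASSES = {
    "NP": "protein",
    "ENSP": "protein",
    "NM": "coding",
    "ENST": "coding",
    "NR": "coding",
    "NC": "genomic",
    "NG": "genomic",
    "NW": "genomic",
    "NT": "genomic",
}

_LEVEL_FOR_CLASS = {"protein": "p", "coding": "c", "genomic": "g"}

_ACCESSION_RE = re.compile(
    r"^(?P<prefix>[A-Z]{2,4})_?(?P<number>\d+)(\.(?P<version>\d+))?$"
)

# change syntax per level (pragmatic subset: substitutions, indels, dup, fs)
_CHANGE_RES = {
    "p": re.compile(
        r"^(\()?"
        r"(?P<from>[A-Z][a-z]{2}|[A-Z\*])(?P<pos>\d+)"
        r"((?P<to>[A-Z][a-z]{2}|[A-Z\*=])|(?P<kind>del|dup|fs|ext)\S*)"
        r"(\))?$"
    ),
    "c": re.compile(r"^[-\*]?\d+([-+]\d+)?(_[-\*]?\d+([-+]\d+)?)?"
                    r"([ACGTN]+>[ACGTN]+|del[ACGTN]*|ins[ACGTN]+|dup[ACGTN]*|inv)$"),
    "g": re.compile(r"^\d+(_\d+)?"
                    r"([ACGTN]+>[ACGTN]+|del[ACGTN]*|ins[ACGTN]+|dup[ACGTN]*|inv)$"),
}

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*", "Sec": "U",
}


@dataclass(frozen=True)
class HgvsExpression:
    """A parsed variant name: reference accession (optionally versioned),
    description level (g/c/p) and the change itself.  ``raw`` preserves the
    input text verbatim — incomplete names are stored as received, flagged,
    never silently corrected."""

    accession: str
    accession_version: Optional[int]
    level: str  # 'g' | 'c' | 'p'
    change: str
    raw: str

    def format(self) -> str:
        version = f".{self.accession_version}" if self.accession_version is not None else ""
        return f"{self.accession}{version}:{self.level}.{self.change}"


def parse_hgvs(text: str) -> HgvsExpression:
    """Parse an HGVS string like ``NP_004324.2:p.V600E``.

    Raises :class:`ParseError` with the failing offset for malformed input.
    The change text is kept as written (three-letter amino-acid codes are not
    rewritten here; comparison-time normalization is
    :func:`normalize_protein_change`).
    """
    if not isinstance(text, str):
        raise ParseError(str(text), 0, "HGVS input must be a string")
    stripped = text.strip()
    if ":" not in stripped:
        raise ParseError(text, len(stripped), "missing ':' separating accession and change")
    acc_part, change_part = stripped.split(":", 1)
    m = _ACCESSION_RE.match(acc_part)
    if not m:
        raise ParseError(text, 0, f"unrecognised accession {acc_part!r}")
    prefix = m.group("prefix")
    accession = f"{prefix}_{m.group('number')}" if "_" in acc_part else acc_part.split(".")[0]
    version = int(m.group("version")) if m.group("version") else None

    lm = re.match(r"^(?P<level>[gcpnmr])\.(?P<change>\S+)$", change_part)
    if not lm:
        raise ParseError(
            text, stripped.index(":") + 1,
            "change must look like 'p.<change>', 'c.<change>' or 'g.<change>'",
        )
    level, change = lm.group("level"), lm.group("change")
    if level not in ("g", "c", "p"):
        raise ParseError(text, stripped.index(":") + 1, f"unsupported level {level!r}")
    acc_class = _ACCESSION_CLASSES.get(prefix)
    if acc_class is not None and _LEVEL_FOR_CLASS[acc_class] != level:
        raise ParseError(
            text, stripped.index(":") + 1,
            f"accession {accession} is a {acc_class} sequence and cannot carry "
            f"a {level}. description",
        )
    change_re = _CHANGE_RES[level]
    if not change_re.match(change):
        raise ParseError(
            text, stripped.index(change, stripped.index(":")),
            f"malformed {level}. change {change!r}",
        )
    return HgvsExpression(accession, version, level, change, raw=stripped)


def format_hgvs(expr: HgvsExpression) -> str:
    """Inverse of :func:`parse_hgvs` (round-trips well-formed input)."""
    return expr.format()


def normalize_protein_change(change: str) -> str:
    """Canonical one-letter form of a protein change, whitespace stripped.

    ``Val600Glu`` and ``V600E`` compare equal; amino-acid letters themselves
    stay case-sensitive (community convention).
    """
    text = re.sub(r"\s+", "", change).strip("()")

    def _sub(m: re.Match) -> str:
        return _THREE_TO_ONE.get(m.group(0), m.group(0))

    return re.sub(r"[A-Z][a-z]{2}", _sub, text)


# --------------------------------------------------------------------------
# Completeness validation
# --------------------------------------------------------------------------

CATEGORY_ORIGIN = "origin"
CATEGORY_REFERENCE = "reference"
CATEGORY_SYMBOL = "symbol"


@dataclass(frozen=True)
class CompletenessReport:
    complete: bool
    category: Optional[str] = None  # origin | reference | symbol when incomplete
    message: str = ""

    def __bool__(self) -> bool:
        return self.complete


def validate_completeness(expr: HgvsExpression) -> CompletenessReport:
    """Check that an expression pins everything needed to interpret it.

    A name without an accession version is incomplete (category
    ``reference``): its numbering may refer to any historical sequence of that
    accession.  Unknown accession classes are ``origin`` failures; malformed
    change text is ``symbol``.
    """
    prefix = expr.accession.split("_")[0]
    if prefix not in _ACCESSION_CLASSES:
        return CompletenessReport(
            False, CATEGORY_ORIGIN,
            f"unrecognised reference data source class {prefix!r}",
        )
    if expr.accession_version is None:
        return CompletenessReport(
            False, CATEGORY_REFERENCE,
            f"{expr.accession} carries no version: the numbering reference is not pinned",
        )
    if expr.accession_version < 1:
        return CompletenessReport(
            False, CATEGORY_REFERENCE,
            f"version {expr.accession_version} is invalid (versions are >= 1)",
        )
    if not _CHANGE_RES[expr.level].match(expr.change):
        return CompletenessReport(
            False, CATEGORY_SYMBOL, f"malformed change {expr.change!r}"
        )
    return CompletenessReport(True, None, "complete")


# --------------------------------------------------------------------------
# Alias index and fragmented-query resolution
# --------------------------------------------------------------------------

KIND_GENE_PROTEIN = "gene_protein_change"
KIND_DBSNP = "dbsnp"
KIND_HGVS = "hgvs"


@dataclass(frozen=True)
class AliasKey:
    key: str
    kind: str


@dataclass
class AliasKeys:
    """Alias keys generated for one stored alteration, with a coverage warning
    when the record has no naming fields at all."""

    keys: list[AliasKey]
    warning: Optional[str] = None


def register_aliases(alteration: GenomicAlteration) -> AliasKeys:
    """Generate the alias keys under which a stored alteration is findable:
    ``GENE:proteinchange``, its dbSNP id, and every full HGVS string."""
    keys: list[AliasKey] = []
    if alteration.gene_symbol and alteration.hgvs_p:
        change = alteration.hgvs_p.split(":", 1)[-1]
        change = re.sub(r"^p\.", "", change)
        keys.append(
            AliasKey(f"{alteration.gene_symbol}:{normalize_protein_change(change)}",
                     KIND_GENE_PROTEIN)
        )
    if alteration.dbsnp_id:
        keys.append(AliasKey(alteration.dbsnp_id, KIND_DBSNP))
    for hgvs in (alteration.hgvs_g, alteration.hgvs_c, alteration.hgvs_p):
        if hgvs:
            keys.append(AliasKey(hgvs, KIND_HGVS))
    warning = None
    if not keys:
        warning = (
            "alteration has no naming fields (HGVS, dbSNP, gene+protein change); "
            "it will not be reachable by semantic query"
        )
    return AliasKeys(keys, warning)


@dataclass
class VariantAliasIndex:
    """In-memory map from alias key to stored alteration ids.

    Persisted in the relational store (``VARIANT_ALIAS`` table, maintained by
    the ETL loader); this class is the query-time view.
    """

    entries: dict[str, list[int]] = field(default_factory=dict)
    kinds: dict[str, str] = field(default_factory=dict)
    genes: dict[int, str] = field(default_factory=dict)  # alteration id -> symbol

    def add(self, key: AliasKey, alteration_id: int, gene_symbol: Optional[str] = None):
        self.entries.setdefault(key.key, [])
        if alteration_id not in self.entries[key.key]:
            self.entries[key.key].append(alteration_id)
        self.kinds[key.key] = key.kind
        if gene_symbol:
            self.genes[alteration_id] = gene_symbol

    @classmethod
    def from_connection(cls, connection) -> "VariantAliasIndex":
        index = cls()
        rows = connection.execute(
            """SELECT a.alias_key, a.alias_kind, a.alteration_id, g.gene
               FROM VARIANT_ALIAS a
               LEFT JOIN GENOMIC_ALTERATION g ON g.alteration_id = a.alteration_id"""
        ).fetchall()
        import json as _json

        for key, kind, alt_id, gene_json in rows:
            gene = None
            if gene_json:
                gene = _json.loads(gene_json).get("gene_symbol")
            index.add(AliasKey(key, kind), alt_id, gene)
        return index


@dataclass(frozen=True)
class QueryCandidate:
    alteration_id: int
    alias_key: str
    gene_symbol: Optional[str]
    exact: bool


@dataclass
class QueryResolution:
    candidates: list[QueryCandidate]
    ambiguous: bool

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self):
        return len(self.candidates)


def resolve_query(fragment: str, index: VariantAliasIndex) -> QueryResolution:
    """Resolve a possibly fragmented search term against the alias index.

    Exact alias matches come first.  A bare protein change ("V600E") matches
    the change component of every ``GENE:change`` key; when several genes
    share the shorthand the result is flagged ambiguous and lists *all*
    candidates — never a silent single guess.  Candidates are stably ordered
    by gene symbol, then alteration id.
    """
    term = re.sub(r"\s+", "", fragment or "")
    if not term:
        return QueryResolution([], ambiguous=False)
    norm_term = normalize_protein_change(term)

    seen: dict[int, QueryCandidate] = {}
    for key, ids in index.entries.items():
        exact = key == term or key == norm_term
        partial = False
        if not exact and index.kinds.get(key) == KIND_GENE_PROTEIN:
            _, _, change = key.partition(":")
            partial = change == norm_term
        if not (exact or partial):
            continue
        for alt_id in ids:
            if alt_id not in seen or (exact and not seen[alt_id].exact):
                seen[alt_id] = QueryCandidate(
                    alt_id, key, index.genes.get(alt_id), exact
                )
    candidates = sorted(
        seen.values(),
        key=lambda c: (not c.exact, c.gene_symbol or "~", c.alteration_id),
    )
    return QueryResolution(candidates, ambiguous=len(candidates) > 1)
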