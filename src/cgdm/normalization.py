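"""Minimal-representation variant normalization.

The same sequence edit can be written many ways in VCF: ``chr10:11805838 C>CT``
and ``chr10:11805838 CG>CTG`` describe one and the same inserted ``T``.  Before
storage every variant is converted to its *minimal representation* so that
equivalent spellings become byte-identical:

1. **trim** — remove the longest shared allele suffix, then the longest shared
   prefix (advancing the position), keeping at least one base per allele
   (the VCF anchor-base convention);
2. **left-align** — for indels, shift to the smallest position that produces
   an identical edited sequence, using local reference context, then re-trim.

Left alignment needs reference sequence.  When none is available (e.g. MAF
ingestion without a genome), only the trim step runs and the result is flagged
``trim_only`` so the store records degraded normalization instead of faking
completeness.  Alleles containing ``N`` trim normally but are never shifted:
an ambiguous base makes the equal-sequence comparison unsound.

Coordinates are 1-based inclusive (VCF-native) throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Optional

from .errors import DataError, ReferenceContextError, ReferenceMismatchError

_ALLELE_RE = re.compile(r"^[ACGTN]+$")

FULL = "full"
TRIM_ONLY = "trim_only"


def strip_chr(chromosome: str) -> str:
    """Canonical internal chromosome name: no ``chr`` prefix."""
    return chromosome[3:] if chromosome.lower().startswith("chr") else chromosome


@dataclass(frozen=True)
class RawVariant:
    """One variant observation as read from input, 1-based coordinates."""

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    genome_build: str

    def __post_init__(self):
        object.__setattr__(self, "chromosome", strip_chr(self.chromosome))
        for name in ("ref_allele", "alt_allele"):
            allele = getattr(self, name)
            if not allele or not _ALLELE_RE.match(allele):
                raise DataError(
                    f"{name} {allele!r} must be a non-empty uppercase [ACGTN]+ string"
                )
        if self.position < 1:
            raise DataError(f"position {self.position} must be >= 1")

    @property
    def end(self) -> int:
        """Last reference base touched by the edit (1-based inclusive)."""
        return self.position + len(self.ref_allele) - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def has_ambiguous_base(self) -> bool:
        return "N" in self.ref_allele or "N" in self.alt_allele


@dataclass(frozen=True)
class ReferenceWindow:
    """A slice of reference sequence providing local context for alignment."""

    chromosome: str
    start: int  # 1-based position of sequence[0]
    sequence: str
    genome_build: str

    def __post_init__(self):
        object.__setattr__(self, "chromosome", strip_chr(self.chromosome))
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise DataError("reference window sequence must be non-empty")
        if self.start < 1:
            raise DataError(f"window start {self.start} must be >= 1")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    def covers(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    def base_at(self, position: int) -> str:
        if not self.covers(position, position):
            raise ReferenceContextError(self.chromosome, position, position)
        return self.sequence[position - self.start]

    def slice(self, start: int, end: int) -> str:
        """Sequence for the 1-based inclusive span [start, end]."""
        if not self.covers(start, end):
            raise ReferenceContextError(self.chromosome, start, end)
        return self.sequence[start - self.start : end - self.start + 1]


@dataclass(frozen=True)
class NormalizedVariant(RawVariant):
    """A variant in minimal representation plus the mode that produced it."""

    mode: str = FULL  # FULL when left-aligned against reference, else TRIM_ONLY

    @property
    def variant(self) -> RawVariant:
        return RawVariant(
            self.chromosome, self.position, self.ref_allele, self.alt_allele,
            self.genome_build,
        )


def _check_window(v: RawVariant, ref: ReferenceWindow) -> None:
    if ref.chromosome != v.chromosome:
        raise ReferenceMismatchError(
            f"window is for chromosome {ref.chromosome}, variant on {v.chromosome}"
        )
    if ref.genome_build != v.genome_build:
        raise ReferenceMismatchError(
            f"window build {ref.genome_build} differs from variant build {v.genome_build}"
        )
    observed = ref.slice(v.position, v.end)
    if observed != v.ref_allele:
        raise ReferenceMismatchError(
            f"REF {v.ref_allele!r} at {v.chromosome}:{v.position} does not match "
            f"reference sequence {observed!r}"
        )


def trim_alleles(v: RawVariant) -> RawVariant:
    """Remove shared allele bases: longest suffix first, then longest prefix
    (advancing the position), always retaining at least one base per allele.

    Pure string operation — needs no reference sequence — and preserves the
    edit the record describes.
    """
    ref, alt, pos = v.ref_allele, v.alt_allele, v.position
    if ref == alt:
        raise DataError(
            f"identity alleles {ref!r} at {v.chromosome}:{pos}: not a variant"
        )
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if not ref or not alt:  # pragma: no cover - unreachable by construction
        raise AssertionError("trim produced an empty allele")
    if (ref, alt, pos) == (v.ref_allele, v.alt_allele, v.position):
        return v
    return replace(v, position=pos, ref_allele=ref, alt_allele=alt)


def left_align(v: RawVariant, ref: ReferenceWindow) -> RawVariant:
    """Shift a trimmed indel to the smallest position yielding the same edited
    sequence, then re-trim.  Idempotent; SNVs/MNVs pass through unchanged
    (after suffix/prefix handling they cannot shift).

    Raises :class:`ReferenceContextError` when the window lacks the left
    context the shift needs, and :class:`ReferenceMismatchError` when the
    record's REF disagrees with the window.
    """
    _check_window(v, ref)
    if v.has_ambiguous_base:
        raise DataError(
            f"allele with ambiguous base 'N' at {v.chromosome}:{v.position} "
            "cannot be left-aligned"
        )
    ref_a, alt_a, pos = v.ref_allele, v.alt_allele, v.position
    while True:
        if ref_a and alt_a and ref_a[-1] == alt_a[-1]:
            ref_a, alt_a = ref_a[:-1], alt_a[:-1]
        elif not ref_a or not alt_a:
            if pos - 1 < ref.start:
                raise ReferenceContextError(
                    v.chromosome, pos - 1, v.end,
                    f"left alignment needs context to the left of "
                    f"{v.chromosome}:{pos}; window starts at {ref.start}",
                )
            base = ref.base_at(pos - 1)
            ref_a, alt_a = base + ref_a, base + alt_a
            pos -= 1
        else:
            break
    while len(ref_a) > 1 and len(alt_a) > 1 and ref_a[0] == alt_a[0]:
        ref_a, alt_a = ref_a[1:], alt_a[1:]
        pos += 1
    if (ref_a, alt_a, pos) == (v.ref_allele, v.alt_allele, v.position):
        return v
    return replace(v, position=pos, ref_allele=ref_a, alt_allele=alt_a)


def normalize(v: RawVariant, ref: Optional[ReferenceWindow] = None) -> NormalizedVariant:
    """Convert to minimal representation: trim, then left-align when reference
    context is available.

    Returns a :class:`NormalizedVariant` whose ``mode`` records whether full
    normalization ran (``full``) or only the reference-free trim
    (``trim_only``: no window given, or an ambiguous ``N`` base blocked the
    shift).  Idempotent: ``normalize(normalize(x)) == normalize(x)``.
    """
    trimmed = trim_alleles(v)
    if ref is None or trimmed.has_ambiguous_base:
        mode = TRIM_ONLY
        result = trimmed
    else:
        mode = FULL
        result = left_align(trimmed, ref)
    return NormalizedVariant(
        result.chromosome, result.position, result.ref_allele,
        result.alt_allele, result.genome_build, mode=mode,
    )


@dataclass(frozen=True)
class EquivalenceResult:
    """Boolean verdict plus a note explaining a structural mismatch."""

    equivalent: bool
    note: Optional[str] = None

    def __bool__(self) -> bool:
        return self.equivalent


def are_equivalent(a: RawVariant, b: RawVariant,
                   ref: Optional[ReferenceWindow] = None) -> EquivalenceResult:
    """True iff the two records normalize to the same minimal representation.

    Variants on different genome builds are never equivalent — the same
    coordinates mean different sequence — and the result says so explicitly.
    """
    if a.genome_build != b.genome_build:
        return EquivalenceResult(
            False,
            f"build mismatch: {a.genome_build} vs {b.genome_build} "
            "(coordinates on different assemblies are not comparable)",
        )
    if a.chromosome != b.chromosome:
        return EquivalenceResult(False, "different chromosomes")
    na, nb = normalize(a, ref), normalize(b, ref)
    same = (na.position, na.ref_allele, na.alt_allele) == (
        nb.position, nb.ref_allele, nb.alt_allele,
    )
    return EquivalenceResult(same)


def apply_edit(window: ReferenceWindow, v: RawVariant) -> str:
    """Apply the edit a variant describes to the window sequence.

    The semantic ground truth behind normalization: two records are the same
    variant exactly when their edited sequences are equal.
    """
    _check_window(v, window)
    left = window.sequence[: v.position - window.start]
    right = window.sequence[v.end - window.start + 1 :]
    return left + v.alt_allele + right
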