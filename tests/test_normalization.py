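"""Minimal-representation normalization: worked examples, properties, and
agreement with the exhaustive-enumeration and htslib oracles."""

import shutil
import subprocess

import pytest
from hypothesis import assume, given, settings, strategies as st

from cgdm.errors import DataError, ReferenceContextError, ReferenceMismatchError
from cgdm.fixtures import FixtureSpec, make_variant_corpus, make_vcf, write_fasta
from cgdm.normalization import (
    RawVariant,
    ReferenceWindow,
    apply_edit,
    are_equivalent,
    left_align,
    normalize,
    trim_alleles,
)

from oracles import edited_sequence, oracle_minimal


class TestTrim:
    def test_insertion_spellings_trim_to_same_record(self):
        # the two published spellings of one inserted T on chromosome 10
        long_form = RawVariant("chr10", 11805838, "CG", "CTG", "GRCh37")
        short_form = RawVariant("chr10", 11805838, "C", "CT", "GRCh37")
        assert trim_alleles(long_form) == short_form
        assert trim_alleles(short_form) == short_form

    def test_minimal_snv_unchanged(self):
        v = RawVariant("chr7", 140453136, "A", "T", "GRCh37")
        assert trim_alleles(v) is v

    def test_mnv_prefix_and_suffix_trim(self):
        v = RawVariant("chrX", 100, "ACCA", "ATCA", "FIXTURE1")
        # brute-force derivable: only position 101 C>T reproduces the edit
        assert trim_alleles(v) == RawVariant("X", 101, "C", "T", "FIXTURE1")

    def test_identity_alleles_rejected(self):
        v = RawVariant("1", 10, "AC", "AC", "FIXTURE1")
        with pytest.raises(DataError):
            trim_alleles(v)


class TestLeftAlign:
    def _repeat_window(self):
        #            1234567890123456789
        return ReferenceWindow("1", 1, "GGCATATATATCCGGGAAC", "FIXTURE1")

    def test_insertion_shifts_to_repeat_left_edge(self):
        window = self._repeat_window()
        # insertion of AT after the last AT unit (right edge, position 11)
        right_edge = RawVariant("1", 11, "T", "TAT", "FIXTURE1")
        aligned = left_align(right_edge, window)
        left_edge = RawVariant("1", 3, "C", "CAT", "FIXTURE1")
        assert aligned == left_edge
        assert apply_edit(window, right_edge) == apply_edit(window, aligned)

    def test_deletion_shifts_left(self):
        window = self._repeat_window()
        v = RawVariant("1", 9, "TAT", "T", "FIXTURE1")
        aligned = left_align(v, window)
        assert aligned.position == 3
        assert apply_edit(window, v) == apply_edit(window, aligned)

    def test_snv_passes_through(self):
        window = self._repeat_window()
        v = RawVariant("1", 5, "T", "G", "FIXTURE1")
        assert left_align(v, window) is v

    def test_nonrepetitive_deletion_stays_put(self):
        window = ReferenceWindow("1", 1, "GGCATGCCTAAC", "FIXTURE1")
        v = RawVariant("1", 5, "TGC", "T", "FIXTURE1")
        assert left_align(v, window) == v

    def test_reference_mismatch_detected(self):
        window = self._repeat_window()
        with pytest.raises(ReferenceMismatchError):
            left_align(RawVariant("1", 5, "G", "GA", "FIXTURE1"), window)

    def test_context_error_names_required_span(self):
        # deletion at the window's first base needs an anchor further left
        window = ReferenceWindow("1", 5, "ATATATAT", "FIXTURE1")
        v = RawVariant("1", 5, "ATA", "A", "FIXTURE1")
        with pytest.raises(ReferenceContextError) as err:
            left_align(v, window)
        assert err.value.start < 5

    def test_ambiguous_base_blocks_alignment(self):
        window = self._repeat_window()
        v = RawVariant("1", 5, "T", "TNT", "FIXTURE1")
        with pytest.raises(DataError):
            left_align(v, window)
        assert normalize(v, window).mode == "trim_only"


class TestNormalize:
    def test_equivalent_spellings_become_identical(self):
        window = ReferenceWindow("10", 11805830, "AATTTCCACGTTGACT", "GRCh37")
        a = RawVariant("chr10", 11805838, "C", "CT", "GRCh37")
        b = RawVariant("chr10", 11805838, "CG", "CTG", "GRCh37")
        na, nb = normalize(a, window), normalize(b, window)
        assert na == nb
        assert na.position == 11805838
        assert (na.ref_allele, na.alt_allele) == ("C", "CT")
        assert na.mode == "full"

    def test_trim_only_when_no_reference(self):
        v = RawVariant("1", 50, "CG", "CTG", "FIXTURE1")
        n = normalize(v)
        assert n.mode == "trim_only"
        assert (n.ref_allele, n.alt_allele) == ("C", "CT")

    def test_idempotent_on_snv(self):
        v = RawVariant("7", 140453136, "A", "T", "GRCh37")
        once = normalize(v)
        assert normalize(once) == once


class TestEquivalence:
    def test_published_spellings_equivalent(self):
        a = RawVariant("chr10", 11805838, "C", "CT", "GRCh37")
        b = RawVariant("chr10", 11805838, "CG", "CTG", "GRCh37")
        assert are_equivalent(a, b)

    def test_build_mismatch_is_not_equivalent(self):
        # same substitution, GRCh37 vs GRCh38 coordinates: never comparable
        g37 = RawVariant("chr7", 140453136, "A", "T", "GRCh37")
        g38 = RawVariant("chr7", 140453136, "A", "T", "GRCh38")
        verdict = are_equivalent(g37, g38)
        assert not verdict
        assert "build" in verdict.note

    def test_reflexive(self):
        v = RawVariant("1", 10, "A", "AT", "FIXTURE1")
        assert are_equivalent(v, v)


# --------------------------------------------------------------------------
# Property tests on the generated corpus
# --------------------------------------------------------------------------

CORPUS_SPEC = FixtureSpec(seed=31, n_subjects=12, n_variants_per_subject=9,
                          fraction_nonminimal=1.0)


@pytest.fixture(scope="module")
def corpus():
    from cgdm.fixtures import make_reference_window

    window = make_reference_window(CORPUS_SPEC)
    entries = make_variant_corpus(CORPUS_SPEC, window)
    return window, entries


def test_normalize_is_idempotent_on_corpus(corpus):
    window, entries = corpus
    for entry in entries:
        for spelling in entry.spellings:
            once = normalize(spelling, window)
            assert normalize(once, window) == once


def test_normalize_preserves_edit_semantics(corpus):
    window, entries = corpus
    for entry in entries:
        for spelling in entry.spellings:
            normalized = normalize(spelling, window)
            assert apply_edit(window, normalized.variant) == apply_edit(window, spelling)


def test_normalize_matches_enumeration_oracle(corpus):
    window, entries = corpus
    checked = 0
    for entry in entries:
        for spelling in entry.spellings:
            if not spelling.is_indel:
                continue
            n = normalize(spelling, window)
            assert (n.position, n.ref_allele, n.alt_allele) == oracle_minimal(
                window, spelling
            )
            checked += 1
    assert checked >= 100


def test_all_spellings_collapse_to_truth(corpus):
    window, entries = corpus
    for entry in entries:
        minimal = normalize(entry.variant, window)
        for spelling in entry.spellings:
            assert normalize(spelling, window) == minimal


def test_equivalence_is_symmetric_and_transitive(corpus):
    window, entries = corpus
    for entry in entries:
        spellings = entry.spellings
        for a in spellings:
            for b in spellings:
                assert are_equivalent(a, b, window) == are_equivalent(b, a, window)
        if len(spellings) == 2:
            a, b = spellings
            assert are_equivalent(a, b, window)
            assert are_equivalent(b, entry.variant, window)
            assert are_equivalent(a, entry.variant, window)  # transitivity


# --------------------------------------------------------------------------
# Hypothesis: random representations over a random repeat window
# --------------------------------------------------------------------------


@st.composite
def window_and_indel(draw):
    unit = draw(st.text(alphabet="ACGT", min_size=1, max_size=3))
    copies = draw(st.integers(min_value=2, max_value=5))
    flank_l = draw(st.text(alphabet="ACGT", min_size=5, max_size=12))
    flank_r = draw(st.text(alphabet="ACGT", min_size=5, max_size=12))
    # a breaker base absent from the repeat unit pins the window start so
    # left shifts always terminate inside the window
    breaker = next(b for b in "ACGT" if b not in unit)
    seq = breaker + flank_l + unit * copies + flank_r
    window = ReferenceWindow("1", 1, seq, "FIXTURE1")
    pos = draw(st.integers(min_value=2, max_value=len(seq) - len(unit) - 1))
    anchor = window.base_at(pos)
    if draw(st.booleans()):  # insertion of the unit
        v = RawVariant("1", pos, anchor, anchor + unit, "FIXTURE1")
    else:  # deletion of whatever follows the anchor
        del_len = min(len(unit), len(seq) - pos)
        deleted = window.slice(pos + 1, pos + del_len)
        v = RawVariant("1", pos, anchor + deleted, anchor, "FIXTURE1")
    return window, v


@given(window_and_indel())
@settings(max_examples=150, derandomize=True, deadline=None)
def test_random_indels_normalize_to_oracle_form(case):
    window, v = case
    try:
        n = normalize(v, window)
    except ReferenceContextError:
        # the run touches the window edge: out of left_align's contract
        # (the window must provide sufficient left context)
        assume(False)
    assert normalize(n, window) == n
    assert edited_sequence(window, n.variant) == edited_sequence(window, v)
    assert (n.position, n.ref_allele, n.alt_allele) == oracle_minimal(window, v)


# --------------------------------------------------------------------------
# External cross-check: htslib's left-align-and-trim
# --------------------------------------------------------------------------


@pytest.mark.skipif(shutil.which("bcftools") is None,
                    reason="bcftools not on PATH")
def test_agrees_with_bcftools_norm(tmp_path):
    spec = FixtureSpec(seed=47, n_subjects=4, n_variants_per_subject=6,
                       fraction_nonminimal=1.0)
    from cgdm.fixtures import make_reference_window

    window = make_reference_window(spec)
    fasta = write_fasta(window, tmp_path / "ref.fa")
    vcf_path = tmp_path / "in.vcf"
    _, truth = make_vcf(spec, window, vcf_path)
    out = subprocess.run(
        ["bcftools", "norm", "-f", str(fasta), "-c", "e", str(vcf_path)],
        capture_output=True, text=True, check=True,
    )
    theirs = []
    for line in out.stdout.splitlines():
        if line.startswith("#"):
            continue
        f = line.split("\t")
        theirs.append((int(f[1]), f[3], f[4]))
    ours = []
    for entry in truth:
        for spelling in entry.spellings:
            n = normalize(spelling, window)
            ours.append((n.position, n.ref_allele, n.alt_allele))
    assert sorted(theirs) == sorted(ours)
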