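"""Self-contained synthetic test inputs.

Everything the other modules need to be exercised without downloads:
reference windows with controlled tandem-repeat structure, VCFs that spell
the same variant in several equivalent ways, pharmacogene cohorts with known
diplotypes, and dosing covariates.  All generators are deterministic under
the seed; the synthetic genome build is labelled ``FIXTURE1`` so fixture
coordinates can never accidentally join against a real assembly.

Non-minimal variant spellings are produced by *inverting* the normalization
operators — padding shared bases from the reference and right-shifting
insertions within their repeat tract — so their equivalence to the minimal
form holds by construction, independent of the code under test.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .normalization import RawVariant, ReferenceWindow, apply_edit
from .query_cds import CYP2C9_DIPLOTYPES, VKORC1_STATES, AlleleDefinitions

FIXTURE_BUILD = "FIXTURE1"
_BASES = "ACGT"


@dataclass
class FixtureSpec:
    seed: int = 0
    n_subjects: int = 3
    n_variants_per_subject: int = 5
    fraction_nonminimal: float = 0.5
    repeat_context_length: int = 12
    build_label: str = FIXTURE_BUILD
    window_length: int = 2400
    chromosome: str = "1"
    margin: int = 60  # repeat tracts stay this far from window edges

    def __post_init__(self):
        if not (0.0 <= self.fraction_nonminimal <= 1.0):
            raise ValueError("fraction_nonminimal must be in [0, 1]")
        if self.n_subjects < 0 or self.n_variants_per_subject < 0:
            raise ValueError("counts must be >= 0")


# --------------------------------------------------------------------------
# Reference windows with repeat tracts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatTract:
    start: int  # 1-based position of first repeat base
    unit: str
    copies: int

    @property
    def length(self) -> int:
        return len(self.unit) * self.copies

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def _window_layout(spec: FixtureSpec) -> tuple[str, list[RepeatTract]]:
    rng = random.Random(spec.seed)
    seq = [rng.choice(_BASES) for _ in range(spec.window_length)]
    tracts: list[RepeatTract] = []
    # lay down evenly spaced tracts, each at least repeat_context_length long
    n_tracts = max(1, (spec.window_length - 2 * spec.margin) // 240)
    stride = (spec.window_length - 2 * spec.margin) // n_tracts
    for i in range(n_tracts):
        unit_len = rng.choice((1, 2, 3))
        copies = max(2, -(-spec.repeat_context_length // unit_len))
        unit = "".join(rng.choice(_BASES) for _ in range(unit_len))
        # avoid a unit that extends the run beyond the intended tract
        start0 = spec.margin + i * stride  # 0-based
        for j in range(copies * unit_len):
            seq[start0 + j] = unit[j % unit_len]
        # break the repeat on both flanks so the tract boundary is sharp
        left, right = start0 - 1, start0 + copies * unit_len
        seq[left] = next(b for b in _BASES if b != unit[-1] and b != seq[left - 1])
        seq[right] = next(b for b in _BASES if b != unit[0])
        tracts.append(RepeatTract(start0 + 1, unit, copies))
    return "".join(seq), tracts


def make_reference_window(spec: FixtureSpec) -> ReferenceWindow:
    """A synthetic reference window containing at least one tandem-repeat
    tract of the spec's length, deterministic under the seed."""
    sequence, _ = _window_layout(spec)
    return ReferenceWindow(spec.chromosome, 1, sequence, spec.build_label)


def repeat_tracts(spec: FixtureSpec) -> list[RepeatTract]:
    """The repeat layout of :func:`make_reference_window` for the same spec."""
    _, tracts = _window_layout(spec)
    return tracts


# --------------------------------------------------------------------------
# Variant corpus with equivalent spellings
# --------------------------------------------------------------------------


@dataclass
class TruthEntry:
    subject_id: str
    variant: RawVariant  # the unique minimal representation
    zygosity: str
    spellings: list[RawVariant] = field(default_factory=list)


def _pad_spelling(v: RawVariant, window: ReferenceWindow, rng: random.Random) -> RawVariant:
    """Un-trim: append shared reference bases after the edit to both alleles
    (the inverse of suffix trimming)."""
    pad = rng.randint(1, 3)
    tail = ""
    for k in range(pad):
        pos = v.end + 1 + k
        if pos > window.end:
            break
        tail += window.base_at(pos)
    if not tail:
        return v
    return RawVariant(v.chromosome, v.position, v.ref_allele + tail,
                      v.alt_allele + tail, v.genome_build)


def _right_shift_spelling(v: RawVariant, window: ReferenceWindow,
                          tract: RepeatTract, rng: random.Random) -> RawVariant:
    """Move an indel spelled at the tract's left edge to a position further
    right that describes the same edited sequence."""
    unit_len = len(tract.unit)
    indel_units = abs(len(v.ref_allele) - len(v.alt_allele)) // unit_len
    max_shift_units = tract.copies - max(indel_units, 1)
    if max_shift_units < 1:
        return _pad_spelling(v, window, rng)
    shift = rng.randint(1, max_shift_units) * unit_len
    pos = v.position + shift
    if len(v.alt_allele) > len(v.ref_allele):  # insertion
        anchor = window.base_at(pos)
        inserted = v.alt_allele[len(v.ref_allele):]
        # rotate the inserted sequence to match the repeat phase at the new anchor
        rot = shift % len(inserted) if len(inserted) else 0
        shifted = RawVariant(v.chromosome, pos, anchor,
                             anchor + inserted[rot:] + inserted[:rot], v.genome_build)
    else:  # deletion
        anchor = window.base_at(pos)
        del_len = len(v.ref_allele) - len(v.alt_allele)
        deleted = window.slice(pos + 1, pos + del_len)
        shifted = RawVariant(v.chromosome, pos, anchor + deleted, anchor, v.genome_build)
    # guaranteed-equivalence check against the construction
    if apply_edit(window, shifted) != apply_edit(window, v):
        return _pad_spelling(v, window, rng)
    return shifted


def _make_variant(window: ReferenceWindow, tract: RepeatTract,
                  rng: random.Random, kind: str) -> RawVariant:
    chrom, build = window.chromosome, window.genome_build
    if kind == "snv":
        pos = rng.randint(window.start + 1, window.end - 1)
        ref = window.base_at(pos)
        alt = rng.choice([b for b in _BASES if b != ref])
        return RawVariant(chrom, pos, ref, alt, build)
    anchor_pos = tract.start - 1  # base just left of the tract
    anchor = window.base_at(anchor_pos)
    if kind == "ins":
        return RawVariant(chrom, anchor_pos, anchor, anchor + tract.unit, build)
    # deletion of one repeat unit, anchored left of the tract
    deleted = window.slice(tract.start, tract.start + len(tract.unit) - 1)
    return RawVariant(chrom, anchor_pos, anchor + deleted, anchor, build)


def make_variant_corpus(spec: FixtureSpec,
                        window: Optional[ReferenceWindow] = None) -> list[TruthEntry]:
    """Per-subject true variants, each with 1-2 equivalent spellings.

    The first spelling is the minimal representation itself; with probability
    ``fraction_nonminimal`` an equivalent padded or right-shifted spelling is
    added.  The truth manifest records the minimal form, which normalization
    of every spelling must reproduce.
    """
    window = window or make_reference_window(spec)
    tracts = repeat_tracts(spec)
    rng = random.Random(spec.seed + 1)
    entries: list[TruthEntry] = []
    kinds = ("snv", "ins", "del")
    for s in range(spec.n_subjects):
        subject = f"S{s + 1:03d}"
        taken: set[RawVariant] = set()
        for i in range(spec.n_variants_per_subject):
            tract = tracts[(s * spec.n_variants_per_subject + i) % len(tracts)]
            kind = kinds[i % len(kinds)]
            v = _make_variant(window, tract, rng, kind)
            for _attempt in range(60):
                if v not in taken:
                    break
                tract = tracts[rng.randrange(len(tracts))]
                v = _make_variant(window, tract, rng, kind)
            taken.add(v)
            spellings = [v]
            if rng.random() < spec.fraction_nonminimal:
                if kind == "snv":
                    spellings.append(_pad_spelling(v, window, rng))
                else:
                    spellings.append(_right_shift_spelling(v, window, tract, rng))
            zygosity = rng.choice(("heterozygous", "homozygous"))
            entries.append(TruthEntry(subject, v, zygosity, spellings))
    return entries


def make_vcf(spec: FixtureSpec, window: Optional[ReferenceWindow] = None,
             out_path: Optional[Path] = None) -> tuple[str, list[TruthEntry]]:
    """A multi-sample VCF realising the corpus, plus its truth manifest."""
    window = window or make_reference_window(spec)
    entries = make_variant_corpus(spec, window)
    subjects = sorted({e.subject_id for e in entries}) or ["S001"]
    idx = {s: i for i, s in enumerate(subjects)}

    lines = [
        "##fileformat=VCFv4.2",
        f"##reference={spec.build_label}",
        f"##contig=<ID={spec.chromosome},length={window.end}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subjects),
    ]
    records: list[tuple[int, int, str]] = []
    for order, entry in enumerate(entries):
        gt = "1/1" if entry.zygosity == "homozygous" else "0/1"
        for spelling in entry.spellings:
            gts = ["0/0"] * len(subjects)
            gts[idx[entry.subject_id]] = gt
            records.append(
                (spelling.position, order,
                 f"{spelling.chromosome}\t{spelling.position}\t.\t{spelling.ref_allele}"
                 f"\t{spelling.alt_allele}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
            )
    records.sort(key=lambda r: (r[0], r[1]))
    lines.extend(r[2] for r in records)
    text = "\n".join(lines) + "\n"
    if out_path is not None:
        Path(out_path).write_text(text, encoding="utf-8")
    return text, entries


def write_fasta(window: ReferenceWindow, path: Path) -> Path:
    """The window as a FASTA contig (position 1 of the contig = window.start)."""
    seq = window.sequence
    body = "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60))
    Path(path).write_text(f">{window.chromosome}\n{body}\n", encoding="utf-8")
    return Path(path)


# --------------------------------------------------------------------------
# Pharmacogene cohort
# --------------------------------------------------------------------------


def make_fixture_allele_definitions(spec: FixtureSpec,
                                    window: Optional[ReferenceWindow] = None) -> AlleleDefinitions:
    """Star-allele defining variants placed on the synthetic build, in
    non-repeat sequence away from the variant corpus."""
    window = window or make_reference_window(spec)
    tracts = repeat_tracts(spec)
    forbidden = set()
    for t in tracts:
        forbidden |= set(range(t.start - 2, t.end + 3))
    rng = random.Random(spec.seed + 2)

    def pick(exclude: set[int]) -> dict:
        while True:
            pos = rng.randint(window.start + spec.margin // 2, window.end - spec.margin // 2)
            if pos in forbidden or pos in exclude:
                continue
            ref = window.base_at(pos)
            alt = rng.choice([b for b in _BASES if b != ref])
            return {"chromosome": window.chromosome, "position": pos,
                    "ref": ref, "alt": alt}

    taken: set[int] = set()
    star2 = pick(taken)
    taken.add(star2["position"])
    star3 = pick(taken)
    taken.add(star3["position"])
    vkorc = pick(taken)
    return AlleleDefinitions(
        genome_build=spec.build_label,
        cyp2c9={"*2": star2, "*3": star3},
        vkorc1_1639=vkorc,
        version=f"fixture-seed{spec.seed}",
    )


@dataclass
class PgxSubject:
    subject_id: str
    cyp2c9: str
    vkorc1: str
    covered: bool
    covariates: dict


@dataclass
class PgxCohort:
    vcf_text: str
    subjects: list[PgxSubject]
    allele_definitions: AlleleDefinitions

    @property
    def expected(self) -> dict[str, tuple[str, str]]:
        return {
            s.subject_id: (
                (s.cyp2c9, s.vkorc1) if s.covered else ("unknown", "unknown")
            )
            for s in self.subjects
        }


def _diplotype_gt(diplotype: str, star: str) -> str:
    count = diplotype.split("/").count(star)
    return {0: "0/0", 1: "0/1", 2: "1/1"}[count]


def make_pgx_cohort(
    spec: FixtureSpec,
    allele_definitions: Optional[AlleleDefinitions] = None,
    *,
    include_uncovered: bool = True,
) -> PgxCohort:
    """A cohort whose subjects tile every CYP2C9 diplotype and VKORC1 state
    in the closed sets, realised as VCF genotypes at the defining positions.

    The expected-genotype table is the construction itself, so it serves as
    the oracle for genotype derivation.  When ``include_uncovered`` is set,
    one extra subject has no coverage evidence and expects ``unknown``.
    """
    defs = allele_definitions or make_fixture_allele_definitions(spec)
    rng = random.Random(spec.seed + 3)
    diplotypes = [d for d in CYP2C9_DIPLOTYPES if d != "unknown"]
    states = [s for s in VKORC1_STATES if s != "unknown"]
    subjects: list[PgxSubject] = []
    n = 0
    for i in range(max(len(diplotypes), len(states), spec.n_subjects)):
        n += 1
        subjects.append(
            PgxSubject(
                subject_id=f"P{n:03d}",
                cyp2c9=diplotypes[i % len(diplotypes)],
                vkorc1=states[i % len(states)],
                covered=True,
                covariates=_random_covariates(rng),
            )
        )
    if include_uncovered:
        # no observed variants and no coverage evidence: nothing may be
        # inferred, the expected genotype is unknown/unknown
        n += 1
        subjects.append(
            PgxSubject(f"P{n:03d}", "*1/*1", "GG", covered=False,
                       covariates=_random_covariates(rng)))

    ids = [s.subject_id for s in subjects]
    lines = [
        "##fileformat=VCFv4.2",
        f"##reference={defs.genome_build}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids),
    ]
    # a benign marker SNV carried by every covered subject guarantees each one
    # is observed in the store (a *1/*1 + GG subject has no defining variant)
    marker_pos = max(
        int(d["position"])
        for d in (defs.cyp2c9["*2"], defs.cyp2c9["*3"], defs.vkorc1_1639)
    ) + 97
    marker = {"chromosome": defs.vkorc1_1639["chromosome"],
              "position": marker_pos, "ref": "A", "alt": "G"}
    sites = [
        (defs.cyp2c9["*2"], [_diplotype_gt(s.cyp2c9, "*2") for s in subjects]),
        (defs.cyp2c9["*3"], [_diplotype_gt(s.cyp2c9, "*3") for s in subjects]),
        (defs.vkorc1_1639,
         [{"GG": "0/0", "GA": "0/1", "AA": "1/1"}[s.vkorc1] for s in subjects]),
        (marker, ["0/1" if s.covered else "0/0" for s in subjects]),
    ]
    sites.sort(key=lambda x: x[0]["position"])
    for defn, gts in sites:
        lines.append(
            f"{defn['chromosome']}\t{defn['position']}\t.\t{defn['ref']}\t{defn['alt']}"
            f"\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    return PgxCohort("\n".join(lines) + "\n", subjects, defs)


def _random_covariates(rng: random.Random) -> dict:
    """Plausible adult anticoagulation-clinic covariates."""
    return {
        "age_decades": rng.randint(4, 9),
        "height_cm": round(rng.uniform(150, 195), 1),
        "weight_kg": round(rng.uniform(50, 110), 1),
        "race_group": rng.choice(
            ("white", "asian", "black_or_african_american", "mixed_or_missing")
        ),
        "enzyme_inducer": rng.random() < 0.05,
        "amiodarone": rng.random() < 0.1,
    }
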