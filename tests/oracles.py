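"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the normalization oracle
works by exhaustive enumeration of equivalent representations and the dosing
oracle is literal spreadsheet-style arithmetic on the coefficient table.
"""

from __future__ import annotations

from cgdm.normalization import RawVariant, ReferenceWindow


def edited_sequence(window: ReferenceWindow, v: RawVariant) -> str:
    """Apply the edit described by (pos, ref, alt) to the window sequence.

    Independent re-statement of the ground truth (string splice only).
    """
    i = v.position - window.start
    assert window.sequence[i : i + len(v.ref_allele)] == v.ref_allele
    return window.sequence[:i] + v.alt_allele + window.sequence[i + len(v.ref_allele):]


def enumerate_representations(window: ReferenceWindow, v: RawVariant,
                              max_ref_len: int | None = None) -> list[tuple[int, str, str]]:
    """All (pos, ref, alt) triples over the window that describe the same
    edited sequence as ``v``, with non-empty alleles."""
    target = edited_sequence(window, v)
    original = window.sequence
    if max_ref_len is None:
        max_ref_len = abs(len(v.ref_allele) - len(v.alt_allele)) + max(
            len(v.ref_allele), len(v.alt_allele)
        ) + 2
    out = []
    delta = len(target) - len(original)
    for i in range(len(original)):  # 0-based offset of ref allele
        for ref_len in range(1, max_ref_len + 1):
            if i + ref_len > len(original):
                break
            alt_len = ref_len + delta
            if alt_len < 1:
                continue
            prefix, suffix = original[:i], original[i + ref_len:]
            if not target.startswith(prefix):
                continue
            if suffix and not target.endswith(suffix):
                continue
            alt = target[i : len(target) - len(suffix)] if suffix else target[i:]
            if len(alt) != alt_len:
                continue
            ref = original[i : i + ref_len]
            if ref == alt:
                continue
            if prefix + alt + suffix != target:
                continue
            out.append((window.start + i, ref, alt))
    return sorted(set(out))


def oracle_minimal(window: ReferenceWindow, v: RawVariant) -> tuple[int, str, str]:
    """The unique left-most minimal representation, found by enumeration.

    A representation is in normal form when (1) its alleles end in different
    bases and (2) they start with different bases unless one allele is a
    single base (the retained anchor).  Within a window whose flanks break
    the repeat context, exactly one equivalent representation satisfies both.
    """
    reps = enumerate_representations(window, v)
    normal = [
        (p, r, a)
        for p, r, a in reps
        if r[-1] != a[-1] and (r[0] != a[0] or min(len(r), len(a)) == 1)
    ]
    assert normal, f"no normal-form representation found for {v}"
    # left-most; ties cannot occur for a fixed edited sequence, but keep the
    # ordering deterministic anyway
    return min(normal)


def oracle_weekly_dose(coeffs: dict, *, age_decades: int, height_cm: float,
                       weight_kg: float, race_group: str, enzyme_inducer: bool,
                       amiodarone: bool, cyp2c9: str | None = None,
                       vkorc1: str | None = None) -> float:
    """Spreadsheet arithmetic for the warfarin models: plain sum of products,
    squared at the end."""
    s = coeffs["intercept"]
    s += coeffs["age_decades"] * age_decades
    s += coeffs["height_cm"] * height_cm
    s += coeffs["weight_kg"] * weight_kg
    s += coeffs["race"][race_group]
    s += coeffs["enzyme_inducer"] * (1 if enzyme_inducer else 0)
    s += coeffs["amiodarone"] * (1 if amiodarone else 0)
    if cyp2c9 is not None:
        s += coeffs["cyp2c9"][cyp2c9]
    if vkorc1 is not None:
        s += coeffs["vkorc1_1639"][vkorc1]
    return s * s
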