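"""Independent brute-force oracles, deliberately written against plain
string codes and explicit loops so they share no code path with the
package implementation they check."""

from __future__ import annotations


def split(code: str) -> list[str]:
    return code.split(".")


def is_strict_prefix(a: str, b: str) -> bool:
    """Segment-wise (not string-prefix) ancestor test."""
    sa, sb = split(a), split(b)
    if len(sa) >= len(sb):
        return False
    for left, right in zip(sa, sb):
        if left != right:
            return False
    return True


def in_35_family(code: str) -> bool:
    return split(code)[0] == "35"


def misc_codes_of(rows: list[tuple[str, str]]) -> set[str]:
    """Catch-all codes given (code, name) rows: last segment 99 or a
    'misc'/'unspecified' name."""
    out = set()
    for code, name in rows:
        lowered = name.lower()
        if split(code)[-1] == "99" or "misc" in lowered or "unspecified" in lowered:
            out.add(code)
    return out


def oracle_classify(
    member_annotation_sets: list[set[str]],
    misc: set[str],
) -> tuple[str, str | None]:
    """Re-derivation of the consolidation decision tree from first
    principles, over string codes.

    Returns (category, resolved code or None).  Members with an empty
    annotation set contribute the not-assigned code "35".
    """
    gathered: set[str] = set()
    for annotations in member_annotation_sets:
        if annotations:
            gathered |= set(annotations)
        else:
            gathered.add("35")

    if all(in_35_family(code) for code in gathered):
        return "UNKNOWN_FUNCTION", "35"
    if len(gathered) == 1:
        return "NO_INCONSISTENCIES", next(iter(gathered))

    informative = {code for code in gathered if not in_35_family(code)}
    if len(informative) == 1:
        target = next(iter(informative))
        if target in misc:
            return "MANUAL_CHECK", None
        return "UPGRADED_FROM_35", target

    finest = set()
    for code in informative:
        ancestor_of_other = False
        for other in informative:
            if other != code and is_strict_prefix(code, other):
                ancestor_of_other = True
                break
        if not ancestor_of_other:
            finest.add(code)
    without_misc = {code for code in finest if code not in misc}
    remaining = without_misc if without_misc else finest
    if len(remaining) == 1:
        target = next(iter(remaining))
        if target not in misc:
            return "UPGRADED_WITHIN_BIN", target
    return "MANUAL_CHECK", None


def oracle_resolve_hierarchy(codes: set[str]) -> set[str]:
    """Pairwise ancestor-removal reference for the finest-level filter."""
    keep = set()
    for code in codes:
        if not any(is_strict_prefix(code, other) for other in codes if other != code):
            keep.add(code)
    return keep
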