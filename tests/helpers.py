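"""Independent brute-force oracles used to check the vectorized detector."""

from __future__ import annotations

ACGT = set("ACGT")


def minimal_period(s: str) -> int:
    """Smallest q >= 1 with s[i] == s[i+q] for all i (partial copies allowed)."""
    n = len(s)
    for q in range(1, n):
        if all(s[i] == s[i + q] for i in range(n - q)):
            return q
    return n


def oracle_find_runs(
    seq: str,
    min_unit: int = 2,
    max_unit: int = 25,
    min_copies: int = 3,
    min_run_bp: int = 12,
) -> list[tuple[int, int, str]]:
    """Enumerate every (start, end, period) triple and test it directly.

    Returns maximal, primitive, zero-mismatch runs as sorted
    (start, end, unit) tuples. Deliberately naive: left/right maximality and
    the minimal period are each re-derived per candidate.
    """
    s = seq.upper()
    n = len(s)
    found = set()
    for p in range(min_unit, max_unit + 1):
        for start in range(0, n - p + 1):
            if any(s[start + k] not in ACGT for k in range(p)):
                continue
            # left-maximality at this period
            if start > 0 and s[start - 1] in ACGT and s[start - 1] == s[start + p - 1]:
                continue
            end = start + p
            while end < n and s[end] in ACGT and s[end] == s[end - p]:
                end += 1
            run_len = end - start
            if run_len // p < min_copies or run_len < min_run_bp:
                continue
            if minimal_period(s[start:end]) != p:
                continue
            found.add((start, end, s[start : start + p]))
    return sorted(found)


def oracle_canonical(unit: str) -> str:
    """Canonical key by explicit enumeration of all rotation/revcomp strings."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(unit.upper()))
    variants = []
    for base in (unit.upper(), rc):
        variants.extend(base[i:] + base[:i] for i in range(len(base)))
    return min(variants)
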