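"""Maximal perfect tandem-repeat detection and repeat-unit canonicalization.

Telomeric arrays are perfect short tandem repeats, so the detector is exact:
it reports every maximal run of a primitive unit of 2-25 bp (configurable)
with zero mismatch tolerance. A repeat unit read off a sequencing read is an
arbitrary rotation of either strand of the underlying monomer; two
normalized representatives are therefore attached to every unit:

* the *canonical key* -- the lexicographically smallest string over all
  rotations of the unit and of its reverse complement (A<C<G<T). This is the
  strand/rotation-invariant identity used for counting.
* the *display form* -- the rotation (of either strand) ending with the
  longest run of consecutive Gs, the convention used in telomere research
  (e.g. canonical AACCT is displayed as TTAGG).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

DEFAULT_MIN_UNIT = 2
DEFAULT_MAX_UNIT = 25
DEFAULT_MIN_COPIES = 3
DEFAULT_MIN_RUN_BP = 12

_COMP = str.maketrans("ACGTN", "TGCAN")
_RC_ALPHABET = frozenset("ACGTN")
_ACGT = frozenset("ACGT")

# uint8 lookup: True for A/C/G/T (uppercase ASCII)
_VALID_LUT = np.zeros(256, dtype=bool)
_VALID_LUT[[ord(c) for c in "ACGT"]] = True


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement, uppercase; N maps to N."""
    s = seq.upper()
    bad = set(s) - _RC_ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s.translate(_COMP)[::-1]


def primitive_root(unit: str) -> str:
    """Shortest string p such that ``unit`` is p repeated an integer number of times."""
    u = unit.upper()
    if not u:
        raise ValueError("empty repeat unit")
    bad = set(u) - _ACGT
    if bad:
        raise ValueError(f"repeat unit must be over ACGT, got: {sorted(bad)}")
    n = len(u)
    for d in range(1, n + 1):
        if n % d == 0 and u[:d] * (n // d) == u:
            return u[:d]
    return u  # pragma: no cover - d == n always matches


@dataclass(frozen=True)
class MotifKey:
    """Strand/rotation-invariant identity of a repeat unit.

    ``canonical`` is the counting key; ``display`` is the G-convention
    representative (same length, same composition up to complementation).
    """

    canonical: str
    display: str
    unit_length: int


def _variants(u: str) -> list[str]:
    """All rotations of u and of its reverse complement (2*|u| strings)."""
    rc = reverse_complement(u)
    out = []
    for s in (u, rc):
        d = s + s
        out.extend(d[i : i + len(s)] for i in range(len(s)))
    return out


def _trailing_g(s: str) -> int:
    n = 0
    for ch in reversed(s):
        if ch != "G":
            break
        n += 1
    return n


def canonical_key(unit: str) -> MotifKey:
    """Normalize a primitive repeat unit to its MotifKey.

    Raises ValueError for non-primitive units; callers must pass
    ``primitive_root`` output.
    """
    u = unit.upper()
    if primitive_root(u) != u:
        raise ValueError(f"repeat unit is not primitive: {unit!r}")
    vs = _variants(u)
    canonical = min(vs)
    best_g = max(map(_trailing_g, vs))
    if best_g == 0:
        display = canonical
    else:
        display = min(v for v in vs if _trailing_g(v) == best_g)
    return MotifKey(canonical=canonical, display=display, unit_length=len(u))


def display_form(unit: str) -> str:
    """G-convention representative of a primitive unit (see :class:`MotifKey`)."""
    return canonical_key(unit).display


@dataclass(frozen=True)
class RepeatRun:
    """One maximal perfect tandem repeat occurrence within one sequence.

    ``unit`` is the repeat unit as observed on the forward orientation of the
    sequence, starting at ``start``; it is always primitive. A partial
    trailing copy extends ``matched_length_bp`` but not ``full_copies``.
    """

    sequence_id: str
    start: int
    end: int
    unit: str
    unit_length: int
    full_copies: int
    matched_length_bp: int


def _check_params(min_unit: int, max_unit: int, min_copies: int, min_run_bp: int) -> None:
    if not (1 < min_unit <= max_unit):
        raise ValueError(f"require 1 < min_unit <= max_unit, got {min_unit}..{max_unit}")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    if min_run_bp < 1:
        raise ValueError("min_run_bp must be positive")


def _is_minimal_period(arr: np.ndarray, start: int, end: int, p: int) -> bool:
    """True iff no q < p is also a shift-period of arr[start:end]."""
    for q in range(1, p):
        if bool(np.all(arr[start : end - q] == arr[start + q : end])):
            return False
    return True


def find_tandem_runs_batch(
    records: Sequence[tuple[str, str]],
    min_unit: int = DEFAULT_MIN_UNIT,
    max_unit: int = DEFAULT_MAX_UNIT,
    min_copies: int = DEFAULT_MIN_COPIES,
    min_run_bp: int = DEFAULT_MIN_RUN_BP,
) -> list[list[RepeatRun]]:
    """Detect maximal perfect tandem runs in many sequences at once.

    The sequences are concatenated with a non-nucleotide sentinel and each
    candidate period is scanned with one vectorized pass, so the cost is a
    small constant number of array operations per period regardless of the
    number of reads. Returns one (start-sorted) run list per input record.
    """
    _check_params(min_unit, max_unit, min_copies, min_run_bp)
    if not records:
        return []
    seqs = [s.upper() for _, s in records]
    ids = [rid for rid, _ in records]
    joined = "\x00".join(seqs)
    arr = np.frombuffer(joined.encode("ascii", "replace"), dtype=np.uint8)
    n = arr.size
    valid = _VALID_LUT[arr]

    # start offset of each sequence inside the concatenation
    seq_starts = np.empty(len(seqs), dtype=np.int64)
    off = 0
    for i, s in enumerate(seqs):
        seq_starts[i] = off
        off += len(s) + 1

    max_len = max(map(len, seqs))
    per_seq: list[list[RepeatRun]] = [[] for _ in seqs]

    for p in range(min_unit, max_unit + 1):
        if max_len < max(p * min_copies, min_run_bp) or n <= p:
            break
        eq = (arr[:-p] == arr[p:]) & valid[:-p] & valid[p:]
        edges = np.diff(np.concatenate(([False], eq, [False])).astype(np.int8))
        starts = np.flatnonzero(edges == 1)
        stops = np.flatnonzero(edges == -1)
        run_len = stops - starts + p
        keep = (run_len >= min_run_bp) & (run_len // p >= min_copies)
        for s0, rl in zip(starts[keep].tolist(), run_len[keep].tolist()):
            end = s0 + rl
            if not _is_minimal_period(arr, s0, end, p):
                continue
            idx = int(np.searchsorted(seq_starts, s0, side="right")) - 1
            ls = s0 - int(seq_starts[idx])
            per_seq[idx].append(
                RepeatRun(
                    sequence_id=ids[idx],
                    start=ls,
                    end=ls + rl,
                    unit=seqs[idx][ls : ls + p],
                    unit_length=p,
                    full_copies=rl // p,
                    matched_length_bp=rl,
                )
            )

    for runs in per_seq:
        runs.sort(key=lambda r: (r.start, r.unit_length))
    return per_seq


def find_tandem_runs(
    seq: str,
    sequence_id: str = "seq",
    min_unit: int = DEFAULT_MIN_UNIT,
    max_unit: int = DEFAULT_MAX_UNIT,
    min_copies: int = DEFAULT_MIN_COPIES,
    min_run_bp: int = DEFAULT_MIN_RUN_BP,
) -> list[RepeatRun]:
    """All maximal perfect tandem runs in one sequence, sorted by start.

    Every run is reported once, at its minimal (primitive) period, with zero
    mismatches; any non-ACGT character (case-insensitive input) breaks runs.
    Runs of distinct motifs may overlap.
    """
    if not seq:
        return []
    return find_tandem_runs_batch(
        [(sequence_id, seq)],
        min_unit=min_unit,
        max_unit=max_unit,
        min_copies=min_copies,
        min_run_bp=min_run_bp,
    )[0]
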