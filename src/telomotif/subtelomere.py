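"""Sub-telomeric anchor extraction from read pairs and greedy contig assembly.

Read pairs with exactly one telomeric mate bridge the junction between a
telomeric array and unique sequence: the non-telomeric mate ("anchor")
originates within roughly one insert size of the array boundary. Instead of
mapping reads to the repeat, a mate is classified by motif content -- the
fraction of its bases covered by perfect tandem runs of the target motif --
which is equivalent for perfect arrays. Anchors can then be merged into
sub-telomeric contigs with a deterministic greedy exact-overlap assembler
(desk-scale; export the anchors FASTA to a real assembler for large data).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .repeat_core import (
    DEFAULT_MAX_UNIT,
    DEFAULT_MIN_COPIES,
    DEFAULT_MIN_RUN_BP,
    DEFAULT_MIN_UNIT,
    MotifKey,
    canonical_key,
    find_tandem_runs_batch,
    reverse_complement,
)

DEFAULT_PURITY = 0.8
DEFAULT_MIN_OVERLAP = 31


def _motif_fractions(
    reads: Sequence[str],
    motif: MotifKey,
    min_unit: int,
    max_unit: int,
    min_copies: int,
    min_run_bp: int,
) -> list[float]:
    records = [(str(i), r) for i, r in enumerate(reads)]
    runs_per_read = find_tandem_runs_batch(
        records, min_unit=min_unit, max_unit=max_unit,
        min_copies=min_copies, min_run_bp=min_run_bp,
    )
    cache: dict[str, str] = {}
    out = []
    for read, runs in zip(reads, runs_per_read):
        intervals = []
        for run in runs:
            canon = cache.get(run.unit)
            if canon is None:
                canon = cache[run.unit] = canonical_key(run.unit).canonical
            if canon == motif.canonical:
                intervals.append((run.start, run.end))
        if not intervals:
            out.append(0.0)
            continue
        intervals.sort()
        covered = 0
        cur_s, cur_e = intervals[0]
        for s, e in intervals[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            elif e > cur_e:
                cur_e = e
        covered += cur_e - cur_s
        out.append(covered / len(read))
    return out


def telomeric_fraction(
    read: str,
    motif: MotifKey,
    *,
    min_unit: int = DEFAULT_MIN_UNIT,
    max_unit: int = DEFAULT_MAX_UNIT,
    min_copies: int = DEFAULT_MIN_COPIES,
    min_run_bp: int = DEFAULT_MIN_RUN_BP,
) -> float:
    """Fraction of read bases inside perfect tandem runs of ``motif`` (in [0, 1])."""
    if not read:
        raise ValueError("empty read")
    return _motif_fractions([read.upper()], motif, min_unit, max_unit, min_copies, min_run_bp)[0]


@dataclass(frozen=True)
class AnchorPair:
    """A read pair with exactly one telomeric mate; the other mate is the anchor."""

    pair_id: str
    telomeric_mate: str
    anchor_mate: str
    telomeric_fraction_of_mate: float


def extract_anchor_mates(
    pairs: Iterable[tuple[str, str, str]],
    motif: MotifKey,
    purity: float = DEFAULT_PURITY,
    *,
    min_unit: int = DEFAULT_MIN_UNIT,
    max_unit: int = DEFAULT_MAX_UNIT,
    min_copies: int = DEFAULT_MIN_COPIES,
    min_run_bp: int = DEFAULT_MIN_RUN_BP,
) -> list[AnchorPair]:
    """Keep pairs where exactly one mate is telomeric (fraction >= purity).

    ``pairs`` yields (pair_id, mate1, mate2). The non-telomeric mate of each
    kept pair is exported as the sub-telomeric anchor.
    """
    if not (0 < purity <= 1):
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    pair_list = [(pid, m1.upper(), m2.upper()) for pid, m1, m2 in pairs]
    for pid, m1, m2 in pair_list:
        if not m1 or not m2:
            raise ValueError(f"pair {pid!r} has an empty mate")
    flat = [m for _, m1, m2 in pair_list for m in (m1, m2)]
    fracs = _motif_fractions(flat, motif, min_unit, max_unit, min_copies, min_run_bp)
    out = []
    for i, (pid, m1, m2) in enumerate(pair_list):
        f1, f2 = fracs[2 * i], fracs[2 * i + 1]
        if (f1 >= purity) == (f2 >= purity):
            continue
        if f1 >= purity:
            out.append(AnchorPair(pid, m1, m2, f1))
        else:
            out.append(AnchorPair(pid, m2, m1, f2))
    return out


def _longest_overlap(a: str, b: str, min_overlap: int) -> int:
    """Longest k >= min_overlap such that a's suffix of length k equals b's prefix."""
    max_k = min(len(a), len(b))
    if max_k < min_overlap:
        return 0
    seed = b[:min_overlap]
    start = len(a) - max_k
    while True:
        i = a.find(seed, start)
        if i == -1:
            return 0
        k = len(a) - i
        if a.endswith(b[:k], i):
            return k
        start = i + 1


def greedy_assemble(seqs: Sequence[str], min_overlap: int = DEFAULT_MIN_OVERLAP) -> list[str]:
    """Merge sequences by longest exact suffix-prefix overlap until none remains.

    Both orientations of the second sequence are considered. Deterministic:
    each step picks the longest overlap, ties broken by the lexicographically
    smallest (left contig, oriented right contig) pair. Returns the final
    contigs in a deterministic order (longest first, then lexicographic).
    """
    if not seqs:
        raise ValueError("no sequences to assemble")
    if min_overlap < 1:
        raise ValueError("min_overlap must be positive")
    contigs: dict[int, str] = {i: s.upper() for i, s in enumerate(seqs)}
    next_id = len(seqs)
    # overlap cache: (left_id, right_id, orient) -> k; orient 0 = forward, 1 = revcomp
    cache: dict[tuple[int, int, int], int] = {}

    def fill(i: int, j: int) -> None:
        a, b = contigs[i], contigs[j]
        cache[(i, j, 0)] = _longest_overlap(a, b, min_overlap)
        cache[(i, j, 1)] = _longest_overlap(a, reverse_complement(b), min_overlap)

    ids = sorted(contigs)
    for i in ids:
        for j in ids:
            if i != j:
                fill(i, j)

    while len(contigs) > 1:
        best = None
        for (i, j, orient), k in cache.items():
            if k == 0:
                continue
            b = contigs[j] if orient == 0 else reverse_complement(contigs[j])
            cand = (-k, contigs[i], b, i, j, orient)
            if best is None or cand < best:
                best = cand
        if best is None:
            break
        _, a, b, i, j, _ = best
        k = -best[0]
        merged = a + b[k:]
        for key in [key for key in cache if key[0] in (i, j) or key[1] in (i, j)]:
            del cache[key]
        del contigs[i], contigs[j]
        new_id = next_id
        next_id += 1
        contigs[new_id] = merged
        for other in contigs:
            if other != new_id:
                fill(new_id, other)
                fill(other, new_id)

    return sorted(contigs.values(), key=lambda s: (-len(s), s))
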