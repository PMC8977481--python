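"""Candidate filtering and the threefold-dominance telomeric-motif call.

A telomeric repeat motif (TRM) is expected to dominate the short-tandem-
repeat landscape of a genome sequenced at >=10x: many repeat-containing
reads, a large coverage-normalized repeat length, and "pure" reads drawn
from inside multi-kb arrays. Motifs passing those thresholds become
candidates; the final verdict calls the single best candidate when its
abundance is threefold or higher than the runner-up (inclusive boundary).
A best candidate that fails the dominance test is reported as *ambiguous*
with the full ranked list preserved, so external evidence (literature, an
assembly-terminus scan) can settle it; no candidates at all means *absent*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Sequence

from .profile import STAT_FIELDS, MotifStats
from .repeat_core import MotifKey

DEFAULT_FOLD_THRESHOLD = 3.0


@dataclass(frozen=True)
class CandidateCriteria:
    """Thresholds a motif must clear to be considered a TRM candidate."""

    min_reads_with_repeat: int = 50
    min_per_1x_bp: float = 500.0
    min_pure_reads: int = 10
    min_unit_length: int = 2
    max_unit_length: int = 25
    abundance_field: str = "total_repeat_length_per_1x"

    def __post_init__(self) -> None:
        if self.abundance_field not in STAT_FIELDS:
            raise ValueError(f"unknown abundance field {self.abundance_field!r}")
        if min(self.min_reads_with_repeat, self.min_per_1x_bp, self.min_pure_reads) < 0:
            raise ValueError("candidate thresholds must be non-negative")


@dataclass(frozen=True)
class TRMCall:
    """Final pipeline verdict with its evidence trail."""

    status: str  # "called" | "ambiguous" | "absent"
    motif: MotifKey | None
    fold_ratio: float
    candidates: tuple[tuple[MotifKey, float], ...] = field(default_factory=tuple)
    note: str = ""


def _passes(row: MotifStats, c: CandidateCriteria) -> bool:
    if not (c.min_unit_length <= row.unit_length <= c.max_unit_length):
        return False
    if row.n_reads_with_repeat < c.min_reads_with_repeat:
        return False
    if row.n_pure_reads < c.min_pure_reads:
        return False
    per_1x = row.total_repeat_length_per_1x
    if c.min_per_1x_bp > 0 and not (per_1x >= c.min_per_1x_bp):  # NaN fails
        return False
    return True


def identify_candidates(
    stats: Sequence[MotifStats],
    criteria: CandidateCriteria | None = None,
) -> list[tuple[MotifKey, float]]:
    """Motifs passing all thresholds, ranked by abundance (descending).

    Ties are broken deterministically by canonical key. Motifs whose
    abundance statistic is NA are never candidates.
    """
    c = criteria or CandidateCriteria()
    ranked = []
    for row in stats:
        if not _passes(row, c):
            continue
        abundance = getattr(row, c.abundance_field)
        if isinstance(abundance, float) and math.isnan(abundance):
            continue
        key = MotifKey(row.canonical, row.display, row.unit_length)
        ranked.append((key, float(abundance)))
    ranked.sort(key=lambda kv: (-kv[1], kv[0].canonical))
    return ranked


def call_trm(
    candidates: Sequence[tuple[MotifKey, float]],
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> TRMCall:
    """Apply the dominance rule to a ranked candidate list.

    No candidates -> absent; a sole candidate -> called; otherwise called
    iff best/second >= fold_threshold (the boundary counts), else ambiguous.
    """
    abundances = [a for _, a in candidates]
    if abundances != sorted(abundances, reverse=True):
        raise ValueError("candidates must be sorted by abundance, descending")
    cands = tuple((k, float(a)) for k, a in candidates)
    if not cands:
        return TRMCall(
            status="absent", motif=None, fold_ratio=math.inf,
            note="no motif passed the candidate criteria",
        )
    if len(cands) == 1:
        return TRMCall(
            status="called", motif=cands[0][0], fold_ratio=math.inf,
            candidates=cands, note="single candidate",
        )
    best, second = cands[0][1], cands[1][1]
    fold = best / second if second > 0 else math.inf
    if fold >= fold_threshold:
        return TRMCall(
            status="called", motif=cands[0][0], fold_ratio=fold, candidates=cands,
            note=f"best/second = {fold:.4g} >= {fold_threshold:g}",
        )
    return TRMCall(
        status="ambiguous", motif=cands[0][0], fold_ratio=fold, candidates=cands,
        note=(
            f"best/second = {fold:.4g} < {fold_threshold:g}; "
            "external evidence (e.g. assembly terminus scan) needed"
        ),
    )


def _fmt_fold(v: float) -> str:
    return "inf" if math.isinf(v) else f"{v:.6g}"


def write_call_tsv(call: TRMCall, handle: IO[str]) -> None:
    """Emit the verdict record plus the ranked candidate table."""
    handle.write("status\tcanonical\tdisplay\tfold_ratio\tn_candidates\n")
    canon = call.motif.canonical if call.motif else "."
    disp = call.motif.display if call.motif else "."
    handle.write(
        f"{call.status}\t{canon}\t{disp}\t{_fmt_fold(call.fold_ratio)}\t{len(call.candidates)}\n"
    )
    handle.write("# note: " + call.note + "\n")
    handle.write("rank\tcanonical\tdisplay\tabundance\n")
    for i, (key, abundance) in enumerate(call.candidates, start=1):
        handle.write(f"{i}\t{key.canonical}\t{key.display}\t{abundance:.6g}\n")
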