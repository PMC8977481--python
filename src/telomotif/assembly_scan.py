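"""Telomeric-array detection at scaffold termini of a genome assembly.

Chromosome-level assemblies validate a motif call directly: the called
repeat should form arrays at (most) scaffold ends. Each scaffold's first
and last ``window_bp`` are scanned with the exact tandem-run detector and
arrays close enough to the end (``max_terminal_gap``) are reported.
Matching is by canonical key, so a 5' terminus carrying the C-rich strand
on the forward sequence matches the same motif as a 3' G-rich array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from .repeat_core import (
    DEFAULT_MAX_UNIT,
    DEFAULT_MIN_COPIES,
    DEFAULT_MIN_UNIT,
    MotifKey,
    RepeatRun,
    canonical_key,
    find_tandem_runs,
)

FIVE_PRIME = "5prime"
THREE_PRIME = "3prime"


@dataclass(frozen=True)
class TerminalArray:
    """One tandem array detected at a scaffold terminus."""

    scaffold_id: str
    terminus: str  # FIVE_PRIME or THREE_PRIME
    motif: MotifKey
    array_length_bp: int
    full_copies: int
    distance_from_terminus_bp: int


def _terminus_arrays(
    scaffold_id: str,
    window: str,
    terminus: str,
    scaffold_len: int,
    window_offset: int,
    motif: MotifKey | None,
    min_array_bp: int,
    max_terminal_gap: int,
    min_unit: int,
    max_unit: int,
    min_copies: int,
    key_cache: dict[str, MotifKey],
) -> list[TerminalArray]:
    runs = find_tandem_runs(
        window, sequence_id=scaffold_id,
        min_unit=min_unit, max_unit=max_unit,
        min_copies=min_copies, min_run_bp=min_array_bp,
    )
    hits: list[tuple[MotifKey, RepeatRun, int]] = []
    for run in runs:
        if terminus == FIVE_PRIME:
            dist = window_offset + run.start
        else:
            dist = scaffold_len - (window_offset + run.end)
        if dist > max_terminal_gap:
            continue
        mk = key_cache.get(run.unit)
        if mk is None:
            mk = key_cache[run.unit] = canonical_key(run.unit)
        if motif is not None and mk.canonical != motif.canonical:
            continue
        hits.append((mk, run, dist))
    if motif is None and hits:
        # no motif given: keep only the dominant (most array bp) motif
        totals: dict[str, int] = {}
        for mk, run, _ in hits:
            totals[mk.canonical] = totals.get(mk.canonical, 0) + run.matched_length_bp
        dominant = max(totals.items(), key=lambda kv: (kv[1], kv[0]))[0]
        hits = [h for h in hits if h[0].canonical == dominant]
    return [
        TerminalArray(
            scaffold_id=scaffold_id,
            terminus=terminus,
            motif=mk,
            array_length_bp=run.matched_length_bp,
            full_copies=run.full_copies,
            distance_from_terminus_bp=dist,
        )
        for mk, run, dist in hits
    ]


def scan_scaffold_ends(
    scaffold: tuple[str, str],
    *,
    window_bp: int = 10_000,
    motif: MotifKey | None = None,
    min_array_bp: int = 100,
    max_terminal_gap: int = 1_000,
    min_unit: int = DEFAULT_MIN_UNIT,
    max_unit: int = DEFAULT_MAX_UNIT,
    min_copies: int = DEFAULT_MIN_COPIES,
) -> list[TerminalArray]:
    """Detect qualifying tandem arrays at both termini of one scaffold.

    With ``motif`` given, only arrays of that canonical key are reported;
    otherwise the dominant (longest-array) motif per terminus is reported.
    """
    scaffold_id, seq = scaffold
    seq = seq.upper()
    n = len(seq)
    if n < 2:
        raise ValueError(f"scaffold {scaffold_id!r} shorter than 2 bp")
    w = min(window_bp, n)
    cache: dict[str, MotifKey] = {}
    out = _terminus_arrays(
        scaffold_id, seq[:w], FIVE_PRIME, n, 0, motif,
        min_array_bp, max_terminal_gap, min_unit, max_unit, min_copies, cache,
    )
    out += _terminus_arrays(
        scaffold_id, seq[n - w:], THREE_PRIME, n, n - w, motif,
        min_array_bp, max_terminal_gap, min_unit, max_unit, min_copies, cache,
    )
    return out


@dataclass
class AssemblyReport:
    """Per-terminus arrays plus the totals an assembly-validation table shows."""

    arrays: list[TerminalArray] = field(default_factory=list)
    n_scaffolds: int = 0
    n_termini: int = 0
    n_termini_with_array: int = 0
    total_array_bp: int = 0

    def summary_line(self) -> str:
        return (
            f"termini_with_array\t{self.n_termini_with_array}/{self.n_termini}"
            f"\ttotal_array_bp\t{self.total_array_bp}"
        )


def summarize_assembly(
    scaffolds: Iterable[tuple[str, str]],
    *,
    motif: MotifKey | None = None,
    window_bp: int = 10_000,
    min_array_bp: int = 100,
    max_terminal_gap: int = 1_000,
    min_unit: int = DEFAULT_MIN_UNIT,
    max_unit: int = DEFAULT_MAX_UNIT,
    min_copies: int = DEFAULT_MIN_COPIES,
) -> AssemblyReport:
    """Scan every scaffold end and tally how many termini carry an array."""
    report = AssemblyReport()
    occupied: set[tuple[str, str]] = set()
    for scaffold in scaffolds:
        report.n_scaffolds += 1
        report.n_termini += 2
        arrays = scan_scaffold_ends(
            scaffold, window_bp=window_bp, motif=motif,
            min_array_bp=min_array_bp, max_terminal_gap=max_terminal_gap,
            min_unit=min_unit, max_unit=max_unit, min_copies=min_copies,
        )
        report.arrays.extend(arrays)
        for arr in arrays:
            occupied.add((arr.scaffold_id, arr.terminus))
            report.total_array_bp += arr.array_length_bp
    if report.n_scaffolds == 0:
        raise ValueError("assembly contains no scaffolds")
    report.n_termini_with_array = len(occupied)
    return report


def write_report_tsv(report: AssemblyReport, handle: IO[str]) -> None:
    handle.write(
        "scaffold_id\tterminus\tcanonical\tdisplay\tarray_length_bp"
        "\tfull_copies\tdistance_from_terminus_bp\n"
    )
    for a in report.arrays:
        handle.write(
            f"{a.scaffold_id}\t{a.terminus}\t{a.motif.canonical}\t{a.motif.display}"
            f"\t{a.array_length_bp}\t{a.full_copies}\t{a.distance_from_terminus_bp}\n"
        )
    handle.write("# " + report.summary_line() + "\n")
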