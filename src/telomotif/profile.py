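"""Per-motif abundance statistics over a whole read set.

Aggregates the detector's tandem-repeat runs across all reads into one
19-statistic record per canonical motif, with optional coverage
normalization ("total repeat length per 1x haploid genome"). The profile is
built in a single streaming pass and supports exact chunk-wise merging, so
results are independent of how the read stream is split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import IO, Iterable, Iterator, Sequence

from .repeat_core import (
    DEFAULT_MAX_UNIT,
    DEFAULT_MIN_COPIES,
    DEFAULT_MIN_RUN_BP,
    DEFAULT_MIN_UNIT,
    MotifKey,
    RepeatRun,
    canonical_key,
    find_tandem_runs_batch,
)

DEFAULT_PURE_READ_FRACTION = 0.9

#: The 19 per-motif summary statistics, in output order. The first five
#: named in the main calling criteria are: n_reads_with_repeat,
#: total_repeat_length_bp, pct_repeat_of_read_bases,
#: total_repeat_length_per_1x and mean_copies_per_run.
STAT_FIELDS: tuple[str, ...] = (
    "unit_length",
    "n_reads_with_repeat",
    "n_runs",
    "total_copies",
    "total_repeat_length_bp",
    "total_repeat_length_per_1x",
    "pct_repeat_of_read_bases",
    "mean_copies_per_run",
    "max_copies_per_run",
    "mean_runs_per_read",
    "mean_run_length_bp",
    "max_run_length_bp",
    "mean_read_fraction_covered",
    "n_pure_reads",
    "unit_gc_fraction",
    "display_trailing_g_run",
    "share_of_total_repeat_bp",
    "rank_by_total_repeat_length",
    "fold_ratio_to_next",
)


@dataclass(frozen=True)
class DetectorParams:
    min_unit: int = DEFAULT_MIN_UNIT
    max_unit: int = DEFAULT_MAX_UNIT
    min_copies: int = DEFAULT_MIN_COPIES
    min_run_bp: int = DEFAULT_MIN_RUN_BP
    pure_read_fraction: float = DEFAULT_PURE_READ_FRACTION


@dataclass
class MotifAccumulator:
    """Raw mergeable per-motif tallies (sums and maxima only)."""

    n_reads: int = 0
    n_runs: int = 0
    total_copies: int = 0
    covered_bp: int = 0  # per-read union of run intervals, summed over reads
    run_bp: int = 0  # sum of matched_length_bp over runs
    max_copies: int = 0
    max_run_bp: int = 0
    # exact rational so chunked merges reproduce single-pass results bit-for-bit
    sum_read_fraction: Fraction = Fraction(0)
    n_pure: int = 0

    def merge(self, other: "MotifAccumulator") -> None:
        self.n_reads += other.n_reads
        self.n_runs += other.n_runs
        self.total_copies += other.total_copies
        self.covered_bp += other.covered_bp
        self.run_bp += other.run_bp
        self.max_copies = max(self.max_copies, other.max_copies)
        self.max_run_bp = max(self.max_run_bp, other.max_run_bp)
        self.sum_read_fraction += other.sum_read_fraction
        self.n_pure += other.n_pure


@dataclass
class DatasetProfile:
    """Whole-dataset repeat profile: global counters plus per-motif tallies.

    ``coverage`` is the explicitly supplied fold coverage (or None);
    ``effective_coverage`` falls back to total_read_bases / genome_size.
    """

    params: DetectorParams = field(default_factory=DetectorParams)
    genome_size: int | None = None
    coverage: float | None = None
    total_reads: int = 0
    total_read_bases: int = 0
    per_motif: dict[str, MotifAccumulator] = field(default_factory=dict)
    display: dict[str, str] = field(default_factory=dict)

    @property
    def effective_coverage(self) -> float | None:
        if self.coverage is not None:
            return self.coverage
        if self.genome_size is not None and self.total_read_bases > 0:
            return self.total_read_bases / self.genome_size
        return None


def _union_length(intervals: list[tuple[int, int]]) -> int:
    intervals.sort()
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        elif e > cur_e:
            cur_e = e
    return total + (cur_e - cur_s)


def _accumulate_read(
    profile: DatasetProfile,
    read_len: int,
    runs: list[RepeatRun],
    key_cache: dict[str, MotifKey],
) -> None:
    by_motif: dict[str, list[RepeatRun]] = {}
    for run in runs:
        mk = key_cache.get(run.unit)
        if mk is None:
            mk = canonical_key(run.unit)
            key_cache[run.unit] = mk
        by_motif.setdefault(mk.canonical, []).append(run)
        if mk.canonical not in profile.display:
            profile.display[mk.canonical] = mk.display
    pure_cut = profile.params.pure_read_fraction
    for canon, motif_runs in by_motif.items():
        acc = profile.per_motif.get(canon)
        if acc is None:
            acc = profile.per_motif[canon] = MotifAccumulator()
        covered = _union_length([(r.start, r.end) for r in motif_runs])
        frac = Fraction(covered, read_len)
        acc.n_reads += 1
        acc.n_runs += len(motif_runs)
        acc.total_copies += sum(r.full_copies for r in motif_runs)
        acc.covered_bp += covered
        acc.run_bp += sum(r.matched_length_bp for r in motif_runs)
        acc.max_copies = max(acc.max_copies, max(r.full_copies for r in motif_runs))
        acc.max_run_bp = max(acc.max_run_bp, max(r.matched_length_bp for r in motif_runs))
        acc.sum_read_fraction += frac
        acc.n_pure += frac >= pure_cut


def profile_reads(
    read_stream: Iterable[tuple[str, str]],
    *,
    min_unit: int = DEFAULT_MIN_UNIT,
    max_unit: int = DEFAULT_MAX_UNIT,
    min_copies: int = DEFAULT_MIN_COPIES,
    min_run_bp: int = DEFAULT_MIN_RUN_BP,
    pure_read_fraction: float = DEFAULT_PURE_READ_FRACTION,
    genome_size: int | None = None,
    coverage: float | None = None,
    chunk_bases: int = 4_000_000,
) -> DatasetProfile:
    """Single-pass repeat profiling of a stream of (read_id, bases) pairs.

    Exactly one of ``genome_size`` / ``coverage`` may be supplied for
    normalization; with neither, only raw counts are produced and the
    per-1x statistic is reported as NA.
    """
    if genome_size is not None and coverage is not None:
        raise ValueError("supply at most one of genome_size and coverage")
    if genome_size is not None and genome_size <= 0:
        raise ValueError(f"genome_size must be positive, got {genome_size}")
    if coverage is not None and coverage <= 0:
        raise ValueError(f"coverage must be positive, got {coverage}")
    params = DetectorParams(min_unit, max_unit, min_copies, min_run_bp, pure_read_fraction)
    profile = DatasetProfile(params=params, genome_size=genome_size, coverage=coverage)
    key_cache: dict[str, MotifKey] = {}

    batch: list[tuple[str, str]] = []
    batch_bases = 0

    def flush() -> None:
        nonlocal batch, batch_bases
        if not batch:
            return
        runs_per_read = find_tandem_runs_batch(
            batch, min_unit=min_unit, max_unit=max_unit,
            min_copies=min_copies, min_run_bp=min_run_bp,
        )
        for (_, bases), runs in zip(batch, runs_per_read):
            if runs:
                _accumulate_read(profile, len(bases), runs, key_cache)
        batch = []
        batch_bases = 0

    for rid, bases in read_stream:
        profile.total_reads += 1
        profile.total_read_bases += len(bases)
        batch.append((rid, bases))
        batch_bases += len(bases)
        if batch_bases >= chunk_bases:
            flush()
    flush()

    if profile.total_read_bases == 0:
        raise ValueError("read stream contains no bases")
    return profile


def merge_profiles(a: DatasetProfile, b: DatasetProfile) -> DatasetProfile:
    """Combine two profiles built with identical parameters (commutative, associative)."""
    if a.params != b.params:
        raise ValueError(f"detector parameter mismatch: {a.params} != {b.params}")
    if a.genome_size != b.genome_size or a.coverage != b.coverage:
        raise ValueError("normalization settings differ between profiles")
    out = DatasetProfile(
        params=a.params,
        genome_size=a.genome_size,
        coverage=a.coverage,
        total_reads=a.total_reads + b.total_reads,
        total_read_bases=a.total_read_bases + b.total_read_bases,
    )
    for src in (a, b):
        for canon, acc in src.per_motif.items():
            tgt = out.per_motif.get(canon)
            if tgt is None:
                out.per_motif[canon] = replace(acc)
            else:
                tgt.merge(acc)
        out.display.update(src.display)
    return out


@dataclass(frozen=True)
class MotifStats:
    """One motif's row of the summary table: labels plus 19 statistics."""

    canonical: str
    display: str
    unit_length: int
    n_reads_with_repeat: int
    n_runs: int
    total_copies: int
    total_repeat_length_bp: int
    total_repeat_length_per_1x: float
    pct_repeat_of_read_bases: float
    mean_copies_per_run: float
    max_copies_per_run: int
    mean_runs_per_read: float
    mean_run_length_bp: float
    max_run_length_bp: int
    mean_read_fraction_covered: float
    n_pure_reads: int
    unit_gc_fraction: float
    display_trailing_g_run: int
    share_of_total_repeat_bp: float
    rank_by_total_repeat_length: int
    fold_ratio_to_next: float


def motif_statistics(profile: DatasetProfile) -> list[MotifStats]:
    """Finalize a profile into ranked per-motif statistics (rank 1 = most repeat bp)."""
    if not profile.per_motif:
        return []
    cov = profile.effective_coverage
    order = sorted(
        profile.per_motif.items(), key=lambda kv: (-kv[1].covered_bp, kv[0])
    )
    grand_total = sum(acc.covered_bp for _, acc in order)
    rows: list[MotifStats] = []
    for rank, (canon, acc) in enumerate(order, start=1):
        if rank < len(order):
            nxt = order[rank][1].covered_bp
            fold = acc.covered_bp / nxt if nxt else math.inf
        else:
            fold = math.inf
        disp = profile.display[canon]
        rows.append(
            MotifStats(
                canonical=canon,
                display=disp,
                unit_length=len(canon),
                n_reads_with_repeat=acc.n_reads,
                n_runs=acc.n_runs,
                total_copies=acc.total_copies,
                total_repeat_length_bp=acc.covered_bp,
                total_repeat_length_per_1x=(acc.covered_bp / cov) if cov else math.nan,
                pct_repeat_of_read_bases=100.0 * acc.covered_bp / profile.total_read_bases,
                mean_copies_per_run=acc.total_copies / acc.n_runs,
                max_copies_per_run=acc.max_copies,
                mean_runs_per_read=acc.n_runs / acc.n_reads,
                mean_run_length_bp=acc.run_bp / acc.n_runs,
                max_run_length_bp=acc.max_run_bp,
                mean_read_fraction_covered=float(acc.sum_read_fraction / acc.n_reads),
                n_pure_reads=acc.n_pure,
                unit_gc_fraction=(canon.count("G") + canon.count("C")) / len(canon),
                display_trailing_g_run=len(disp) - len(disp.rstrip("G")),
                share_of_total_repeat_bp=acc.covered_bp / grand_total,
                rank_by_total_repeat_length=rank,
                fold_ratio_to_next=fold,
            )
        )
    return rows


def _fmt(v) -> str:
    if isinstance(v, bool):  # defensive: bools are ints
        return str(int(v))
    if isinstance(v, int):
        return str(v)
    if isinstance(v, float):
        if math.isnan(v):
            return "NA"
        if math.isinf(v):
            return "inf"
        return f"{v:.6g}"
    return str(v)


def write_stats_tsv(stats: Sequence[MotifStats], handle: IO[str]) -> None:
    """Write the per-motif table as TSV: canonical, display, then the 19 statistics."""
    handle.write("canonical\tdisplay\t" + "\t".join(STAT_FIELDS) + "\n")
    for row in stats:
        values = [getattr(row, f) for f in STAT_FIELDS]
        handle.write(row.canonical + "\t" + row.display + "\t" + "\t".join(map(_fmt, values)) + "\n")


_INT_FIELDS = {
    "unit_length", "n_reads_with_repeat", "n_runs", "total_copies",
    "total_repeat_length_bp", "max_copies_per_run", "max_run_length_bp",
    "n_pure_reads", "display_trailing_g_run", "rank_by_total_repeat_length",
}


def read_stats_tsv(handle: IO[str]) -> list[MotifStats]:
    """Parse a table written by :func:`write_stats_tsv` back into MotifStats rows."""
    header = handle.readline().rstrip("\n").split("\t")
    expected = ["canonical", "display", *STAT_FIELDS]
    if header != expected:
        raise ValueError("unrecognized profile table header")
    rows = []
    for line in handle:
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        kw = {"canonical": parts[0], "display": parts[1]}
        for name, raw in zip(STAT_FIELDS, parts[2:]):
            if name in _INT_FIELDS:
                kw[name] = int(raw)
            elif raw == "NA":
                kw[name] = math.nan
            elif raw == "inf":
                kw[name] = math.inf
            else:
                kw[name] = float(raw)
        rows.append(MotifStats(**kw))
    return rows
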