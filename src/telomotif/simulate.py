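"""Synthetic genomes with planted telomeric arrays, plus read simulation.

Every chromosome is built as ``[revcomp(motif) array] + random core +
[motif array]``: with a G-rich motif the 3' terminus carries the G-strand
and the 5' terminus carries the C-rich strand on the forward sequence,
matching the biological orientation of telomeres. Interstitial
microsatellites can be planted away from the termini as negative-control
material. Reads are sampled uniformly from both strands with an optional
substitution-only error model, and full ground truth (telomere intervals,
interstitial sites, per-read origins) is recorded so downstream modules can
be validated against planted facts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np

from .repeat_core import MotifKey, canonical_key, primitive_root, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of a simulated genome with planted telomeric arrays."""

    n_chromosomes: int = 5
    chromosome_length_bp: int = 100_000
    telomere_motif: str | None = "TTAGG"  # display-form (G-rich) unit; None = no arrays
    telomere_length_bp: int | tuple[int, int] = 5_000  # fixed bp, or uniform (lo, hi) per end
    interstitial_repeats: tuple[tuple[str, int, int], ...] = ()  # (unit, copies, n_sites)
    terminal_buffer_bp: int = 10_000  # interstitial sites are kept this far from termini
    seed: int = 0


@dataclass(frozen=True)
class ReadSpec:
    """Short-read library parameters (75-250 bp reads)."""

    read_length_bp: int = 100
    coverage: float = 30.0
    paired: bool = False
    insert_mean_bp: float = 400.0
    insert_sd_bp: float = 40.0
    substitution_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (75 <= self.read_length_bp <= 250):
            raise ValueError("read_length_bp must be in [75, 250]")
        if not (0 <= self.substitution_error_rate < 1):
            raise ValueError("substitution_error_rate must be in [0, 1)")


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    label: str  # "5prime"/"3prime" for telomeres; unit string for interstitials


@dataclass(frozen=True)
class ReadOrigin:
    read_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"


@dataclass
class SyntheticTruth:
    """Ground truth bookkeeping for one simulated dataset."""

    genome_size: int = 0
    chromosome_lengths: dict[str, int] = field(default_factory=dict)
    motif: MotifKey | None = None
    telomeres: list[Interval] = field(default_factory=list)
    interstitial: list[Interval] = field(default_factory=list)
    reads: list[ReadOrigin] = field(default_factory=list)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def _tile(unit: str, length: int) -> str:
    return (unit * (length // len(unit) + 1))[:length]


def _tel_len(rng: np.random.Generator, spec: GenomeSpec) -> int:
    if isinstance(spec.telomere_length_bp, tuple):
        lo, hi = spec.telomere_length_bp
        return int(rng.integers(lo, hi + 1))
    return int(spec.telomere_length_bp)


def simulate_genome(spec: GenomeSpec) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Build FASTA-ready scaffolds and their ground truth; reproducible from seed."""
    rng = np.random.default_rng(spec.seed)
    truth = SyntheticTruth()
    motif_key = None
    g_unit = None
    if spec.telomere_motif is not None:
        g_unit = spec.telomere_motif.upper()
        if primitive_root(g_unit) != g_unit:
            raise ValueError(f"telomere motif must be primitive: {spec.telomere_motif!r}")
        motif_key = canonical_key(g_unit)
    truth.motif = motif_key

    for unit, copies, n_sites in spec.interstitial_repeats:
        u = unit.upper()
        if primitive_root(u) != u:
            raise ValueError(f"interstitial unit must be primitive: {unit!r}")
        if copies < 1 or n_sites < 1:
            raise ValueError("interstitial copies and site counts must be positive")

    genome: list[tuple[str, str]] = []
    chrom_arrays: dict[str, np.ndarray] = {}
    for ci in range(spec.n_chromosomes):
        name = f"chr{ci + 1}"
        clen = spec.chromosome_length_bp
        if g_unit is not None:
            l5, l3 = _tel_len(rng, spec), _tel_len(rng, spec)
        else:
            l5 = l3 = 0
        core_len = clen - l5 - l3
        if core_len < 0:
            raise ValueError(
                f"telomeres ({l5}+{l3} bp) longer than chromosome ({clen} bp)"
            )
        left = _tile(reverse_complement(g_unit), l5) if l5 else ""
        right = _tile(g_unit, l3) if l3 else ""
        seq = left + _random_dna(rng, core_len) + right
        chrom_arrays[name] = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        truth.chromosome_lengths[name] = clen
        if l5:
            truth.telomeres.append(Interval(name, 0, l5, "5prime"))
        if l3:
            truth.telomeres.append(Interval(name, clen - l3, clen, "3prime"))

    truth.genome_size = sum(truth.chromosome_lengths.values())

    # plant interstitial arrays inside cores, away from both termini
    names = sorted(chrom_arrays)
    planted: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    for unit, copies, n_sites in spec.interstitial_repeats:
        u = unit.upper()
        arr_len = len(u) * copies
        for _ in range(n_sites):
            for _attempt in range(1000):
                name = names[int(rng.integers(len(names)))]
                clen = truth.chromosome_lengths[name]
                tel5 = next((t.end for t in truth.telomeres if t.chrom == name and t.label == "5prime"), 0)
                tel3 = next((t.start for t in truth.telomeres if t.chrom == name and t.label == "3prime"), clen)
                lo = max(tel5, spec.terminal_buffer_bp)
                hi = min(tel3, clen - spec.terminal_buffer_bp) - arr_len
                if hi <= lo:
                    continue
                pos = int(rng.integers(lo, hi))
                if any(pos < e and pos + arr_len > s for s, e in planted[name]):
                    continue
                chrom_arrays[name][pos : pos + arr_len] = np.frombuffer(
                    (u * copies).encode(), dtype=np.uint8
                )
                planted[name].append((pos, pos + arr_len))
                truth.interstitial.append(Interval(name, pos, pos + arr_len, u))
                break
            else:
                raise ValueError(
                    "could not place interstitial array; chromosome too small "
                    "for the requested terminal buffer"
                )

    for name in truth.chromosome_lengths:
        genome.append((name, chrom_arrays[name].tobytes().decode("ascii")))
    return genome, truth


def _apply_errors(rng: np.random.Generator, read: str, rate: float) -> str:
    if rate <= 0:
        return read
    n_err = int(rng.binomial(len(read), rate))
    if n_err == 0:
        return read
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(read), size=n_err, replace=False)
    # substitute with one of the three other bases
    for p in pos:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = choices[int(rng.integers(3))]
    return arr.tobytes().decode("ascii")


def simulate_reads(
    genome: Sequence[tuple[str, str]],
    truth: SyntheticTruth,
    spec: ReadSpec,
) -> tuple[list[tuple], SyntheticTruth]:
    """Sample a read library from a simulated genome, extending its truth.

    Single-end mode returns (read_id, bases) tuples; paired mode returns
    (pair_id, mate1, mate2), with mates on opposite strands of fragments
    whose size is drawn from Normal(insert_mean_bp, insert_sd_bp). Read
    count is round(coverage x genome_bp / read_length) (pairs count two
    reads). Substitution errors only.
    """
    rl = spec.read_length_bp
    seqs = {name: seq for name, seq in genome}
    lengths = {name: len(seq) for name, seq in genome}
    if min(lengths.values()) < rl:
        raise ValueError("read length exceeds the shortest chromosome")
    genome_bp = sum(lengths.values())
    rng = np.random.default_rng(spec.seed)
    names = [name for name, _ in genome]
    rate = spec.substitution_error_rate

    if not spec.paired:
        n_reads = round(spec.coverage * genome_bp / rl)
        n_pos = np.array([lengths[n] - rl + 1 for n in names], dtype=np.int64)
        cum = np.cumsum(n_pos)
        u = rng.integers(0, int(cum[-1]), size=n_reads)
        chrom_idx = np.searchsorted(cum, u, side="right")
        local = u - (cum[chrom_idx] - n_pos[chrom_idx])
        strands = rng.integers(0, 2, size=n_reads)
        reads = []
        for i in range(n_reads):
            name = names[int(chrom_idx[i])]
            s = int(local[i])
            frag = seqs[name][s : s + rl]
            strand = "+" if strands[i] == 0 else "-"
            bases = frag if strand == "+" else reverse_complement(frag)
            bases = _apply_errors(rng, bases, rate)
            rid = f"r{i:07d}"
            reads.append((rid, bases))
            truth.reads.append(ReadOrigin(rid, name, s, s + rl, strand))
        return reads, truth

    n_pairs = round(spec.coverage * genome_bp / (2 * rl))
    weights = np.array([lengths[n] for n in names], dtype=float)
    weights /= weights.sum()
    chrom_idx = rng.choice(len(names), size=n_pairs, p=weights)
    inserts = rng.normal(spec.insert_mean_bp, spec.insert_sd_bp, size=n_pairs)
    strands = rng.integers(0, 2, size=n_pairs)
    pairs = []
    for i in range(n_pairs):
        name = names[int(chrom_idx[i])]
        clen = lengths[name]
        ins = int(round(inserts[i]))
        ins = max(rl, min(ins, clen))
        s = int(rng.integers(0, clen - ins + 1))
        e = s + ins
        left = seqs[name][s : s + rl]
        right = reverse_complement(seqs[name][e - rl : e])
        if strands[i] == 0:
            m1, m2 = left, right
            o1 = ReadOrigin(f"p{i:07d}/1", name, s, s + rl, "+")
            o2 = ReadOrigin(f"p{i:07d}/2", name, e - rl, e, "-")
        else:
            m1, m2 = right, left
            o1 = ReadOrigin(f"p{i:07d}/1", name, e - rl, e, "-")
            o2 = ReadOrigin(f"p{i:07d}/2", name, s, s + rl, "+")
        m1 = _apply_errors(rng, m1, rate)
        m2 = _apply_errors(rng, m2, rate)
        pairs.append((f"p{i:07d}", m1, m2))
        truth.reads.extend((o1, o2))
    return pairs, truth


# ---------------------------------------------------------------------------
# truth serialization (plain TSV; round-trips exactly)

def write_truth(truth: SyntheticTruth, handle: IO[str]) -> None:
    handle.write(f"#genome_size\t{truth.genome_size}\n")
    if truth.motif is not None:
        handle.write(f"#motif\t{truth.motif.canonical}\t{truth.motif.display}\n")
    for name, clen in truth.chromosome_lengths.items():
        handle.write(f"chromosome\t{name}\t{clen}\t.\t.\n")
    for iv in truth.telomeres:
        handle.write(f"telomere\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")
    for iv in truth.interstitial:
        handle.write(f"interstitial\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")
    for ro in truth.reads:
        handle.write(f"read\t{ro.read_id}\t{ro.chrom}\t{ro.start}\t{ro.end}\t{ro.strand}\n")


def read_truth(handle: IO[str]) -> SyntheticTruth:
    truth = SyntheticTruth()
    for line in handle:
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if parts[0] == "#genome_size":
            truth.genome_size = int(parts[1])
        elif parts[0] == "#motif":
            truth.motif = canonical_key(parts[1])
        elif parts[0] == "chromosome":
            truth.chromosome_lengths[parts[1]] = int(parts[2])
        elif parts[0] == "telomere":
            truth.telomeres.append(Interval(parts[1], int(parts[2]), int(parts[3]), parts[4]))
        elif parts[0] == "interstitial":
            truth.interstitial.append(Interval(parts[1], int(parts[2]), int(parts[3]), parts[4]))
        elif parts[0] == "read":
            truth.reads.append(ReadOrigin(parts[1], parts[2], int(parts[3]), int(parts[4]), parts[5]))
        else:
            raise ValueError(f"unrecognized truth record: {parts[0]!r}")
    return truth
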