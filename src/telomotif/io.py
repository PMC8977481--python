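"""FASTQ/FASTA reading and writing (plain or gzip) via Biopython."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

from Bio import SeqIO


class InputFormatError(ValueError):
    """Raised for malformed sequence files, naming the file and record index."""


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a text file, transparently decompressing ``.gz``."""
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, mode)
    return open(p, mode)


def _parse(path: str | Path, fmt: str) -> Iterator[tuple[str, str]]:
    idx = 0
    try:
        with open_text(path) as handle:
            for record in SeqIO.parse(handle, fmt):
                idx += 1
                yield record.id, str(record.seq).upper()
    except (ValueError, OSError) as exc:
        raise InputFormatError(
            f"{path}: malformed {fmt.upper()} near record {idx + 1}: {exc}"
        ) from exc


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Iterate (read_id, bases) from a FASTQ(.gz) file; qualities are ignored."""
    return _parse(path, "fastq")


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Iterate (sequence_id, bases) from a FASTA(.gz) file."""
    return _parse(path, "fasta")


def _strip_mate(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[tuple[str, str, str]]:
    """Iterate (pair_id, mate1, mate2) from two parallel FASTQ(.gz) files."""
    it1, it2 = read_fastq(path1), read_fastq(path2)
    for rec1 in it1:
        rec2 = next(it2, None)
        if rec2 is None:
            raise InputFormatError(f"{path2}: fewer records than {path1}")
        yield _strip_mate(rec1[0]), rec1[1], rec2[1]
    if next(it2, None) is not None:
        raise InputFormatError(f"{path1}: fewer records than {path2}")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open_text(path, "wt") as handle:
        for rid, seq in records:
            handle.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path, qual_char: str = "I") -> None:
    with open_text(path, "wt") as handle:
        for rid, seq in records:
            handle.write(f"@{rid}\n{seq}\n+\n{qual_char * len(seq)}\n")


def write_fastq_pairs(
    pairs: Sequence[tuple[str, str, str]],
    path1: str | Path,
    path2: str | Path,
    qual_char: str = "I",
) -> None:
    write_fastq(((pid + "/1", m1) for pid, m1, _ in pairs), path1, qual_char)
    write_fastq(((pid + "/2", m2) for pid, _, m2 in pairs), path2, qual_char)
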