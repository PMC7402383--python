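"""FASTQ/FASTA input-output and seeded reservoir sampling of reads.

Reads are held as :class:`ReadRecord` (identifier, bases, integer Phred
scores); assembled scaffolds as :class:`ScaffoldRecord`. Quality strings are
decoded with a fixed Phred+33 offset. Gzip-compressed files are accepted
transparently by extension.
"""

from __future__ import annotations

import gzip
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
#: Highest Phred score representable in printable Sanger encoding.
PHRED_MAX = 93


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: identifier, bases and per-base Phred scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.bases)} "
                f"!= quality length {len(self.quals)}"
            )
        if self.quals and not (0 <= min(self.quals) and max(self.quals) <= PHRED_MAX):
            raise ValueError(f"read {self.read_id!r}: Phred score outside [0, {PHRED_MAX}]")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def qual_array(self) -> np.ndarray:
        return np.asarray(self.quals, dtype=np.int16)


@dataclass(frozen=True)
class ScaffoldRecord:
    """One assembled scaffold; sequence is uppercased on input."""

    scaffold_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"scaffold {self.scaffold_id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def decode_quals(qual_string: str, offset: int = PHRED_OFFSET) -> tuple[int, ...]:
    """Decode a FASTQ quality string into integer Phred scores."""
    return tuple(ord(c) - offset for c in qual_string)


def encode_quals(quals: Sequence[int], offset: int = PHRED_OFFSET) -> str:
    return "".join(chr(q + offset) for q in quals)


def read_fastq(path: str | Path, offset: int = PHRED_OFFSET) -> Iterator[ReadRecord]:
    """Stream records from a 4-line FASTQ file (Phred+33 by default).

    Raises ``ValueError`` naming the record index on a malformed record.
    """
    with _open_text(path) as handle:
        index = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise ValueError("sequence/quality length mismatch")
                yield ReadRecord(title.split()[0], seq.upper(), decode_quals(qual, offset))
                index += 1
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {index} in {path}: {exc}") from exc


def write_fastq(records: Iterable[ReadRecord], path: str | Path,
                offset: int = PHRED_OFFSET) -> int:
    """Write records as 4-line FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f"@{rec.read_id}\n{rec.bases}\n+\n{encode_quals(rec.quals, offset)}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> Iterator[ScaffoldRecord]:
    """Stream scaffolds from a (multi-line) FASTA file, uppercased, in order."""
    with _open_text(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            yield ScaffoldRecord(title.split()[0], seq.upper())


def write_fasta(records: Iterable[ScaffoldRecord], path: str | Path, width: int = 70) -> int:
    n = 0
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.scaffold_id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i:i + width] + "\n")
            n += 1
    return n


def sample_reads(reads: Iterable[ReadRecord], n: int | None, seed: int = 0) -> list[ReadRecord]:
    """Draw ``min(n, population)`` distinct reads uniformly without replacement.

    Single-pass reservoir sampling (Algorithm R), so arbitrarily large FASTQ
    streams are handled in O(n) memory. ``n=None`` bypasses sampling and
    returns every read. Identical (input, n, seed) gives an identical sample.
    Output order is the reservoir's order, not the input order.
    """
    if n is None:
        return list(reads)
    if n <= 0:
        raise ValueError(f"sample size must be positive, got {n}")
    rng = random.Random(seed)
    reservoir: list[ReadRecord] = []
    for i, rec in enumerate(reads):
        if i < n:
            reservoir.append(rec)
        else:
            j = rng.randrange(i + 1)
            if j < n:
                reservoir[j] = rec
    return reservoir


DEFAULT_SAMPLE_SIZE = 1_000_000
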