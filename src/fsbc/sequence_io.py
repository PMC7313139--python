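"""Reading, dereplicating and filtering HT-SELEX sequence pools.

A pool is a single round of reads (typically the final SELEX round), assumed
already trimmed to the random region.  Reads are normalized to uppercase
DNA over the alphabet {A, C, G, T} (U is mapped to T), identical reads are
collapsed into (sequence, count) pairs, and the pool keeps the composition
and length statistics every downstream score needs: the total read count N,
the multiset of read lengths L_i and the per-base counts n_j, all weighted
by read multiplicity.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = ("A", "C", "G", "T")
_VALID = frozenset(ALPHABET)


class PoolError(ValueError):
    """Raised for unreadable inputs or pools with no surviving reads."""


@dataclass(frozen=True)
class SequencePool:
    """A dereplicated sequence pool.

    Attributes
    ----------
    records:
        Tuples ``(sequence, count)``; sequences are unique, uppercase over
        {A,C,G,T}, counts >= 1.
    """

    records: tuple[tuple[str, int], ...]
    _length_counts: Counter = field(init=False, repr=False, compare=False)
    _base_counts: Counter = field(init=False, repr=False, compare=False)
    _n_reads: int = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        length_counts: Counter = Counter()
        base_counts: Counter = Counter()
        for seq, count in self.records:
            if not seq or set(seq) - _VALID:
                raise PoolError(f"invalid sequence in pool: {seq!r}")
            if count < 1:
                raise PoolError(f"non-positive count for {seq!r}")
            if seq in seen:
                raise PoolError(f"duplicate sequence in pool: {seq!r}")
            seen.add(seq)
            length_counts[len(seq)] += count
            for base, n in Counter(seq).items():
                base_counts[base] += n * count
        object.__setattr__(self, "_length_counts", length_counts)
        object.__setattr__(self, "_base_counts", base_counts)
        object.__setattr__(self, "_n_reads", sum(c for _, c in self.records))

    @property
    def n_reads(self) -> int:
        """Total read count N (with multiplicity)."""
        return self._n_reads

    @property
    def n_unique(self) -> int:
        return len(self.records)

    @property
    def length_counts(self) -> dict[int, int]:
        """Read-length histogram {L: number of reads of length L}."""
        return dict(self._length_counts)

    @property
    def max_length(self) -> int:
        return max(self._length_counts)

    @property
    def base_counts(self) -> dict[str, int]:
        """n_j: occurrences of each base over all reads, with multiplicity."""
        return {b: self._base_counts.get(b, 0) for b in ALPHABET}

    @property
    def total_bases(self) -> int:
        """Sum_i L_i over all N reads."""
        return sum(length * c for length, c in self._length_counts.items())

    def sequences(self) -> Iterator[str]:
        return (seq for seq, _ in self.records)

    def to_fasta(self, path: str | Path) -> None:
        """Write the dereplicated pool; headers carry the count."""
        with open(path, "w") as fh:
            for i, (seq, count) in enumerate(self.records, start=1):
                fh.write(f">seq_{i:05d};count={count}\n{seq}\n")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sequence\tcount\tlength\n")
            for seq, count in self.records:
                fh.write(f"{seq}\t{count}\t{len(seq)}\n")


def pool_from_counts(counts: dict[str, int] | Iterable[tuple[str, int]]) -> SequencePool:
    """Build a pool directly from a sequence -> count mapping."""
    items = counts.items() if isinstance(counts, dict) else counts
    return SequencePool(tuple((s, c) for s, c in items))


def pool_from_reads(reads: Iterable[str]) -> SequencePool:
    """Dereplicate an iterable of already-normalized reads."""
    merged: Counter = Counter(reads)
    return SequencePool(tuple(merged.items()))


def normalize_read(raw: str) -> str | None:
    """Uppercase, map U->T; return None if any other non-ACGT character remains."""
    seq = raw.strip().upper().replace("U", "T")
    if not seq or set(seq) - _VALID:
        return None
    return seq


def _open_text(path: Path) -> TextIO:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: Path) -> str:
    stem = path.name[: -len(".gz")] if path.suffix == ".gz" else path.name
    ext = Path(stem).suffix.lower()
    if ext in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if ext in {".fq", ".fastq"}:
        return "fastq"
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise PoolError(f"cannot determine format of {path}")


def read_pool(
    path: str | Path,
    format: str = "auto",
    trim_left: int = 0,
    trim_right: int = 0,
) -> SequencePool:
    """Read a FASTA/FASTQ file (optionally gzipped) into a dereplicated pool.

    Reads containing characters outside {A,C,G,T,U} after uppercasing are
    dropped with a logged warning.  ``trim_left``/``trim_right`` remove fixed
    primer widths; the default is no trimming (reads are assumed pre-trimmed
    to the random region).  FASTQ qualities are ignored.

    Raises
    ------
    PoolError
        If the file is unreadable/empty or no reads survive normalization.
    """
    path = Path(path)
    if not path.exists():
        raise PoolError(f"input file not found: {path}")
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt not in {"fasta", "fastq"}:
        raise PoolError(f"unsupported format: {fmt!r}")

    merged: Counter = Counter()
    dropped = 0
    total = 0
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, fmt):
            total += 1
            raw = str(record.seq)
            if trim_left or trim_right:
                raw = raw[trim_left: len(raw) - trim_right if trim_right else None]
            seq = normalize_read(raw)
            if seq is None:
                dropped += 1
                continue
            merged[seq] += 1
    if dropped:
        logger.warning("dropped %d of %d reads with non-ACGT characters", dropped, total)
    if total == 0:
        raise PoolError(f"no sequence records in {path}")
    if not merged:
        raise PoolError("no reads survived normalization")
    return SequencePool(tuple(merged.items()))


def filter_by_frequency(pool: SequencePool, min_count: int) -> SequencePool:
    """Retain unique sequences with count >= min_count (inclusive cutoff).

    All pool statistics (N, lengths, base counts) are recomputed on the
    retained reads.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept = tuple((s, c) for s, c in pool.records if c >= min_count)
    if not kept:
        raise PoolError(f"no sequences with count >= {min_count}")
    return SequencePool(kept)
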