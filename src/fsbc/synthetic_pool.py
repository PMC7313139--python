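"""Synthetic HT-SELEX-like pools with known ground truth.

Emulates the features of a late-round SELEX pool that the string statistics
depend on: a large set of reads around a nominal random-region length with
a minority of off-length reads (roughly a fifth of reads deviate from the
expected length in real pools), a possibly skewed base composition, and one
or more planted motif strings — stand-ins for target binding regions —
overwriting a window of a controllable fraction of reads.  It does not
model PCR amplification dynamics, sequencing errors, or multi-round
selection trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import ALPHABET, SequencePool, pool_from_reads


@dataclass(frozen=True)
class PlantedMotif:
    string: str
    prevalence: float  # fraction of reads carrying the motif

    def __post_init__(self) -> None:
        if not self.string or set(self.string) - set(ALPHABET):
            raise ValueError(f"motif must be a non-empty ACGT string: {self.string!r}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence out of [0,1]: {self.prevalence}")


@dataclass(frozen=True)
class SyntheticPoolSpec:
    """Generative parameters for a synthetic pool.

    Motifs are mutually exclusive per read (their prevalences must sum to
    at most 1); each carrier read has the motif overwrite a uniformly
    chosen window.  ``off_length_fraction`` of reads get their length
    jittered by +-1..max_jitter nt (uniform over the nonzero offsets).
    """

    n_reads: int = 10_000
    nominal_length: int = 30
    off_length_fraction: float = 0.22
    max_jitter: int = 3
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motifs: tuple[PlantedMotif, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")
        if not 0.0 <= self.off_length_fraction <= 1.0:
            raise ValueError("off_length_fraction out of [0,1]")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        total_prev = sum(m.prevalence for m in self.motifs)
        if total_prev > 1.0 + 1e-12:
            raise ValueError("motif prevalences sum beyond 1")
        min_length = self.nominal_length - (self.max_jitter if self.off_length_fraction else 0)
        for m in self.motifs:
            if len(m.string) > min_length:
                raise ValueError(
                    f"motif {m.string!r} longer than the shortest possible read ({min_length})"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Which generated reads carry which motif, and where."""

    entries: tuple[tuple[str, str, int], ...]  # (read_id, motif, insert position)
    reads: dict[str, str] = field(compare=False)  # read_id -> sequence

    def carriers(self, motif: str) -> set[str]:
        """Distinct carrier sequences of a motif."""
        return {self.reads[rid] for rid, m, _ in self.entries if m == motif}

    def carrier_read_ids(self, motif: str) -> set[str]:
        return {rid for rid, m, _ in self.entries if m == motif}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tmotif\tinsert_position\n")
            for rid, motif, pos in self.entries:
                fh.write(f"{rid}\t{motif}\t{pos}\n")


def generate_pool(spec: SyntheticPoolSpec) -> tuple[SequencePool, GroundTruth]:
    """Draw a pool per the spec; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list(ALPHABET))
    p = np.asarray(spec.base_probs)

    lengths = np.full(spec.n_reads, spec.nominal_length, dtype=np.int64)
    off = rng.random(spec.n_reads) < spec.off_length_fraction
    if off.any():
        offsets = np.concatenate(
            [np.arange(-spec.max_jitter, 0), np.arange(1, spec.max_jitter + 1)]
        )
        lengths[off] += rng.choice(offsets, size=int(off.sum()))

    # per-read motif assignment: one categorical draw over motifs + "none"
    probs = [m.prevalence for m in spec.motifs]
    choice = rng.choice(
        len(spec.motifs) + 1,
        size=spec.n_reads,
        p=probs + [1.0 - sum(probs)],
    )

    reads: dict[str, str] = {}
    truth: list[tuple[str, str, int]] = []
    for i in range(spec.n_reads):
        L = int(lengths[i])
        seq = "".join(rng.choice(bases, size=L, p=p))
        rid = f"read_{i:06d}"
        k = int(choice[i])
        if k < len(spec.motifs):
            motif = spec.motifs[k].string
            pos = int(rng.integers(0, L - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
            truth.append((rid, motif, pos))
        reads[rid] = seq

    pool = pool_from_reads(reads.values())
    return pool, GroundTruth(entries=tuple(truth), reads=reads)


def write_reads_fasta(truth: GroundTruth, path: str | Path) -> None:
    """Write the generated reads (pre-dereplication) as FASTA."""
    with open(path, "w") as fh:
        for rid, seq in truth.reads.items():
            fh.write(f">{rid}\n{seq}\n")
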