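"""Length-normalized ranking of selected strings and greedy clustering.

Z-scores grow with string rarity, so raw Z is not comparable across string
lengths.  Within each length class of *selected* strings the Z-scores are
standardized,

    Z*_s = (Z_s - mu_|s|) / sigma_|s|,

with mu and sigma the sample mean and (n-1) standard deviation of that
class.  Strings are ranked by Z* and clusters are extracted greedily: the
rank-1 string claims every remaining sequence containing it, the claimed
sequences are removed, and the process repeats.  Extractions that find no
remaining sequence do not consume a cluster rank, so cluster ranks are
consecutive over non-empty clusters.  Sequences containing no selected
string stay unassigned (reported as NA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .motif_search import SelectedStringSet
from .sequence_io import SequencePool


@dataclass(frozen=True)
class RankedString:
    s: str
    Z: float
    z_star: float
    rank: int  # 1 = best


@dataclass(frozen=True)
class ClusterAssignment:
    """Greedy clustering result over the unique sequences of a pool.

    ``assignments`` maps each unique sequence to
    (cluster_rank, matched_string) or None if unassigned.
    """

    assignments: dict[str, tuple[int, str] | None]
    cluster_strings: tuple[str, ...]  # string that extracted cluster i (1-based)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_strings)

    def cluster_members(self, rank: int) -> list[str]:
        return [
            seq
            for seq, a in self.assignments.items()
            if a is not None and a[0] == rank
        ]

    def unassigned(self) -> list[str]:
        return [seq for seq, a in self.assignments.items() if a is None]

    def cluster_sizes(self, pool: SequencePool) -> list[tuple[int, int]]:
        """Per cluster (unique sequences, reads with multiplicity)."""
        counts = dict(pool.records)
        sizes = [[0, 0] for _ in self.cluster_strings]
        for seq, a in self.assignments.items():
            if a is not None:
                sizes[a[0] - 1][0] += 1
                sizes[a[0] - 1][1] += counts[seq]
        return [tuple(x) for x in sizes]


def normalize_z(selected: SelectedStringSet) -> list[RankedString]:
    """Standardize Z within each length class and rank by Z*.

    A class with a single string gets Z* = 0 (its class mean); likewise
    when the class standard deviation vanishes.  Ties in Z* break by higher
    Z, then longer string, then lexicographic order, making the ranking
    deterministic.
    """
    if selected.m == 0:
        raise ValueError("no selected strings to normalize")
    provisional: list[tuple[str, float, float]] = []
    for length, entries in selected.by_length.items():
        zs = [e.Z for e in entries]
        n = len(zs)
        mu = sum(zs) / n
        if n >= 2:
            var = sum((z - mu) ** 2 for z in zs) / (n - 1)
            sigma = math.sqrt(var)
        else:
            sigma = 0.0
        for e in entries:
            z_star = (e.Z - mu) / sigma if sigma > 0 else 0.0
            provisional.append((e.s, e.Z, z_star))
    provisional.sort(key=lambda t: (-t[2], -t[1], -len(t[0]), t[0]))
    return [
        RankedString(s=s, Z=z, z_star=zs, rank=i)
        for i, (s, z, zs) in enumerate(provisional, start=1)
    ]


def rank_strings(ranked: list[RankedString]) -> list[RankedString]:
    """Return strings in rank order (1 = best)."""
    return sorted(ranked, key=lambda r: r.rank)


def greedy_cluster(
    pool: SequencePool, ordered: list[RankedString]
) -> ClusterAssignment:
    """Extract clusters by descending Z* rank.

    Each string claims all remaining unique sequences containing it; empty
    extractions do not consume a cluster rank; clustering stops when no
    sequence remains.
    """
    # inverted index: for each string length in play, string -> containing
    # sequences; equivalent to re-scanning the remaining pool per string
    wanted_by_len: dict[int, set[str]] = {}
    for r in ordered:
        wanted_by_len.setdefault(len(r.s), set()).add(r.s)
    index: dict[str, list[str]] = {}
    for seq, _ in pool.records:
        for length, wanted in wanted_by_len.items():
            if len(seq) < length:
                continue
            for sub in {seq[i: i + length] for i in range(len(seq) - length + 1)}:
                if sub in wanted:
                    index.setdefault(sub, []).append(seq)

    remaining = {seq for seq, _ in pool.records}
    assignments: dict[str, tuple[int, str] | None] = {}
    cluster_strings: list[str] = []
    for r in rank_strings(ordered):
        if not remaining:
            break
        hit = [seq for seq in index.get(r.s, ()) if seq in remaining]
        if not hit:
            continue
        cluster_rank = len(cluster_strings) + 1
        cluster_strings.append(r.s)
        for seq in hit:
            assignments[seq] = (cluster_rank, r.s)
            remaining.remove(seq)
    for seq in remaining:
        assignments[seq] = None
    return ClusterAssignment(
        assignments=assignments, cluster_strings=tuple(cluster_strings)
    )


def write_clusters_tsv(
    assignment: ClusterAssignment,
    pool: SequencePool,
    ranked: list[RankedString],
    path: str | Path,
) -> None:
    z_star = {r.s: r.z_star for r in ranked}
    with open(path, "w") as fh:
        fh.write("sequence\tcount\tcluster_rank\tmatched_string\tstring_Zstar\n")
        for seq, count in pool.records:
            a = assignment.assignments[seq]
            if a is None:
                fh.write(f"{seq}\t{count}\tNA\tNA\tNA\n")
            else:
                rank, s = a
                fh.write(f"{seq}\t{count}\t{rank}\t{s}\t{z_star[s]:.6f}\n")


def read_clusters_tsv(path: str | Path) -> dict[str, int | None]:
    """sequence -> cluster rank (None for NA), as written by write_clusters_tsv."""
    out: dict[str, int | None] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        seq_col = header.index("sequence")
        rank_col = header.index("cluster_rank")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rank = fields[rank_col]
            out[fields[seq_col]] = None if rank == "NA" else int(rank)
    return out
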