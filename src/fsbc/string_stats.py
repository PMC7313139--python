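"""Containment probability and enrichment Z-score for strings in random text.

The central quantity is P_{s,L}: the probability that an i.i.d. random
L-mer (base j drawn with probability p_j) contains string s at least once.
It satisfies a renewal recurrence corrected for the self-overlap structure
(borders) of s,

    P_{s,L} = P_{s,L-1}
              + Q * (1 - P_{s,L-|s|}
                       - sum_t (1/q_t) * (P_{s,L-|s|+|t|} - P_{s,L-|s|+|t|-1})),

with P_{s,L} = 0 for L < |s|, Q = prod_j p_j^{n_{s,j}} and, per border t
(a non-empty proper prefix of s that is also a suffix),
q_t = prod_j p_j^{n_{t,j}}.  The three subtracted terms remove L-mers whose
first occurrence of s ends before L - |s|, at L - |s|, or inside the final
window at a self-overlapping position.

Averaging P_{s,L} over the empirical read-length distribution gives P_s,
and the enrichment of s in a pool of N reads of which F_s contain s is

    Z_s = (F_s/N - P_s) / sqrt(P_s (1 - P_s) / N),

the normal approximation to the binomial containment count.

Two independent oracles (exhaustive enumeration over all 4^L L-mers, and a
dynamic program over the KMP failure automaton of s) are provided to
validate the recurrence; they share no code with it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sequence_io import ALPHABET, SequencePool

logger = logging.getLogger(__name__)

_CLIP_TOL = 1e-9
_ENUMERATE_CAP = 11  # 4^11 ~ 4.2e6 L-mers


class ScoreUndefinedError(ValueError):
    """Z-score is undefined because P_s is 0 or 1."""


@dataclass(frozen=True)
class AlphabetProbs:
    """Per-base probabilities p_j over {A, C, G, T}."""

    p: tuple[float, float, float, float]  # order A, C, G, T

    def __post_init__(self) -> None:
        if any(x < 0 for x in self.p):
            raise ValueError("negative base probability")
        if abs(sum(self.p) - 1.0) > 1e-12:
            raise ValueError(f"base probabilities sum to {sum(self.p)!r}, not 1")
        object.__setattr__(self, "_by_base", dict(zip(ALPHABET, self.p)))

    def __getitem__(self, base: str) -> float:
        return self._by_base[base]

    @classmethod
    def uniform(cls) -> "AlphabetProbs":
        return cls((0.25, 0.25, 0.25, 0.25))

    @classmethod
    def from_mapping(cls, probs: dict[str, float]) -> "AlphabetProbs":
        return cls(tuple(probs.get(b, 0.0) for b in ALPHABET))

    def string_prob(self, s: str) -> float:
        """prod_j p_j^{n_{s,j}}: probability of s at a fixed position."""
        out = 1.0
        for ch in s:
            out *= self[ch]
        return out


@dataclass(frozen=True)
class ContainmentProfile:
    """Containment statistics of one string against one pool."""

    string: str
    Q: float
    table: np.ndarray  # P_{s,L} for L = 0..L_max
    P: float  # length-averaged containment probability
    F: int  # number of reads containing the string (with multiplicity)
    Z: float


def estimate_base_probs(pool: SequencePool) -> AlphabetProbs:
    """Estimate p_j = n_j / sum_i L_i from the pool composition.

    Counts are weighted by read multiplicity, so PCR-amplified duplicates
    contribute each copy — matching the pool the containment model sees.
    """
    total = pool.total_bases
    counts = pool.base_counts
    return AlphabetProbs(tuple(counts[b] / total for b in ALPHABET))


def border_set(s: str) -> list[str]:
    """Non-empty proper borders of s (prefixes that are also suffixes).

    E.g. the self-overlapping regions of "ATATA" are {"A", "ATA"}.
    Returned shortest-first.
    """
    if not s:
        raise ValueError("empty string has no border set")
    return [s[:k] for k in range(1, len(s)) if s[:k] == s[-k:]]


def containment_prob_table(
    s: str, probs: AlphabetProbs, L_max: int
) -> np.ndarray:
    """P_{s,L} for L = 0..L_max via the border-corrected renewal recurrence.

    Returns an array of length L_max + 1.  If Q = 0 (s uses a base of
    probability zero) the table is identically zero.
    """
    m = len(s)
    if m < 1:
        raise ValueError("string must be non-empty")
    if L_max < 0:
        raise ValueError("L_max must be >= 0")
    Q = probs.string_prob(s)
    if Q == 0.0 or L_max < m:
        return np.zeros(L_max + 1)
    borders = border_set(s)
    # plain-list recurrence: scalar indexing dominates this hot loop
    corr = [(len(t), 1.0 / probs.string_prob(t)) for t in borders]
    P = [0.0] * (L_max + 1)
    for L in range(m, L_max + 1):
        base = L - m
        overlap = 0.0
        for k, iq in corr:
            overlap += iq * (P[base + k] - P[base + k - 1])
        val = P[L - 1] + Q * (1.0 - P[base] - overlap)
        if not (-_CLIP_TOL <= val <= 1.0 + _CLIP_TOL):
            raise FloatingPointError(
                f"containment probability out of range for {s!r} at L={L}: {val!r}"
            )
        if val < 0.0 or val > 1.0:
            logger.warning("clipping P_{%s,%d}=%r to [0,1]", s, L, val)
            val = min(max(val, 0.0), 1.0)
        P[L] = val
    return np.asarray(P)


def length_averaged_prob(table: Sequence[float], pool: SequencePool) -> float:
    """P_s = (1/N) sum_i P_{s,L_i}, weighted by read multiplicity."""
    length_counts = pool.length_counts
    if max(length_counts) > len(table) - 1:
        raise ValueError("containment table does not cover the longest read")
    acc = sum(count * table[L] for L, count in length_counts.items())
    return acc / pool.n_reads


def count_containing_reads(s: str, pool: SequencePool) -> int:
    """F_s: summed count of reads containing s at least once."""
    return sum(count for seq, count in pool.records if s in seq)


def substring_containment_counts(pool: SequencePool, length: int) -> dict[str, int]:
    """Containment counts for every distinct substring of a given length.

    One scan over the unique sequences; each read contributes its count once
    per distinct substring (containment, not occurrence count).  This is the
    batch counterpart of :func:`count_containing_reads` used by the
    extension search, which evaluates whole length classes at a time.
    """
    counts: dict[str, int] = {}
    for seq, count in pool.records:
        if len(seq) < length:
            continue
        for sub in {seq[i: i + length] for i in range(len(seq) - length + 1)}:
            counts[sub] = counts.get(sub, 0) + count
    return counts


def z_score(F: int, N: int, P: float) -> float:
    """Z_s = (F/N - P) / sqrt(P (1-P) / N)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 < P < 1.0:
        raise ScoreUndefinedError(f"Z undefined for containment probability {P!r}")
    return (F / N - P) / math.sqrt(P * (1.0 - P) / N)


def score_string(
    s: str, pool: SequencePool, probs: AlphabetProbs | None = None
) -> ContainmentProfile:
    """Convenience: full containment profile of one string against a pool."""
    if probs is None:
        probs = estimate_base_probs(pool)
    table = containment_prob_table(s, probs, pool.max_length)
    P = length_averaged_prob(table, pool)
    F = count_containing_reads(s, pool)
    Z = z_score(F, pool.n_reads, P)
    return ContainmentProfile(
        string=s, Q=probs.string_prob(s), table=table, P=P, F=F, Z=Z
    )


# ---------------------------------------------------------------------------
# Independent oracles


def _enumeration_table(s: str, probs: AlphabetProbs, L_max: int) -> np.ndarray:
    """P_{s,L} for L = 0..L_max by exhaustive enumeration of all 4^L_max mers.

    Every L_max-mer is classified by the end position of its first occurrence
    of s; marginalizing gives P_{s,L} for every prefix length L at once.
    Vectorized over integer codes (two bits per base, first base most
    significant); independent of the recurrence.
    """
    m = len(s)
    if L_max < m:
        return np.zeros(L_max + 1)
    if L_max > _ENUMERATE_CAP:
        raise ValueError(f"enumeration refused beyond L={_ENUMERATE_CAP}")
    idx = np.arange(4 ** L_max, dtype=np.int64)
    weight = np.ones(len(idx))
    p = np.asarray(probs.p)
    for d in range(L_max):
        weight *= p[(idx >> (2 * (L_max - 1 - d))) & 3]
    s_code = 0
    for ch in s:
        s_code = (s_code << 2) | ALPHABET.index(ch)
    mask = (1 << (2 * m)) - 1
    first_occ = np.zeros(L_max + 1)
    seen = np.zeros(len(idx), dtype=bool)
    for end in range(m, L_max + 1):
        window = (idx >> (2 * (L_max - end))) & mask
        hit = window == s_code
        first_occ[end] = weight[hit & ~seen].sum()
        seen |= hit
    return np.cumsum(first_occ)


def _kmp_transitions(s: str) -> np.ndarray:
    """KMP automaton: delta[state, base] for states 0..|s|-1 (|s| = accept)."""
    m = len(s)
    fail = np.zeros(m, dtype=np.int64)
    k = 0
    for i in range(1, m):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    delta = np.zeros((m, 4), dtype=np.int64)
    for state in range(m):
        for b, ch in enumerate(ALPHABET):
            k = state
            while k and s[k] != ch:
                k = fail[k - 1]
            delta[state, b] = k + 1 if s[k] == ch else 0
    return delta


def _automaton_table(s: str, probs: AlphabetProbs, L_max: int) -> np.ndarray:
    """P_{s,L} via a dynamic program over the KMP failure automaton of s.

    Tracks the distribution over "longest suffix matching a prefix of s"
    states among texts not yet containing s; the accepting mass is P_{s,L}.
    Exact to float precision for any L; independent of the recurrence.
    """
    m = len(s)
    table = np.zeros(L_max + 1)
    if L_max < m:
        return table
    delta = _kmp_transitions(s)
    p = np.asarray(probs.p)
    state_prob = np.zeros(m)
    state_prob[0] = 1.0
    contained = 0.0
    for L in range(1, L_max + 1):
        nxt = np.zeros(m)
        for b in range(4):
            if p[b] == 0.0:
                continue
            moved = state_prob * p[b]
            for state in range(m):
                to = delta[state, b]
                if to == m:
                    contained += moved[state]
                else:
                    nxt[to] += moved[state]
        state_prob = nxt
        if L >= m:
            table[L] = contained
    return table


def exact_containment_oracle(
    s: str, probs: AlphabetProbs, L: int, method: str = "automaton"
) -> float:
    """Exact P_{s,L} by a route independent of the recurrence.

    method="enumerate" sums the probability of every L-mer containing s
    (refused for L > 11); method="automaton" runs the failure-automaton
    dynamic program and works for any L.
    """
    if method == "enumerate":
        return float(_enumeration_table(s, probs, L)[L])
    if method == "automaton":
        return float(_automaton_table(s, probs, L)[L])
    raise ValueError(f"unknown oracle method {method!r}")


def dump_scores_tsv(profiles: Sequence[ContainmentProfile], path) -> None:
    """Debug dump of (s, F_s, P_s, Z_s)."""
    with open(path, "w") as fh:
        fh.write("string\tF\tP\tZ\n")
        for pr in profiles:
            fh.write(f"{pr.string}\t{pr.F}\t{pr.P:.10g}\t{pr.Z:.6f}\n")
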