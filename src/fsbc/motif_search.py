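"""Selection of over-represented strings by Z-score-pruned extension.

Candidate target-binding regions of lengths l_min..l_max are found without
enumerating the full 4^l space at every length.  All 4^{l_min} seeds are
scored; a seed survives if its Z-score is non-negative.  Each survivor of
length l is then extended by one base on either end, and an extended string
is kept only if its Z-score does not fall below that of (at least one of)
the strings it extends.  The selected set is the union of survivors over
all lengths; the number of strings actually scored is the search-space
reporter's measure of the pruning.

F_s counting is batched: one scan of the unique sequences per length class
collects containment counts for every distinct substring of that length, so
scoring a level is O(total bases) plus one probability table per candidate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .sequence_io import ALPHABET, SequencePool
from .string_stats import (
    AlphabetProbs,
    containment_prob_table,
    length_averaged_prob,
    substring_containment_counts,
    z_score,
)

logger = logging.getLogger(__name__)


class EmptySelectionError(RuntimeError):
    """No seed string had a non-negative Z-score."""


@dataclass(frozen=True)
class SearchConfig:
    """Lengths of strings to search and how to extend them.

    ``extend`` chooses which ends gain a base per extension step; the default
    grows both ends, which is required for a short core (e.g. GACTT) to reach
    an asymmetric longer string around it.
    """

    l_min: int = 5
    l_max: int = 10
    extend: str = "both"  # {"both", "left", "right"}

    def __post_init__(self) -> None:
        if self.l_min < 1 or self.l_max < self.l_min:
            raise ValueError(f"invalid length range [{self.l_min}, {self.l_max}]")
        if self.extend not in {"both", "left", "right"}:
            raise ValueError(f"invalid extension mode {self.extend!r}")

    def search_space_size(self) -> int:
        """Number of strings an exhaustive enumeration would score:
        sum over l = l_min..l_max of 4^l."""
        return sum(4 ** l for l in range(self.l_min, self.l_max + 1))


@dataclass(frozen=True)
class ScoredString:
    s: str
    F: int
    P: float
    Z: float

    @property
    def length(self) -> int:
        return len(self.s)


@dataclass
class SelectedStringSet:
    """Survivors of the pruned extension search, grouped by length."""

    by_length: dict[int, list[ScoredString]] = field(default_factory=dict)
    n_z_evaluations: int = 0  # strings actually scored, incl. rejected ones

    @property
    def entries(self) -> list[ScoredString]:
        return [e for l in sorted(self.by_length) for e in self.by_length[l]]

    @property
    def m(self) -> int:
        return sum(len(v) for v in self.by_length.values())

    def survivor_counts(self) -> dict[int, int]:
        return {l: len(v) for l, v in sorted(self.by_length.items())}


def _score_level(
    candidates: list[str],
    pool: SequencePool,
    probs: AlphabetProbs,
    counts: dict[str, int],
) -> dict[str, ScoredString]:
    """Z-score every candidate of one length class against the pool.

    Candidates absent from every read (F = 0) necessarily have Z < 0
    whenever P > 0, so they are dropped without a probability table.
    Strings with degenerate P (0 or 1) cannot be scored and are excluded.
    """
    N = pool.n_reads
    L_max = pool.max_length
    length_items = list(pool.length_counts.items())
    scored: dict[str, ScoredString] = {}
    for s in candidates:
        F = counts.get(s, 0)
        if F == 0:
            continue
        table = containment_prob_table(s, probs, L_max)
        P = sum(c * table[L] for L, c in length_items) / N
        if not 0.0 < P < 1.0:
            logger.info("excluding %s: degenerate containment probability %g", s, P)
            continue
        scored[s] = ScoredString(s, F, P, z_score(F, N, P))
    return scored


def enumerate_seeds(
    pool: SequencePool, probs: AlphabetProbs, config: SearchConfig
) -> tuple[list[ScoredString], int]:
    """Score all 4^{l_min} seed strings; keep those with Z >= 0.

    Returns (survivors, number of candidates enumerated).
    """
    candidates = [
        "".join(t) for t in itertools.product(ALPHABET, repeat=config.l_min)
    ]
    counts = substring_containment_counts(pool, config.l_min)
    scored = _score_level(candidates, pool, probs, counts)
    survivors = [e for e in scored.values() if e.Z >= 0.0]
    return survivors, len(candidates)


def extend_strings(
    survivors: list[ScoredString],
    pool: SequencePool,
    probs: AlphabetProbs,
    extend: str = "both",
) -> tuple[list[ScoredString], int]:
    """One extension step: length l survivors -> length l+1 survivors.

    Each parent s proposes children x+s and/or s+x for every base x
    (deduplicated across parents).  A child is retained iff its Z-score is
    at least the Z-score of some parent that proposes it.

    Returns (retained children, number of distinct children scored).
    """
    if not survivors:
        return [], 0
    # child -> weakest Z threshold among its proposing parents
    threshold: dict[str, float] = {}
    for parent in survivors:
        children: list[str] = []
        if extend in ("both", "left"):
            children += [x + parent.s for x in ALPHABET]
        if extend in ("both", "right"):
            children += [parent.s + x for x in ALPHABET]
        for child in children:
            prev = threshold.get(child)
            if prev is None or parent.Z < prev:
                threshold[child] = parent.Z
    counts = substring_containment_counts(pool, len(survivors[0].s) + 1)
    scored = _score_level(list(threshold), pool, probs, counts)
    retained = [e for s, e in scored.items() if e.Z >= threshold[s]]
    return retained, len(threshold)


def select_strings(
    pool: SequencePool, probs: AlphabetProbs, config: SearchConfig
) -> SelectedStringSet:
    """Run the pruned extension search over lengths l_min..l_max.

    Deterministic given pool and config.  Raises
    :class:`EmptySelectionError` if no seed survives.
    """
    if config.l_max > pool.max_length:
        logger.warning(
            "l_max=%d exceeds the longest read (%d); long strings cannot occur",
            config.l_max,
            pool.max_length,
        )
    result = SelectedStringSet()
    survivors, n_scored = enumerate_seeds(pool, probs, config)
    result.n_z_evaluations += n_scored
    if not survivors:
        raise EmptySelectionError(
            f"no {config.l_min}-mer has non-negative Z in this pool "
            f"(N={pool.n_reads}, unique={pool.n_unique})"
        )
    result.by_length[config.l_min] = sorted(survivors, key=lambda e: e.s)
    for length in range(config.l_min, config.l_max):
        survivors, n_scored = extend_strings(
            survivors, pool, probs, config.extend
        )
        result.n_z_evaluations += n_scored
        if not survivors:
            break
        result.by_length[length + 1] = sorted(survivors, key=lambda e: e.s)
    logger.info(
        "selected %d strings; survivors per length %s; %d Z evaluations "
        "(exhaustive would need %d)",
        result.m,
        result.survivor_counts(),
        result.n_z_evaluations,
        config.search_space_size(),
    )
    return result


def write_strings_tsv(selected: SelectedStringSet, path, ranked=None) -> None:
    """Write strings.tsv; Z* and rank columns are filled when a ranking
    from the clustering stage is supplied."""
    extra = {}
    if ranked is not None:
        extra = {r.s: (r.z_star, r.rank) for r in ranked}
    with open(path, "w") as fh:
        fh.write("string\tlength\tF\tP\tZ\tZ_star\trank\n")
        for e in selected.entries:
            z_star, rank = extra.get(e.s, (float("nan"), ""))
            fh.write(
                f"{e.s}\t{e.length}\t{e.F}\t{e.P:.10g}\t{e.Z:.6f}"
                f"\t{z_star:.6f}\t{rank}\n"
            )
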