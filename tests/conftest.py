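"""Shared fixtures: small hand-built pools and the planted-motif study.

The "study" fixture runs the full pipeline over 20 seeded synthetic
replicates under fixed conditions (10^4 reads of nominal length 30 with 22%
off-length jitter, skewed composition A/C/G/T = 0.3/0.2/0.3/0.2, one
planted 10-mer at prevalence 0.2) and caches light per-replicate records so
several tests can share one computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from fsbc.clustering import greedy_cluster, normalize_z
from fsbc.evaluation import LabeledSequence, roc_auc_by_cluster_rank
from fsbc.motif_search import SearchConfig, _score_level, select_strings
from fsbc.sequence_io import pool_from_counts
from fsbc.string_stats import estimate_base_probs, substring_containment_counts
from fsbc.synthetic_pool import PlantedMotif, SyntheticPoolSpec, generate_pool

STUDY_MOTIF = "TATGGACTTC"
STUDY_SEEDS = tuple(range(1, 21))
ANTIMISSING_LENGTHS = (5, 6, 7, 8)


def study_spec(seed: int, **overrides) -> SyntheticPoolSpec:
    params = dict(
        n_reads=10_000,
        nominal_length=30,
        off_length_fraction=0.22,
        base_probs=(0.3, 0.2, 0.3, 0.2),
        motifs=(PlantedMotif(STUDY_MOTIF, 0.2),),
        seed=seed,
    )
    params.update(overrides)
    return SyntheticPoolSpec(**params)


@dataclass(frozen=True)
class ReplicateResult:
    seed: int
    top_string: str
    top_is_motif_related: bool  # rank-1 string is a sub- or superstring of the motif
    carrier_fraction_in_cluster1: float
    auc: float
    n_selected: int
    n_z_evaluations: int
    survivor_counts: dict[int, int]
    exhaustive_top_in_survivors: dict[int, bool]  # per length, anti-missing check


def run_replicate(seed: int) -> ReplicateResult:
    pool, truth = generate_pool(study_spec(seed))
    probs = estimate_base_probs(pool)
    selected = select_strings(pool, probs, SearchConfig(l_min=5, l_max=10))
    ranked = normalize_z(selected)
    assignment = greedy_cluster(pool, ranked)

    top = ranked[0].s
    # carrier = sequence containing the motif; a background read that picked
    # up the motif by chance carries the binding region just as a planted one
    carriers = {seq for seq in pool.sequences() if STUDY_MOTIF in seq}
    assert truth.carriers(STUDY_MOTIF) <= carriers
    cluster1 = set(assignment.cluster_members(1))
    labeled = [
        LabeledSequence(seq, seq in carriers, a[0] if a else None)
        for seq, a in assignment.assignments.items()
    ]

    survivors = {l: {e.s for e in v} for l, v in selected.by_length.items()}
    anti_missing: dict[int, bool] = {}
    for length in ANTIMISSING_LENGTHS:
        counts = substring_containment_counts(pool, length)
        scored = _score_level(list(counts), pool, probs, counts)
        best = max(scored.values(), key=lambda e: (e.Z, e.s))
        anti_missing[length] = best.s in survivors.get(length, set())

    return ReplicateResult(
        seed=seed,
        top_string=top,
        top_is_motif_related=(top in STUDY_MOTIF) or (STUDY_MOTIF in top),
        carrier_fraction_in_cluster1=len(carriers & cluster1) / len(carriers),
        auc=roc_auc_by_cluster_rank(labeled),
        n_selected=selected.m,
        n_z_evaluations=selected.n_z_evaluations,
        survivor_counts=selected.survivor_counts(),
        exhaustive_top_in_survivors=anti_missing,
    )


@pytest.fixture(scope="session")
def study_results() -> list[ReplicateResult]:
    return [run_replicate(seed) for seed in STUDY_SEEDS]


@pytest.fixture
def toy_pool():
    """A tiny pool with known composition: {ACGT: 2, GGGG: 1, ACGTACGT: 1}."""
    return pool_from_counts({"ACGT": 2, "GGGG": 1, "ACGTACGT": 1})
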