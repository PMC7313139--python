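"""Cluster-ranking accuracy against binding labels (ROC/AUC).

Labeled sequences are ordered by the rank of the cluster they fall in;
the ROC curve treats a lower cluster rank as a higher score, sequences in
the same cluster as tied, and unclustered (NA) sequences as strictly worse
than every cluster.  The AUC is the Mann-Whitney U statistic with half
credit for ties, divided by n_pos * n_neg — the standard tie-aware
definition, so it is invariant to any strictly monotone transform of the
cluster ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .sequence_io import normalize_read


@dataclass(frozen=True)
class LabeledSequence:
    sequence: str
    binding: bool
    cluster_rank: int | None  # None = unassigned (NA)


def read_labels_tsv(path: str | Path) -> dict[str, bool]:
    """Labels TSV with columns sequence, binding in {yes,no}.

    Sequences are normalized the same way as pool reads so they match the
    pool exactly.
    """
    labels: dict[str, bool] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        seq_col = header.index("sequence")
        bind_col = header.index("binding")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            seq = normalize_read(fields[seq_col])
            if seq is None:
                raise ValueError(f"unparseable labeled sequence: {fields[seq_col]!r}")
            value = fields[bind_col].strip().lower()
            if value not in {"yes", "no"}:
                raise ValueError(f"binding label must be yes/no, got {value!r}")
            labels[seq] = value == "yes"
    return labels


def attach_cluster_ranks(
    labels: dict[str, bool], ranks: dict[str, int | None]
) -> list[LabeledSequence]:
    return [
        LabeledSequence(seq, binding, ranks.get(seq))
        for seq, binding in labels.items()
    ]


def _scores(labeled: list[LabeledSequence]) -> tuple[np.ndarray, np.ndarray]:
    """Higher score = better cluster; NA strictly below every real cluster."""
    ranks = [ls.cluster_rank for ls in labeled]
    worst = max((r for r in ranks if r is not None), default=0) + 1
    score = np.array([-(worst if r is None else r) for r in ranks], dtype=float)
    y = np.array([ls.binding for ls in labeled], dtype=bool)
    return y, score


def roc_auc_by_cluster_rank(labeled: list[LabeledSequence]) -> float:
    """AUC of binding vs cluster rank (tie-aware Mann-Whitney U / (n+ n-))."""
    y, score = _scores(labeled)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    r = rankdata(score)  # average ranks give the 0.5 tie credit
    u = r[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_points(labeled: list[LabeledSequence]) -> list[tuple[float, float]]:
    """ROC curve points (FPR, TPR), from (0,0) to (1,1), one step per
    distinct score level (tied sequences move diagonally together)."""
    y, score = _scores(labeled)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    points = [(0.0, 0.0)]
    tp = fp = 0
    for level in sorted(set(score), reverse=True):
        at = score == level
        tp += int(y[at].sum())
        fp += int((~y)[at].sum())
        points.append((fp / n_neg, tp / n_pos))
    return points


def write_roc_tsv(points: list[tuple[float, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")
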