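"""Rank-sum consensus scoring of lineage specificity.

Each probe is ranked within every target category by its fold change against
the maximum-expressing reference (rank 1 = largest fold change). A strict
fold-change threshold assigns a consensus group — the subset of categories in
which the probe exceeds the threshold, rendered "OV/HC/SC" style. The
consensus score is the plain sum of the per-category ranks; ranking probes by
ascending score (rank 1 = most lineage-specific) collapses the multi-category
comparison to a single prioritized list.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: rendering of the empty consensus group
NO_GROUP = "-"

DEFAULT_THRESHOLD = 4.0


def rank_by_fold_change(
    folds: pd.Series,
    q_values: pd.Series | None = None,
) -> pd.Series:
    """Strict integer ranks, 1 = largest fold change.

    Ties are broken by ascending q-value, then lexicographic probe id, so
    ranks are a deterministic permutation of 1..N.
    """
    folds = pd.Series(folds)
    probe_ids = folds.index.astype(str).to_numpy()
    if q_values is None:
        q = np.zeros(len(folds))
    else:
        q = pd.Series(q_values).reindex(folds.index).to_numpy(dtype=float)
    # last key dominates in lexsort: descending fold, then asc q, then id
    order = np.lexsort((probe_ids, q, -folds.to_numpy(dtype=float)))
    ranks = np.empty(len(folds), dtype=np.int64)
    ranks[order] = np.arange(1, len(folds) + 1)
    return pd.Series(ranks, index=folds.index)


def assign_consensus_groups(
    folds_per_category: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.Series:
    """Label each probe with the categories whose fold change exceeds threshold.

    The comparison is strict (> threshold). Category order in the label
    follows the column order of ``folds_per_category``; the empty set renders
    as ``"-"``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cats = list(folds_per_category.columns)
    above = folds_per_category.to_numpy(dtype=float) > threshold

    def render(row: np.ndarray) -> str:
        members = [c for c, flag in zip(cats, row) if flag]
        return "/".join(members) if members else NO_GROUP

    labels = [render(row) for row in above]
    return pd.Series(labels, index=folds_per_category.index)


def consensus_score(ranks_per_category: pd.DataFrame) -> pd.Series:
    """Sum of per-category ranks; smaller = more lineage-specific."""
    ranks = ranks_per_category.to_numpy()
    if np.any(ranks < 1):
        raise ValueError("ranks must be ≥ 1")
    return pd.Series(
        ranks.sum(axis=1, dtype=np.int64), index=ranks_per_category.index
    )


def consensus_rank(
    scores: pd.Series,
    ranks_per_category: pd.DataFrame | None = None,
) -> pd.Series:
    """Rank probes by ascending consensus score (1 = most specific).

    Ties are broken by the probe's best (smallest) single-category rank, then
    by probe id, so the result is a deterministic permutation of 1..N.
    """
    scores = pd.Series(scores)
    probe_ids = scores.index.astype(str).to_numpy()
    if ranks_per_category is not None:
        best = ranks_per_category.reindex(scores.index).min(axis=1).to_numpy()
    else:
        best = np.zeros(len(scores))
    order = np.lexsort((probe_ids, best, scores.to_numpy()))
    out = np.empty(len(scores), dtype=np.int64)
    out[order] = np.arange(1, len(scores) + 1)
    return pd.Series(out, index=scores.index)


def volcano_counts(
    folds: np.ndarray,
    q_values: np.ndarray,
    fc_cut: float = 4.0,
    q_cut: float = 1e-3,
) -> int:
    """Count probes beyond both volcano-plot cutoffs (strict comparisons)."""
    folds = np.asarray(folds, dtype=float)
    q_values = np.asarray(q_values, dtype=float)
    if folds.shape != q_values.shape:
        raise ValueError(
            f"length mismatch: {folds.shape} folds vs {q_values.shape} q-values"
        )
    return int(np.sum((folds > fc_cut) & (q_values < q_cut)))


def top_k_overlap(
    category_ranks: pd.Series,
    consensus_set: pd.Index | list,
    k: int,
) -> tuple[int, float | None]:
    """Overlap of a consensus set with the top-k probes of a category ranking.

    Returns ``(count, fraction_percent)`` where the fraction is the share of
    the consensus set found at category rank ≤ k, as a percentage rounded to
    one decimal (e.g. 119/684 → 17.4). An empty consensus set has no defined
    fraction and returns ``None``.
    """
    category_ranks = pd.Series(category_ranks)
    if k > len(category_ranks):
        raise ValueError(f"k={k} exceeds probe count {len(category_ranks)}")
    members = pd.Index(consensus_set)
    if len(members) == 0:
        return 0, None
    count = int((category_ranks.loc[members] <= k).sum())
    return count, overlap_percent(count, len(members))


def overlap_percent(count: int, total: int) -> float:
    """Fraction as a one-decimal percentage, the convention used in reporting."""
    return round(100.0 * count / total, 1)
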