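"""Putting raw intensities on the analysis scale.

Bead-array summary intensities arrive on a linear scale and can dip to or
below zero after background correction, so values are floored, log2
transformed, and then quantile normalized jointly across all arrays: each
array's distribution is replaced by the common reference distribution formed
by averaging each quantile across arrays. Any per-array monotone distortion
is thereby removed while within-array ranks are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, LINEAR, LOG2

log = logging.getLogger(__name__)


@dataclass
class NormalizationReport:
    """Diagnostics from quantile normalization.

    ``reference_distribution`` is the sorted per-quantile average (length =
    probe count); ``per_sample_shift`` is the median change applied to each
    sample's values. ``order`` records that log2 transform precedes
    normalization in this pipeline.
    """

    reference_distribution: np.ndarray
    per_sample_shift: pd.Series
    order: str = "log2_then_quantile"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.reference_distribution) < 0):
            raise ValueError("reference distribution must be non-decreasing")


def log2_transform(matrix: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """Floor linear intensities at ``floor`` and take log2."""
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    if matrix.scale != LINEAR:
        raise ValueError("log2_transform expects a linear-scale matrix")
    values = np.log2(matrix.values.clip(lower=floor))
    return matrix.copy_with(values, scale=LOG2)


def _normalize_column(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Map one column onto the reference distribution.

    Tied values receive the mean of the reference entries over the tied rank
    span, which keeps the map deterministic and permutation-equivariant.
    """
    order = np.argsort(col, kind="stable")
    sorted_vals = col[order]
    out_sorted = ref.astype(float).copy()
    # collapse tie spans to the span mean of the reference
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(col)]))
    for s, e in zip(starts, ends):
        if e - s > 1:
            out_sorted[s:e] = ref[s:e].mean()
    out = np.empty_like(out_sorted)
    out[order] = out_sorted
    return out


def quantile_normalize(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Quantile normalize all samples jointly (log2 scale).

    After normalization every sample holds the same multiset of values: the
    k-th smallest value of each column equals the mean of the k-th smallest
    values across the original columns.
    """
    if matrix.scale != LOG2:
        raise ValueError("quantile_normalize operates on the log2 scale")
    vals = matrix.values.to_numpy(dtype=float)
    n_probes, n_samples = vals.shape
    if n_samples < 2:
        log.warning("quantile normalization skipped: single-sample matrix")
        report = NormalizationReport(
            reference_distribution=np.sort(vals[:, 0]),
            per_sample_shift=pd.Series(0.0, index=matrix.sample_ids),
        )
        return matrix.copy_with(matrix.values.copy()), report

    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.column_stack(
        [_normalize_column(vals[:, j], ref) for j in range(n_samples)]
    )
    shifts = pd.Series(
        np.median(out - vals, axis=0), index=matrix.sample_ids
    )
    values = pd.DataFrame(out, index=matrix.probe_ids, columns=matrix.sample_ids)
    return matrix.copy_with(values), NormalizationReport(ref, shifts)


def combine_and_normalize(
    matrices: list[ExpressionMatrix],
    floor: float = 1.0,
    joint: bool = True,
) -> ExpressionMatrix:
    """Combine linear-scale datasets and quantile normalize on log2 scale.

    ``joint=True`` (the default analysis mode) normalizes once across all
    arrays of the combined matrix; ``joint=False`` normalizes each dataset
    separately before combining, as a sensitivity analysis.
    """
    if joint:
        combined = combine_datasets(matrices)
        out, _ = quantile_normalize(log2_transform(combined, floor))
        return out
    normalized = [quantile_normalize(log2_transform(m, floor))[0] for m in matrices]
    return combine_datasets(normalized)


def combine_datasets(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate same-platform matrices, aligning rows by probe id.

    All matrices must share an identical probe universe (order may differ);
    sample ids must be globally unique. Normalization is expected to be run
    once afterwards on the combined matrix.
    """
    if not matrices:
        raise ValueError("no matrices to combine")
    if len(matrices) == 1:
        return matrices[0]
    base = matrices[0]
    probe_set = set(base.probe_ids)
    for m in matrices[1:]:
        other = set(m.probe_ids)
        if other != probe_set:
            raise ValueError(
                "probe sets differ: "
                f"{len(probe_set - other)} probes only in first, "
                f"{len(other - probe_set)} probes only in other"
            )
        if m.scale != base.scale:
            raise ValueError("cannot combine matrices on different scales")
    frames = [base.values] + [m.values.reindex(base.probe_ids) for m in matrices[1:]]
    all_samples = [s for f in frames for s in f.columns]
    if len(set(all_samples)) != len(all_samples):
        dups = sorted({s for s in all_samples if all_samples.count(s) > 1})
        raise ValueError(f"duplicate sample ids across datasets: {dups}")
    combined = pd.concat(frames, axis=1)
    return ExpressionMatrix(
        values=combined, gene_symbols=base.gene_symbols.copy(), scale=base.scale
    )
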