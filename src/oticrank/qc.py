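"""Sample-level quality control: PCA projection, Spearman correlation and
agglomerative clustering of samples.

Replicates of a tissue group should project near each other on the first two
principal components, correlate more strongly with each other than with other
groups, and merge first in the dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from .matrix import ExpressionMatrix


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples × components
    explained_variance_fraction: np.ndarray
    loadings_available: bool = False

    def __post_init__(self) -> None:
        frac = self.explained_variance_fraction
        if np.any(np.diff(frac) > 1e-9) or frac.sum() > 1 + 1e-9:
            raise ValueError("explained variance fractions must be non-increasing and sum ≤ 1")


@dataclass
class CorrelationMatrix:
    corr: pd.DataFrame  # sample × sample Spearman coefficients
    linkage: np.ndarray | None = None  # scipy linkage matrix (merge order + heights)

    def __post_init__(self) -> None:
        c = self.corr.to_numpy()
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(c) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")


def pca_scores(matrix: ExpressionMatrix, n_components: int = 2) -> PCAResult:
    """Project samples onto principal components of probe-centered data.

    Each probe is centered across samples (no variance scaling) and the
    decomposition is by SVD. Sign convention: the largest-magnitude score
    coordinate of every component is positive, making output deterministic.
    """
    n_samples, n_probes = matrix.n_samples, matrix.n_probes
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    max_comp = min(n_samples - 1, n_probes)
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds limit {max_comp}")
    X = matrix.values.to_numpy(dtype=float).T  # samples × probes
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return PCAResult(
        scores=pd.DataFrame(
            scores,
            index=matrix.sample_ids,
            columns=[f"PC{j + 1}" for j in range(scores.shape[1])],
        ),
        explained_variance_fraction=pca.explained_variance_ratio_,
    )


def spearman_matrix(matrix: ExpressionMatrix) -> CorrelationMatrix:
    """Sample × sample Spearman correlation (ties get mean ranks)."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    vals = matrix.values.to_numpy(dtype=float)
    constant = vals.std(axis=0) == 0
    if constant.any():
        bad = list(matrix.sample_ids[constant])
        raise ValueError(f"constant sample column(s), correlation undefined: {bad}")
    rho = spearmanr(vals, axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    corr = pd.DataFrame(rho, index=matrix.sample_ids, columns=matrix.sample_ids)
    return CorrelationMatrix(corr=corr)


def cluster_samples(corr: CorrelationMatrix) -> np.ndarray:
    """Average-linkage agglomerative clustering on distance 1 − ρ.

    Returns the scipy linkage matrix (merge sequence with heights) and stores
    it on ``corr.linkage``.
    """
    dist = 1.0 - corr.corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    corr.linkage = Z
    return Z


def replicate_groups_recovered(
    corr: CorrelationMatrix, sample_groups: dict[str, str]
) -> bool:
    """Whether cutting the dendrogram at k = #groups reproduces the groups.

    True iff replicates of every group merge before any cross-group merge.
    """
    Z = corr.linkage if corr.linkage is not None else cluster_samples(corr)
    labels = [sample_groups[s] for s in corr.corr.index]
    k = len(set(labels))
    assignment = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    mapping: dict[str, int] = {}
    for lab, cl in zip(labels, assignment):
        if mapping.setdefault(lab, cl) != cl:
            return False
    return len(set(mapping.values())) == k
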