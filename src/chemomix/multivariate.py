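"""Ordination, permutational ANOVA, and heatmap clustering.

* :func:`pca` — principal component analysis by singular value
  decomposition of the column-centred sample x analyte matrix; the
  variance explained by component k is sigma_k^2 / sum(sigma^2) * 100.
* :func:`permanova` — one-way permutational multivariate ANOVA on a
  distance matrix: total and within-group sums of squared distances
  give a pseudo-F whose null distribution is obtained by freely
  permuting group labels.  On Euclidean distances of univariate data
  the pseudo-F equals the classical one-way ANOVA F.
* :func:`hierarchical_cluster` — Euclidean/Ward agglomeration for
  ordering heatmap rows or columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .datamodel import ValidationError


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # analytes x components
    explained_variance_pct: np.ndarray  # per component, sums to 100


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p: float
    n_permutations: int
    seed: int


def pca(matrix: pd.DataFrame, center: bool = True) -> PCAResult:
    """PCA of a samples x analytes matrix via SVD.

    Column (analyte) means are removed unless the input is already
    centred; loadings have unit norm and scores are the centred data
    projected onto them.  Component signs are fixed so that each
    loading's largest-magnitude entry is positive.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if np.isnan(X).any():
        raise ValidationError("PCA input contains missing values")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = (s**2).sum()
    if total == 0:
        raise ValidationError("matrix has no variance")
    # deterministic sign convention
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    comps = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(U * s, index=matrix.index, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=matrix.columns, columns=comps)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_pct=s**2 / total * 100.0,
    )


def _within_ss(D2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss


def permanova(
    D: np.ndarray | pd.DataFrame,
    labels,
    n_perm: int = 9999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a symmetric distance matrix.

    SS_total = sum_{i<j} d_ij^2 / N;
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g;
    pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a));
    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1) over free label
    permutations.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    N = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValidationError("distance matrix diagonal must be zero")
    if len(labels) != N:
        raise ValidationError("one label per sample required")
    groups = np.unique(labels)
    a = len(groups)
    if a < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    if N - a < 1:
        raise ValidationError("not enough residual degrees of freedom")

    D2 = D**2
    ss_total = D2.sum() / (2.0 * N)

    def pseudo_f(lab: np.ndarray) -> float:
        ss_within = _within_ss(D2, lab, groups)
        ss_between = ss_total - ss_within
        return (ss_between / (a - 1)) / (ss_within / (N - a))

    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(labels)) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_F=float(f_obs), p=float(p), n_permutations=n_perm, seed=seed
    )


def euclidean_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Euclidean sample-to-sample distances of a samples x analytes matrix."""
    D = squareform(pdist(matrix.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


@dataclass
class ClusteringResult:
    order: list  # leaf order (labels)
    linkage: np.ndarray  # scipy merge list with heights


def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "samples") -> ClusteringResult:
    """Agglomerative clustering (Euclidean distance, Ward linkage).

    ``axis="samples"`` clusters rows; ``axis="analytes"`` clusters
    columns.  Returns the dendrogram leaf order and the merge list.
    """
    if axis == "analytes":
        matrix = matrix.T
    elif axis != "samples":
        raise ValidationError(f"unknown axis {axis!r}")
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 items")
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    leaves = hierarchy.leaves_list(Z)
    return ClusteringResult(
        order=[matrix.index[i] for i in leaves], linkage=Z
    )
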