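"""Global methylome structure: distances, clustering, PCA, ANOSIM.

These operate on per-sample methylation proportion vectors restricted to
sites observed in every sample (complete cases), the standard substrate for
sample-level ordination of bisulfite data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .matrix import MethylationMatrix


@dataclass
class DistanceMatrix:
    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")
        np.fill_diagonal(self.values, 0.0)
        self.values = np.maximum(self.values, 0.0)
        self.values = 0.5 * (self.values + self.values.T)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def complete_case_proportions(matrix: MethylationMatrix) -> np.ndarray:
    """Samples x sites proportion matrix over sites observed everywhere."""
    obs = matrix.observed()
    complete = obs.all(axis=1)
    props = matrix.proportions()[complete]
    return props.T  # samples x sites


def distance_matrix(matrix: MethylationMatrix, metric: str = "correlation") -> DistanceMatrix:
    """Pairwise sample distances on complete-case proportion vectors.

    metric 'euclidean' or 'correlation' (1 - Pearson r).
    """
    X = complete_case_proportions(matrix)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 complete-case sites")
    if metric == "euclidean":
        sq = np.sum(X**2, axis=1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
        D = np.sqrt(d2)
        np.fill_diagonal(D, 0.0)
        D = 0.5 * (D + D.T)
    elif metric == "correlation":
        C = np.corrcoef(X)
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        D = 0.5 * (D + D.T)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(matrix.sample_ids, D)


def hierarchical_cluster(D: DistanceMatrix, linkage: str = "average") -> np.ndarray:
    """Agglomerative clustering of a distance matrix.

    Returns the scipy linkage matrix; ties are broken deterministically by
    scipy's ordering of the condensed distances (i.e., by sample order).
    """
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    return hierarchy.linkage(D.condensed(), method=linkage)


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Serialize a linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def cophenetic_distances(Z: np.ndarray, sample_ids) -> DistanceMatrix:
    return DistanceMatrix(list(sample_ids), squareform(hierarchy.cophenet(Z)))


def pca(matrix: MethylationMatrix) -> tuple:
    """PCA of the complete-case proportion matrix via SVD.

    Returns (scores, variance fractions); columns of `scores` are the
    component scores of the samples, variance fractions are non-increasing.
    """
    X = complete_case_proportions(matrix)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return scores, frac


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    seed: int


def anosim(D: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0) -> AnosimResult:
    """Analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (M/2), with
    ranks over all M = n(n-1)/2 pairwise distances.  The permutation
    p-value uses the +1 correction: p = (1 + #{R_perm >= R_obs}) / (1 + n_perm).
    """
    labels = np.asarray(labels)
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise ValueError("ANOSIM needs >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 members")
    d = D.condensed()
    m = len(d)
    # tie-averaged ranks of all pairwise distances
    ranks = rankdata(d)

    n = len(D.sample_ids)
    iu = np.triu_indices(n, k=1)

    def r_stat(lab):
        within = lab[iu[0]] == lab[iu[1]]
        rb = ranks[~within].mean()
        rw = ranks[within].mean()
        return (rb - rw) / (m / 2.0)

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if r_stat(perm) >= r_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return AnosimResult(R=float(r_obs), p_value=float(p), n_permutations=n_perm, seed=seed)
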