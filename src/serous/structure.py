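"""Unsupervised structure checks.

Covariance-matrix PCA (samples as observations, genes as variables),
bivariate-t confidence ellipses for score plots, Euclidean agglomerative
clustering, and most-variable-site selection by value range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io import ExpressionMatrix


@dataclass
class PCAResult:
    scores: pd.DataFrame      # samples x components
    loadings: pd.DataFrame    # genes x components
    var_explained: np.ndarray
    mean: np.ndarray          # per-gene mean used for centering


def pca_covariance(matrix: ExpressionMatrix, genes=None,
                   log2_transform: bool = False) -> PCAResult:
    """PCA via eigendecomposition of the sample covariance matrix.

    Samples are observations and the selected genes are variables; the
    covariance (not correlation) matrix is decomposed, so high-abundance
    genes dominate unless ``log2_transform`` applies log2(x+1) first.  Sign
    convention: each component's largest-magnitude loading is positive.
    """
    if genes is not None:
        matrix = matrix.subset_genes(genes)
    X = matrix.values.to_numpy(dtype=float).T  # samples x genes
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if log2_transform:
        X = np.log2(X + 1.0)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = np.cov(Xc, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    total = eigval.sum()
    if total <= 0:
        raise ValueError("constant matrix: all eigenvalues are zero")
    flip = np.sign(eigvec[np.abs(eigvec).argmax(axis=0), np.arange(eigvec.shape[1])])
    flip[flip == 0] = 1.0
    eigvec = eigvec * flip
    scores = Xc @ eigvec
    comp = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=comp),
        loadings=pd.DataFrame(eigvec, index=matrix.gene_ids, columns=comp),
        var_explained=eigval / total,
        mean=mean,
    )


@dataclass
class Ellipse:
    center: np.ndarray
    axes: np.ndarray   # semi-axis lengths, major first
    angle: float       # radians, major axis vs x-axis
    radius2: float     # squared Mahalanobis radius
    cov: np.ndarray

    def contains(self, points) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        m2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(self.cov), d)
        return m2 <= self.radius2


def confidence_ellipse(scores, level: float = 0.8) -> Ellipse:
    """Confidence ellipse of a 2-D score cloud under a bivariate t model.

    The squared Mahalanobis radius is 2 * F^{-1}(level; 2, n-2), the
    bivariate-t quantile used by the usual score-plot ellipse; at least 3
    points are required for a full-rank covariance.
    """
    pts = np.asarray(scores, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be an n x 2 array")
    n = pts.shape[0]
    if n < 3:
        raise ValueError("need >= 3 points for a confidence ellipse")
    if not 0 <= level < 1:
        raise ValueError("level must be in [0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    r2 = 2.0 * stats.f.ppf(level, 2, n - 2) if level > 0 else 0.0
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    axes = np.sqrt(np.clip(eigval, 0, None) * r2)
    angle = float(np.arctan2(eigvec[1, 0], eigvec[0, 0]))
    return Ellipse(center, axes, angle, float(r2), cov)


def hclust_euclidean(data, axis: str = "samples", linkage: str = "complete"):
    """Agglomerative clustering with Euclidean distances.

    ``data`` is an ExpressionMatrix or DataFrame (rows = genes/sites,
    columns = samples); ``axis`` picks whether samples or sites are
    clustered.  Returns ``(Z, labels)`` where Z is a SciPy linkage matrix.
    """
    df = data.values if isinstance(data, ExpressionMatrix) else data
    X = df.to_numpy(dtype=float)
    labels = list(df.columns) if axis == "samples" else list(df.index)
    if axis == "samples":
        X = X.T
    elif axis != "sites":
        raise ValueError("axis must be 'samples' or 'sites'")
    if np.isnan(X).any():
        raise ValueError("NaN in input; apply the intersection filter first")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    Z = hierarchy.linkage(X, method=linkage, metric="euclidean")
    return Z, labels


def dendrogram_to_newick(Z, labels) -> str:
    """Serialize a linkage matrix as Newick with branch lengths derived from
    merge heights (leaf height 0)."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = rec(node.left, node.dist - node.left.dist)
        right = rec(node.right, node.dist - node.right.dist)
        return f"({left},{right}):{parent_height:.6g}"

    root = f"({rec(tree.left, tree.dist - tree.left.dist)}," \
           f"{rec(tree.right, tree.dist - tree.right.dist)});"
    return root


def cut_two(Z, labels) -> list[set]:
    """Membership of the two clusters below the top split."""
    assignments = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return [
        {lab for lab, a in zip(labels, assignments) if a == c}
        for c in sorted(set(assignments))
    ]


def top_variable_sites(beta: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k sites ranked by value range (max - min) across samples.

    Mirrors the most-variable-CpG selection used ahead of methylation
    clustering; ties are broken by site id for determinism.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > beta.shape[0]:
        raise ValueError(f"k={k} exceeds number of sites {beta.shape[0]}")
    rng_stat = beta.max(axis=1) - beta.min(axis=1)
    order = sorted(beta.index, key=lambda s: (-rng_stat[s], s))
    return beta.loc[order[:k]]
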