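"""Graph clustering on LSI components and Pearson-residual marker statistics.

Markers are ranked by the analytic Pearson residual of cluster-aggregated
counts under a negative binomial null with the dispersion fixed at
theta = 100:

    Z_cg = (X_cg - mu_cg) / sqrt(mu_cg - mu_cg^2 / theta)

where mu_cg = c_tot(c) * g_frac(g) is the expected count given the
cluster's total fragments and the feature's overall fragment fraction.
"""
from __future__ import annotations

import random as _random

import numpy as np
import scipy.sparse as sp
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.neighbors import NearestNeighbors

from ._types import ClusterPartition, LsiEmbedding, NucleusFeatureMatrix, ResidualMatrix


def build_knn(embedding: LsiEmbedding, k: int):
    """Symmetrized k-nearest-neighbour graph under Euclidean distance.

    An undirected edge joins i and j when either lies among the other's k
    nearest; a nucleus is never its own neighbour.
    """
    import igraph

    n = embedding.components.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of nuclei")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding.components)
    _, idx = nn.kneighbors(embedding.components)
    edges = set()
    for i in range(n):
        for j in idx[i]:
            if j != i:
                edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def louvain_cluster(graph, resolution: float = 1.0, seed: int = 0) -> ClusterPartition:
    """Louvain modularity clustering; deterministic under a fixed seed."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    state = _random.getstate()
    try:
        _random.seed(seed)
        part = graph.community_multilevel(resolution=resolution)
    finally:
        _random.setstate(state)
    labels = np.asarray(part.membership, dtype=int)
    return ClusterPartition(labels, modularity=float(part.modularity))


def pearson_residuals(
    matrix: NucleusFeatureMatrix,
    partition: ClusterPartition,
    theta: float = 100.0,
    clamp: float = 30.0,
    variance_form: str = "minus",
) -> ResidualMatrix:
    """Cluster-aggregated Pearson residuals under the dispersion-theta null.

    ``variance_form='minus'`` uses the variance mu - mu^2/theta; entries
    where that variance is non-positive (mu >= theta) are clamped to 0.
    ``'plus'`` switches to the conventional negative binomial variance
    mu + mu^2/theta.  Residuals are clamped to ``|Z| <= clamp``.
    """
    if matrix.normalization != "raw":
        raise ValueError("pearson_residuals requires raw counts")
    labels = partition.labels
    if len(labels) != matrix.shape[0]:
        raise ValueError("partition length mismatch")
    clusters = sorted(np.unique(labels).tolist())
    X = np.zeros((len(clusters), matrix.shape[1]))
    V = sp.csr_matrix(matrix.values)
    for ci, c in enumerate(clusters):
        X[ci] = np.asarray(V[labels == c].sum(axis=0)).ravel()
    c_tot = X.sum(axis=1)
    total = c_tot.sum()
    g_frac = X.sum(axis=0) / total if total > 0 else np.zeros(X.shape[1])
    mu = np.outer(c_tot, g_frac)
    if variance_form == "minus":
        var = mu - mu**2 / theta
    elif variance_form == "plus":
        var = mu + mu**2 / theta
    else:
        raise ValueError("variance_form must be 'minus' or 'plus'")
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (X - mu) / np.sqrt(var)
    Z[~np.isfinite(Z)] = 0.0
    Z[var <= 0] = 0.0
    Z[:, g_frac == 0] = 0.0
    np.clip(Z, -clamp, clamp, out=Z)
    return ResidualMatrix(
        Z=Z, X=X, mu_hat=mu, theta=theta, c_tot=c_tot, g_frac=g_frac,
        clusters=clusters, features=list(matrix.features),
    )


def select_markers(residuals: ResidualMatrix, n: int = 2000) -> dict[int, list[str]]:
    """Per cluster, the ``n`` features with the largest residual.

    Ties break towards the earlier feature in coordinate order.
    """
    if n > len(residuals.features):
        raise ValueError("n exceeds the number of features")
    out = {}
    for ci, c in enumerate(residuals.clusters):
        # stable sort on -Z keeps coordinate order among ties
        order = np.argsort(-residuals.Z[ci], kind="mergesort")[:n]
        out[c] = [residuals.features[i] for i in order]
    return out


def cluster_dendrogram(residuals: ResidualMatrix, top_var: int = 20_000):
    """Hierarchical tree over clusters on the most variable residuals.

    Features are ranked by across-cluster variance of Z; the ``top_var``
    most variable are kept and clusters are merged by average linkage on
    correlation distance.  Returns a scipy linkage matrix (or None for a
    single cluster).
    """
    k = residuals.Z.shape[0]
    if k < 2:
        return None
    var = residuals.Z.var(axis=0)
    idx = np.argsort(-var, kind="mergesort")[: min(top_var, len(var))]
    profiles = residuals.Z[:, idx]
    d = pdist(profiles, metric="correlation")
    d = np.nan_to_num(d, nan=0.0)
    return hierarchy.linkage(d, method="average")


def dendrogram_newick(linkage_matrix, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix to Newick with branch lengths."""
    tree = hierarchy.to_tree(linkage_matrix)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def aggregate_cpm(matrix: NucleusFeatureMatrix, partition: ClusterPartition) -> ResidualMatrix | np.ndarray:
    """Per-cluster counts scaled to one million per cluster."""
    if matrix.normalization != "raw":
        raise ValueError("aggregate_cpm requires raw counts")
    labels = partition.labels
    clusters = sorted(np.unique(labels).tolist())
    V = sp.csr_matrix(matrix.values)
    out = np.zeros((len(clusters), matrix.shape[1]))
    for ci, c in enumerate(clusters):
        row = np.asarray(V[labels == c].sum(axis=0)).ravel()
        tot = row.sum()
        if tot == 0:
            raise ValueError(f"cluster {c} has zero counts")
        out[ci] = row / tot * 1e6
    return out
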