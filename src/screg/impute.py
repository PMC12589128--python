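"""Anchor-net RNA imputation and trinarization scores.

ATAC-only nuclei borrow expression from their 10 nearest multiome
neighbours in the shared LSI embedding: neighbour weights are
inverse-distance, normalized to sum to 1, and applied to the multiome
profiles after scaling every profile to 5,000 UMIs.  Trinarization gives
the posterior probability that a cluster's expressing fraction exceeds a
threshold f0 under a Beta posterior.
"""
from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from ._types import AnchorNet, ClusterPartition, LsiEmbedding, NucleusFeatureMatrix

UMI_TARGET = 5000.0
EPS_DIST = 1e-12


def build_anchor_net(embedding: LsiEmbedding, is_multiome, k: int = 10) -> AnchorNet:
    """k nearest multiome neighbours per nucleus with normalized weights.

    Weights are inverse distance (with a small epsilon guard) scaled to sum
    to 1 per nucleus.  Multiome nuclei also get rows (their nearest
    multiome neighbour is themselves at distance 0, so their own profile
    dominates).
    """
    is_multiome = np.asarray(is_multiome, dtype=bool)
    multi_idx = np.flatnonzero(is_multiome)
    if len(multi_idx) == 0:
        raise ValueError("no multiome nuclei")
    if len(multi_idx) < k:
        warnings.warn(f"only {len(multi_idx)} multiome nuclei; using all as neighbours")
        k = len(multi_idx)
    Z = embedding.components
    nn = NearestNeighbors(n_neighbors=k).fit(Z[multi_idx])
    dist, idx = nn.kneighbors(Z)
    w = 1.0 / (dist + EPS_DIST)
    w /= w.sum(axis=1, keepdims=True)
    return AnchorNet(
        neighbours=idx,
        weights=w,
        nuclei=list(embedding.nuclei),
        multiome_ids=[embedding.nuclei[i] for i in multi_idx],
    )


def impute_expression(net: AnchorNet, rna: NucleusFeatureMatrix) -> NucleusFeatureMatrix:
    """Weighted anchor-neighbour mean of 5,000-UMI-scaled multiome profiles.

    Multiome nuclei end up with (almost exactly) their own scaled profile,
    since their zero-distance self-neighbour carries all the weight.
    """
    rna_index = {b: i for i, b in enumerate(rna.nuclei)}
    missing = [b for b in net.multiome_ids if b not in rna_index]
    if missing:
        raise ValueError(f"RNA matrix missing multiome nuclei: {missing[:3]}...")
    R = sp.csr_matrix(rna.values, dtype=float)
    order = np.array([rna_index[b] for b in net.multiome_ids])
    R = R[order]  # rows aligned with multiome_ids
    tot = np.asarray(R.sum(axis=1)).ravel()
    scale = UMI_TARGET / np.maximum(tot, 1e-300)
    R = sp.diags(scale) @ R
    n, k = net.neighbours.shape
    W = sp.coo_matrix(
        (net.weights.ravel(), (np.repeat(np.arange(n), k), net.neighbours.ravel())),
        shape=(n, len(net.multiome_ids)),
    ).tocsr()
    imputed = W @ R
    # multiome nuclei keep exactly their own scaled profile
    multi_pos = {b: j for j, b in enumerate(net.multiome_ids)}
    own_rows = [i for i, b in enumerate(net.nuclei) if b in multi_pos]
    if own_rows:
        imputed = imputed.tolil()
        for i in own_rows:
            imputed[i] = R[multi_pos[net.nuclei[i]]]
    return NucleusFeatureMatrix(
        imputed.tocsr(), list(net.nuclei), list(rna.features),
        feature_kind="gene", normalization="cpm",
    )


def trinarize(
    expression: NucleusFeatureMatrix,
    partition: ClusterPartition,
    f0: float = 0.2,
    a: float = 1.5,
    b: float = 2.0,
    positive_threshold: float = 0.0,
) -> np.ndarray:
    """Posterior probability that each cluster expresses each gene.

    With f of n nuclei expressing (count > ``positive_threshold``), the
    expressing fraction has a Beta(f + a, n - f + b) posterior; the score
    is P(fraction > f0).  Returns a clusters x genes array in [0, 1].
    """
    labels = partition.labels
    if len(labels) != expression.shape[0]:
        raise ValueError("partition length mismatch")
    clusters = sorted(np.unique(labels).tolist())
    V = sp.csr_matrix(expression.values)
    out = np.zeros((len(clusters), expression.shape[1]))
    for ci, c in enumerate(clusters):
        rows = np.flatnonzero(labels == c)
        if rows.size == 0:
            raise ValueError(f"cluster {c} is empty")
        sub = V[rows]
        f = np.asarray((sub > positive_threshold).sum(axis=0)).ravel()
        n = rows.size
        out[ci] = stats.beta.sf(f0, f + a, n - f + b)
    return out
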