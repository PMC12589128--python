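"""TF-IDF weighting, truncated LSI with component filtering, batch
correction and the two-round iterative LSI.

The embedding workflow is the standard scATAC latent semantic indexing:
depth-normalized term frequencies are reweighted by inverse document
frequency, decomposed by a truncated randomized SVD, and components that
track sequencing depth or that are statistically indistinguishable from
their predecessor are discarded.
"""
from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy import stats
from sklearn.utils.extmath import randomized_svd

from ._types import LsiEmbedding, NucleusFeatureMatrix

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def tfidf_transform(matrix: NucleusFeatureMatrix) -> NucleusFeatureMatrix:
    """Term frequency-inverse document frequency weighting.

    ``value_ij = (count_ij / depth_i) * log(1 + n_nuclei / df_j)`` where
    ``df_j`` is the number of nuclei detecting feature j.  All-zero rows
    stay zero; the sparsity pattern is preserved.
    """
    X = sp.csr_matrix(matrix.values, dtype=float)
    depth = np.asarray(X.sum(axis=1)).ravel()
    if depth.sum() == 0:
        raise ValueError("all-zero matrix cannot be TF-IDF weighted")
    df = np.asarray((X > 0).sum(axis=0)).ravel()
    n = X.shape[0]
    with np.errstate(divide="ignore"):
        idf = np.log1p(n / np.maximum(df, 1e-300))
    idf[df == 0] = 0.0
    inv_depth = np.where(depth > 0, 1.0 / np.maximum(depth, 1), 0.0)
    W = sp.diags(inv_depth) @ X @ sp.diags(idf)
    return NucleusFeatureMatrix(
        W.tocsr(), matrix.nuclei, matrix.features, matrix.feature_kind, normalization="tfidf"
    )


def fit_lsi(
    weighted: NucleusFeatureMatrix,
    n_components: int = 40,
    depth: np.ndarray | None = None,
    seed: int = 0,
    depth_corr_threshold: float = 0.7,
    successor_ks_alpha: float = 0.05,
) -> LsiEmbedding:
    """Truncated decomposition of a TF-IDF matrix with component filtering.

    Components are computed by randomized SVD.  A component is discarded if
    the magnitude of its Spearman correlation with log depth exceeds
    ``depth_corr_threshold``; and from the second component on, if a
    two-sample KS test against the previous retained component's score
    distribution is non-significant (p > ``successor_ks_alpha``) the
    component and all later ones are dropped, on the grounds that the
    spectrum has hit its noise floor.
    """
    X = sp.csr_matrix(weighted.values)
    max_rank = min(X.shape) - 1
    if n_components > max_rank:
        warnings.warn(f"n_components reduced from {n_components} to {max_rank}")
        n_components = max(1, max_rank)
    U, S, _ = randomized_svd(X, n_components=n_components, random_state=seed)
    scores = U * S  # nuclei x d
    if depth is None:
        depth = np.asarray(X.sum(axis=1)).ravel()
    logd = np.log1p(np.asarray(depth, dtype=float))

    kept: list[int] = []
    prev = None
    for j in range(scores.shape[1]):
        rho = stats.spearmanr(scores[:, j], logd).statistic if np.ptp(scores[:, j]) else 0.0
        if abs(rho) > depth_corr_threshold:
            continue
        if prev is not None:
            # raw (uncentred, unscaled) scores: once the spectrum hits its
            # noise floor, successive components become indistinguishable
            p = stats.ks_2samp(scores[:, prev], scores[:, j]).pvalue
            if p > successor_ks_alpha:
                break  # this and all later components discarded
        kept.append(j)
        prev = j
    if not kept:
        kept = [0]
    return LsiEmbedding(
        components=scores[:, kept],
        nuclei=list(weighted.nuclei),
        kept_components=kept,
        feature_ids=list(weighted.features),
        round=1,
    )


def correct_batches(
    embedding: LsiEmbedding,
    batch_labels,
    n_clusters: int = 8,
    n_iter: int = 5,
    seed: int = 0,
    corrector=None,
) -> LsiEmbedding:
    """Equalize per-component batch means by soft-cluster centroid alignment.

    Within each soft cluster, every batch's centroid is pulled onto the
    cluster centroid (an iterated, responsibility-weighted mean shift).
    ``corrector`` may supply an external implementation with signature
    ``(components, batch_labels) -> components``.
    """
    batch_labels = np.asarray(batch_labels)
    if len(batch_labels) != embedding.components.shape[0]:
        raise ValueError("batch labels length mismatch")
    batches = np.unique(batch_labels)
    if len(batches) < 2:
        warnings.warn("single batch: correction is a passthrough")
        return embedding
    if corrector is not None:
        Z = corrector(embedding.components.copy(), batch_labels)
    else:
        Z = embedding.components.copy()
        rng = np.random.default_rng(seed)
        k = min(n_clusters, Z.shape[0])
        centroids = Z[rng.choice(Z.shape[0], size=k, replace=False)]
        for _ in range(n_iter):
            d2 = ((Z[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
            scale = np.median(d2) + 1e-12
            R = np.exp(-d2 / scale)
            R /= R.sum(axis=1, keepdims=True)
            centroids = (R.T @ Z) / np.maximum(R.sum(axis=0)[:, None], 1e-12)
            shift = np.zeros_like(Z)
            for c in range(k):
                w = R[:, c]
                mu_c = (w[:, None] * Z).sum(0) / max(w.sum(), 1e-12)
                for b in batches:
                    m = batch_labels == b
                    wb = w[m]
                    if wb.sum() < 1e-9:
                        continue
                    mu_bc = (wb[:, None] * Z[m]).sum(0) / wb.sum()
                    shift[m] += (w[m] / 1.0)[:, None] * (mu_c - mu_bc)[None, :]
            Z = Z + shift
    out = LsiEmbedding(
        components=Z,
        nuclei=embedding.nuclei,
        kept_components=embedding.kept_components,
        feature_ids=embedding.feature_ids,
        round=embedding.round,
        batch_corrected=True,
    )
    return out


def _is_autosomal(feature_id: str) -> bool:
    chrom = feature_id.rsplit(":", 1)[0] if ":" in feature_id else feature_id
    return chrom not in SEX_CHROMS


def select_top_coverage(matrix: NucleusFeatureMatrix, n_features: int,
                        autosomal_only: bool = True) -> np.ndarray:
    """Indices of the top features by total coverage (autosomes only)."""
    cov = np.asarray(matrix.values.sum(axis=0)).ravel()
    ok = np.ones(len(cov), dtype=bool)
    if autosomal_only:
        ok = np.array([_is_autosomal(f) for f in matrix.features])
    idx = np.flatnonzero(ok)
    order = idx[np.argsort(-cov[idx], kind="mergesort")]
    return np.sort(order[:n_features])


def _subset(matrix: NucleusFeatureMatrix, idx: np.ndarray) -> NucleusFeatureMatrix:
    return NucleusFeatureMatrix(
        matrix.values[:, idx],
        matrix.nuclei,
        [matrix.features[i] for i in idx],
        matrix.feature_kind,
        matrix.normalization,
    )


def iterative_lsi(
    matrix: NucleusFeatureMatrix,
    n_features: int = 20_000,
    clusterer=None,
    n_components: int = 40,
    seed: int = 0,
    theta: float = 100.0,
) -> tuple[LsiEmbedding, np.ndarray]:
    """Two-round iterative LSI.

    Round 1 embeds the top-coverage autosomal features and preclusters the
    nuclei.  Round 2 re-selects the ``n_features`` features with the
    highest variance of precluster-level Pearson residuals and re-embeds.
    Returns the round-2 embedding and the round-2 feature indices.
    """
    from . import cluster_markers as cm
    from ._types import ClusterPartition

    if clusterer is None:
        def clusterer(emb: LsiEmbedding) -> np.ndarray:
            g = cm.build_knn(emb, k=min(15, emb.components.shape[0] - 1))
            return cm.louvain_cluster(g, seed=seed).labels

    idx1 = select_top_coverage(matrix, n_features)
    emb1 = fit_lsi(tfidf_transform(_subset(matrix, idx1)), n_components, seed=seed)
    labels = np.asarray(clusterer(emb1))
    if len(np.unique(labels)) < 2:
        warnings.warn("preclustering found a single cluster; returning round-1 embedding")
        return emb1, idx1

    res = cm.pearson_residuals(matrix, ClusterPartition(labels), theta=theta)
    var = res.Z.var(axis=0)
    auto = np.array([_is_autosomal(f) for f in matrix.features])
    var = np.where(auto, var, -np.inf)
    idx2 = np.sort(np.argsort(-var, kind="mergesort")[:n_features])
    emb2 = fit_lsi(tfidf_transform(_subset(matrix, idx2)), n_components, seed=seed)
    emb2.round = 2
    return emb2, idx2
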