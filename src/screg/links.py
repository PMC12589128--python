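"""Distance-penalized regularized-covariance co-accessibility and cCREs.

Region-region and region-gene links are estimated with a graphical lasso
whose per-entry penalty grows exponentially with genomic distance,
``penalty_ij = lambda * exp(d_ij / d0)``, evaluated in 500-kb windows with
250-kb overlap.  Pairs sampled in two windows must agree in sign and
within 2-fold in magnitude, or they are discarded.  The co-accessibility
score of a pair is the regularized covariance rescaled to a correlation.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from ._types import CoaccessLinkSet, LsiEmbedding, NucleusFeatureMatrix

MAX_LINK_DISTANCE = 500_000


def _soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def _lasso_cd(A: np.ndarray, b: np.ndarray, rho: np.ndarray,
              beta: np.ndarray, max_iter: int = 200, tol: float = 1e-6) -> np.ndarray:
    """Coordinate descent for 0.5 b'Ab - b'beta + sum rho|beta|."""
    p = len(b)
    for _ in range(max_iter):
        delta = 0.0
        for k in range(p):
            r = b[k] - A[k] @ beta + A[k, k] * beta[k]
            new = _soft(r, rho[k]) / A[k, k]
            delta = max(delta, abs(new - beta[k]))
            beta[k] = new
        if delta < tol:
            break
    return beta


def weighted_graphical_lasso(
    S: np.ndarray, penalty: np.ndarray, max_iter: int = 50, tol: float = 1e-4
) -> tuple[np.ndarray, np.ndarray]:
    """Graphical lasso with an elementwise penalty matrix.

    Block coordinate descent over columns of the covariance estimate W;
    returns (W, precision).  ``penalty`` must be symmetric, non-negative,
    with zero diagonal (a diagonal penalty is added to W's diagonal).
    """
    p = S.shape[0]
    S = S + 1e-8 * np.eye(p)  # numerical guard for degenerate windows
    W = S.copy()
    W[np.diag_indices(p)] += penalty.diagonal()
    B = np.zeros((p, p))
    off_scale = np.abs(S - np.diag(np.diag(S))).mean() + 1e-12
    for _ in range(max_iter):
        W_old = W.copy()
        for j in range(p):
            idx = np.arange(p) != j
            W11 = W[np.ix_(idx, idx)]
            beta = _lasso_cd(W11, S[idx, j], penalty[idx, j], B[idx, j].copy())
            B[idx, j] = beta
            w12 = W11 @ beta
            W[idx, j] = w12
            W[j, idx] = w12
        if np.abs(W - W_old).max() < tol * off_scale:
            break
    theta = np.zeros((p, p))
    for j in range(p):
        idx = np.arange(p) != j
        denom = W[j, j] - W[idx, j] @ B[idx, j]
        t22 = 1.0 / max(denom, 1e-12)
        theta[j, j] = t22
        theta[idx, j] = -B[idx, j] * t22
    theta = (theta + theta.T) / 2
    return W, theta


def _normalized_accessibility(matrix: NucleusFeatureMatrix) -> np.ndarray:
    """Depth-normalized log1p accessibility (dense nuclei x features)."""
    X = sp.csr_matrix(matrix.values, dtype=float)
    depth = np.asarray(X.sum(axis=1)).ravel()
    scale = 1e4 / np.maximum(depth, 1)
    X = sp.diags(scale) @ X
    return np.log1p(np.asarray(X.todense()))


def _feature_positions(peaks: pd.DataFrame) -> np.ndarray:
    return ((peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2).astype(np.int64)


def _window_scores(
    data: np.ndarray, positions: np.ndarray, lam: float, d0: float
) -> np.ndarray:
    """Regularized correlation matrix for one window's features."""
    S = np.cov(data, rowvar=False)
    S = np.atleast_2d(S)
    d = np.abs(positions[:, None] - positions[None, :]).astype(float)
    penalty = lam * np.exp(np.minimum(d / d0, 45.0))
    np.fill_diagonal(penalty, 0.0)
    W, _ = weighted_graphical_lasso(S, penalty)
    sd = np.sqrt(np.clip(np.diag(W), 1e-12, None))
    return W / np.outer(sd, sd)


def _heldout_loglik(
    train: np.ndarray, test: np.ndarray, positions: np.ndarray, lam: float, d0: float
) -> float:
    """Gaussian log-likelihood of held-out nuclei under the regularized fit."""
    S_train = np.atleast_2d(np.cov(train, rowvar=False))
    S_test = np.atleast_2d(np.cov(test, rowvar=False))
    d = np.abs(positions[:, None] - positions[None, :]).astype(float)
    penalty = lam * np.exp(np.minimum(d / d0, 45.0))
    np.fill_diagonal(penalty, 0.0)
    _, theta = weighted_graphical_lasso(S_train, penalty)
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    return float(logdet - np.trace(S_test @ theta))


def _calibrate_lambda(
    datas: list[np.ndarray], positions: list[np.ndarray], d0: float,
    target_nonzero: float = 0.05, grid=None,
) -> float:
    """Pick lambda so the mean off-diagonal non-zero precision fraction ~ target."""
    if grid is None:
        grid = np.geomspace(1e-4, 1.0, 9)
    best, best_gap = grid[0], np.inf
    for lam in grid:
        fracs = []
        for X, pos in zip(datas, positions):
            d = np.abs(pos[:, None] - pos[None, :]).astype(float)
            penalty = lam * np.exp(np.minimum(d / d0, 45.0))
            np.fill_diagonal(penalty, 0.0)
            S = np.atleast_2d(np.cov(X, rowvar=False))
            _, theta = weighted_graphical_lasso(S, penalty)
            off = ~np.eye(theta.shape[0], dtype=bool)
            fracs.append((np.abs(theta[off]) > 1e-8).mean())
        gap = abs(np.mean(fracs) - target_nonzero)
        if gap < best_gap:
            best, best_gap = lam, gap
    return float(best)


def _sample_windows(
    matrix: NucleusFeatureMatrix, peaks: pd.DataFrame, n_regions: int,
    window: int, rng: np.random.Generator, min_peaks: int = 3,
):
    """Random windows with their accessibility slices and positions."""
    data = _normalized_accessibility(matrix)
    pos = _feature_positions(peaks)
    chroms = peaks["chrom"].to_numpy()
    out = []
    tries = 0
    while len(out) < n_regions and tries < n_regions * 20:
        tries += 1
        i = int(rng.integers(0, len(peaks)))
        sel = np.flatnonzero((chroms == chroms[i]) & (pos >= pos[i]) & (pos < pos[i] + window))
        if len(sel) < min_peaks:
            continue
        out.append((data[:, sel], pos[sel]))
    if not out:
        raise ValueError("no windows with enough peaks")
    return out


def estimate_distance_param(
    matrix: NucleusFeatureMatrix,
    peaks: pd.DataFrame,
    n_regions: int = 100,
    window: int = MAX_LINK_DISTANCE,
    seed: int = 0,
    d0_grid=None,
    lam: float | None = None,
    lam_grid=None,
) -> tuple[float, float]:
    """Grid-search the distance decay scale d0 and the penalty scale lambda.

    The weighted graphical lasso is fitted on a random half of the nuclei
    for each of ``n_regions`` random windows; the (d0, lambda) pair
    maximizing the mean Gaussian log-likelihood of the held-out half is
    returned.  A d0 that is too small over-penalizes true short-range
    links, one too large lets long-range noise pairs overfit; both hurt
    the held-out fit, giving an interior optimum at the scale where links
    actually live.
    """
    rng = np.random.default_rng(seed)
    windows = _sample_windows(matrix, peaks, n_regions, window, rng)
    datas = [w[0] for w in windows]
    positions = [w[1] for w in windows]
    n_nuclei = datas[0].shape[0]
    perm = rng.permutation(n_nuclei)
    tr, te = perm[: n_nuclei // 2], perm[n_nuclei // 2 :]
    if d0_grid is None:
        d0_grid = np.array([window / 50, window / 20, window / 10, window / 5, window / 2])
    if lam is not None:
        lam_grid = [lam]
    elif lam_grid is None:
        lam_grid = np.geomspace(1e-3, 0.1, 5)
    best_d0, best_ll, best_lam = None, -np.inf, None
    for d0 in d0_grid:
        for lam_d in lam_grid:
            ll = np.mean(
                [_heldout_loglik(X[tr], X[te], p, lam_d, d0)
                 for X, p in zip(datas, positions)]
            )
            if ll > best_ll:
                best_d0, best_ll, best_lam = float(d0), ll, float(lam_d)
    return best_d0, best_lam


def coaccess_scan(
    matrix: NucleusFeatureMatrix,
    peaks: pd.DataFrame,
    d0: float,
    lam: float,
    window: int = MAX_LINK_DISTANCE,
    step: int = MAX_LINK_DISTANCE // 2,
    data: np.ndarray | None = None,
    positions: np.ndarray | None = None,
    feature_names: list[str] | None = None,
    min_peaks: int = 3,
) -> CoaccessLinkSet:
    """Windowed distance-penalized covariance scan over sorted peaks.

    Pairs estimated in two overlapping windows are kept only when both
    estimates agree in sign and differ by less than 2-fold in magnitude
    (the scores are then averaged); inconsistent pairs are discarded.
    """
    if data is None:
        data = _normalized_accessibility(matrix)
    if positions is None:
        positions = _feature_positions(peaks)
    if feature_names is None:
        feature_names = list(matrix.features)
    chroms = peaks["chrom"].to_numpy()
    estimates: dict[tuple[int, int], list[tuple[float, int]]] = {}
    win_id = 0
    for chrom in pd.unique(chroms):
        csel = np.flatnonzero(chroms == chrom)
        cpos = positions[csel]
        lo, hi = int(cpos.min()), int(cpos.max())
        start = lo - (lo % step)
        while start <= hi:
            sel = csel[(cpos >= start) & (cpos < start + window)]
            start += step
            win_id += 1
            if len(sel) < min_peaks:
                continue
            R = _window_scores(data[:, sel], positions[sel], lam, d0)
            for a in range(len(sel)):
                for b in range(a + 1, len(sel)):
                    key = (int(sel[a]), int(sel[b]))
                    estimates.setdefault(key, []).append((float(R[a, b]), win_id))
    rows = []
    n_discarded = 0
    for (i, j), ests in estimates.items():
        scores = [e[0] for e in ests]
        wins = [e[1] for e in ests]
        if len(scores) > 1:
            mags = [abs(s) for s in scores]
            signs = {np.sign(s) for s in scores if abs(s) > 1e-10}
            consistent = len(signs) <= 1 and (
                max(mags) < 1e-10 or max(mags) / max(min(mags), 1e-300) < 2.0
            )
            if not consistent:
                n_discarded += 1
                continue
            score = float(np.mean(scores))
        else:
            score = scores[0]
        rows.append(
            (
                feature_names[i],
                feature_names[j],
                score,
                int(abs(positions[j] - positions[i])),
                len(wins),
            )
        )
    links = pd.DataFrame(rows, columns=["a", "b", "score", "distance", "n_windows"])
    links.attrs["n_discarded"] = n_discarded
    links.attrs["n_pairs"] = len(estimates)
    return CoaccessLinkSet(links, kind="region-region")


def choose_cutoff(links: CoaccessLinkSet, grid=None, rise_fraction: float = 0.5) -> float:
    """Threshold from the component-count-vs-cutoff curve.

    Nodes are all features of the unthresholded link set, so raising the
    cutoff can only disconnect and the component count is non-decreasing.
    In a two-regime link set the curve rises steeply while noise edges
    drop out, then plateaus across the score gap before true links start
    breaking; the cutoff is the start of the longest flat stretch after
    the curve has climbed ``rise_fraction`` of its total rise.  A flat
    curve falls back to the median threshold with a warning.
    """
    import igraph

    df = links.links
    if not len(df):
        raise ValueError("empty link set")
    mags = np.abs(df["score"].to_numpy())
    if grid is None:
        top = mags.max()
        if top <= 0:
            raise ValueError("all scores are zero")
        # log-spaced grid over the informative magnitude range; scores below
        # 1e-4 x max are numerical dust from the regularized estimate
        grid = np.geomspace(max(mags[mags > 0].min(), 1e-4 * top), top, 25)
    grid = np.sort(np.asarray(grid, dtype=float))
    nodes = sorted(set(df["a"]) | set(df["b"]))
    nidx = {n: i for i, n in enumerate(nodes)}
    counts = []
    for t in grid:
        sub = df[np.abs(df["score"]) >= t]
        g = igraph.Graph(
            n=len(nodes),
            edges=[(nidx[a], nidx[b]) for a, b in zip(sub["a"], sub["b"])],
        )
        counts.append(len(g.connected_components()))
    counts = np.asarray(counts, dtype=float)
    if np.ptp(counts) == 0:
        warnings.warn("flat component curve; using median threshold")
        return float(np.median(grid))
    floor = counts[0] + rise_fraction * np.ptp(counts)
    best_start, best_len = None, 0
    run_start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[run_start]:
            run_len = i - run_start
            if counts[run_start] >= floor and run_len > best_len:
                best_start, best_len = run_start, run_len
            run_start = i
    if best_start is None:  # no flat stretch above the floor: steepest-rise knee
        return float(grid[int(np.argmax(np.diff(counts)))])
    return float(grid[best_start])


def gene_activity(
    matrix: NucleusFeatureMatrix,
    tss_links: CoaccessLinkSet,
    embedding: LsiEmbedding | None = None,
    nn: int = 25,
    depth: np.ndarray | None = None,
) -> NucleusFeatureMatrix:
    """Link-weighted accessibility as a per-nucleus gene activity score.

    Raw activity is the peak-by-nucleus matrix times the non-negative
    link-score matrix; size factors come from an OLS fit of log1p(total
    activity) on log(depth); activities are then pooled over the ``nn``
    nearest neighbours in the embedding.
    """
    import statsmodels.api as sm

    if tss_links.kind not in ("region-tss", "region-gene-expression"):
        raise ValueError("tss_links must be region-tss links")
    df = tss_links.links
    genes = sorted(set(df["b"]))
    gidx = {g: i for i, g in enumerate(genes)}
    fidx = {f: i for i, f in enumerate(matrix.features)}
    rows, cols, vals = [], [], []
    for a, b, s in zip(df["a"], df["b"], df["score"]):
        if s > 0 and a in fidx:
            rows.append(fidx[a])
            cols.append(gidx[b])
            vals.append(float(s))
    L = sp.coo_matrix((vals, (rows, cols)), shape=(len(matrix.features), len(genes))).tocsr()
    A = sp.csr_matrix(matrix.values, dtype=float) @ L
    A = np.asarray(A.todense())
    if depth is None:
        depth = matrix.depth()
    total = A.sum(axis=1)
    X = sm.add_constant(np.log(np.maximum(depth, 1)))
    fit = sm.OLS(np.log1p(total), X).fit()
    sf = np.exp(fit.fittedvalues)
    sf = sf / np.exp(np.mean(np.log(np.maximum(sf, 1e-300))))
    A = A / sf[:, None]
    if embedding is not None and nn > 1:
        k = min(nn, A.shape[0])
        knn = NearestNeighbors(n_neighbors=k).fit(embedding.components)
        _, idx = knn.kneighbors(embedding.components)
        A = A[idx].mean(axis=1)
    return NucleusFeatureMatrix(
        sp.csr_matrix(A), list(matrix.nuclei), genes,
        feature_kind="gene", normalization="cpm",
    )


def link_ccres(
    matrix: NucleusFeatureMatrix,
    rna: NucleusFeatureMatrix,
    peaks: pd.DataFrame,
    gene_tss: pd.DataFrame,
    d0: float,
    lam: float,
    window: int = MAX_LINK_DISTANCE,
    step: int = MAX_LINK_DISTANCE // 2,
    cutoff: float = 0.0,
) -> CoaccessLinkSet:
    """Region-gene-expression links (cCREs) from joint windowed covariance.

    Gene expression vectors (5,000-UMI scaled, log1p) are placed at their
    TSS and joined to the peak accessibility features over the multiome
    nuclei; the same windowed regularized-covariance machinery then scores
    region-gene pairs, and pairs above ``cutoff`` are reported.
    """
    shared = [b for b in matrix.nuclei if b in set(rna.nuclei)]
    if not shared:
        raise ValueError("no multiome nuclei shared between ATAC and RNA matrices")
    aidx = {b: i for i, b in enumerate(matrix.nuclei)}
    ridx = {b: i for i, b in enumerate(rna.nuclei)}
    arow = [aidx[b] for b in shared]
    rrow = [ridx[b] for b in shared]
    acc = _normalized_accessibility(matrix)[arow]
    R = sp.csr_matrix(rna.values, dtype=float)[rrow]
    tot = np.asarray(R.sum(axis=1)).ravel()
    R = sp.diags(5000.0 / np.maximum(tot, 1)) @ R
    expr = np.log1p(np.asarray(R.todense()))

    tss = gene_tss.set_index("name")
    gene_names = [g for g in rna.features if g in tss.index]
    gsel = [i for i, g in enumerate(rna.features) if g in tss.index]
    gpos = tss.loc[gene_names, "start"].to_numpy(dtype=np.int64)
    gchrom = tss.loc[gene_names, "chrom"].to_numpy()

    ppos = _feature_positions(peaks)
    pchrom = peaks["chrom"].to_numpy()
    data = np.concatenate([acc, expr[:, gsel]], axis=1)
    positions = np.concatenate([ppos, gpos])
    chroms = np.concatenate([pchrom, gchrom])
    names = list(matrix.features) + [f"gene:{g}" for g in gene_names]
    pseudo_peaks = pd.DataFrame(
        {"chrom": chroms, "start": positions, "end": positions + 1}
    )
    scan = coaccess_scan(
        matrix, pseudo_peaks, d0, lam, window=window, step=step,
        data=data, positions=positions, feature_names=names,
    )
    df = scan.links
    is_gene_a = df["a"].str.startswith("gene:")
    is_gene_b = df["b"].str.startswith("gene:")
    mixed = df[is_gene_a ^ is_gene_b].copy()
    # orient as (region, gene)
    a = np.where(is_gene_a[mixed.index], mixed["b"], mixed["a"])
    b = np.where(is_gene_a[mixed.index], mixed["a"], mixed["b"])
    mixed["a"], mixed["b"] = a, [g.removeprefix("gene:") for g in b]
    mixed = mixed[mixed["score"] > cutoff].reset_index(drop=True)
    out = CoaccessLinkSet(mixed, kind="region-gene-expression", cutoff=cutoff)
    out.links.attrs.update(scan.links.attrs)
    return out
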