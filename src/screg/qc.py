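"""Per-nucleus and per-sample quality control.

TSS enrichment follows the standard calculator: insertion density in a
50-bp window centred on each TSS relative to the density in the outermost
100 bp of the +/-1,000-bp flanks.  Doublets are detected by co-embedding
real nuclei with 20% artificial doublets (summed random pairs) and scoring
each nucleus by the artificial fraction among its nearest neighbours.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from ._types import FragmentTable, NucleusFeatureMatrix
from .dimred import fit_lsi, tfidf_transform

TSS_HALF_WINDOW = 25  # the 50-bp TSS window
FLANK = 1000
FLANK_EDGE = 100  # outermost bases of each flank used as background
MAX_TSS_SCORE = 100.0  # cap when the flank density is zero

FRAGMENT_MIN = 5_000
FRAGMENT_MAX = 100_000
TSS_FRACTION_MIN = 0.20
RNA_UMI_MIN = 1_000
UNSPLICED_MIN = 0.10
SAMPLE_TSS_MIN = 5.0
Y_FRACTION_MALE = 0.0005


def _insertions(table: FragmentTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Both ends of every fragment as insertion events (chrom, pos, barcode idx)."""
    df = table.records
    chrom = np.concatenate([df["chrom"].to_numpy()] * 2)
    pos = np.concatenate([df["start"].to_numpy(), df["end"].to_numpy() - 1])
    bc = np.concatenate([df["barcode"].to_numpy()] * 2)
    return chrom, pos, bc


def tss_enrichment(
    fragments: FragmentTable, tss: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Per-nucleus TSS metrics and the per-sample enrichment score.

    Returns a frame indexed by barcode with columns ``n_fragments``,
    ``tss_fraction`` (fraction of fragments overlapping TSS +/- 1 kb) and
    ``tss_score`` (insertion density in TSS +/- 25 bp over density in the
    outermost 100 bp of the +/- 1 kb flanks), plus the depth-weighted mean
    sample score.  Samples scoring below 5 should be discarded.
    """
    if not len(tss):
        raise ValueError("need at least one TSS")
    df = fragments.records
    barcodes = pd.Index(sorted(df["barcode"].unique()))
    n_frag = df.groupby("barcode")["count"].sum().reindex(barcodes, fill_value=0)

    centre = np.zeros(len(barcodes))
    edge = np.zeros(len(barcodes))
    bidx = {b: i for i, b in enumerate(barcodes)}

    chrom_arr, pos_arr, bc_arr = _insertions(fragments)
    bi = np.array([bidx[b] for b in bc_arr])
    for chrom, grp in tss.groupby("chrom"):
        m = chrom_arr == chrom
        if not m.any():
            continue
        pos = pos_arr[m]
        rows = bi[m]
        starts = np.sort(grp["start"].to_numpy())
        # distance to the nearest TSS
        j = np.searchsorted(starts, pos)
        left = np.abs(pos - starts[np.clip(j - 1, 0, len(starts) - 1)])
        right = np.abs(starts[np.clip(j, 0, len(starts) - 1)] - pos)
        dist = np.minimum(left, right)
        np.add.at(centre, rows[dist <= TSS_HALF_WINDOW], 1)
        in_edge = (dist > FLANK - FLANK_EDGE) & (dist <= FLANK)
        np.add.at(edge, rows[in_edge], 1)

    centre_density = centre / (2 * TSS_HALF_WINDOW + 1)
    edge_density = edge / (2 * FLANK_EDGE)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = centre_density / edge_density
    score[(edge == 0) & (centre > 0)] = MAX_TSS_SCORE
    score[(edge == 0) & (centre == 0)] = 0.0
    # tss_fraction counts fragments (not insertions) with either end near a TSS
    half = len(df)
    frag_near = np.zeros(len(barcodes))
    frag_mask = np.zeros(2 * half, dtype=bool)
    for chrom, grp in tss.groupby("chrom"):
        m = chrom_arr == chrom
        if not m.any():
            continue
        starts = np.sort(grp["start"].to_numpy())
        pos = pos_arr[m]
        j = np.searchsorted(starts, pos)
        left = np.abs(pos - starts[np.clip(j - 1, 0, len(starts) - 1)])
        right = np.abs(starts[np.clip(j, 0, len(starts) - 1)] - pos)
        frag_mask[np.flatnonzero(m)] = np.minimum(left, right) <= FLANK
    either = frag_mask[:half] | frag_mask[half:]
    np.add.at(frag_near, bi[:half][either], 1)
    tss_fraction = frag_near / np.maximum(n_frag.to_numpy(), 1)

    out = pd.DataFrame(
        {
            "n_fragments": n_frag.to_numpy(),
            "tss_fraction": tss_fraction,
            "tss_score": score,
        },
        index=barcodes,
    )
    weights = out["n_fragments"].to_numpy().astype(float)
    if weights.sum() == 0 or (centre.sum() == 0 and edge.sum() == 0):
        warnings.warn("no fragments near any TSS; sample score set to 0")
        sample_score = 0.0
    else:
        sample_score = float(np.average(score, weights=np.maximum(weights, 1)))
    return out, sample_score


def detect_doublets(
    matrix: NucleusFeatureMatrix,
    spike_fraction: float = 0.20,
    k: int = 10,
    expected_rate: float = 0.05,
    seed: int = 0,
    n_components: int = 20,
) -> pd.DataFrame:
    """Score doublets by co-embedding with artificial doublets.

    ``round(spike_fraction * n)`` artificial profiles are formed by summing
    the counts of random nucleus pairs; a joint TF-IDF/LSI embedding is
    built and each real nucleus is scored by the fraction of artificial
    doublets among its ``k`` nearest neighbours.  The call threshold is set
    so the called fraction among real nuclei equals ``expected_rate``.
    """
    n = matrix.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of nuclei")
    rng = np.random.default_rng(seed)
    n_art = int(round(spike_fraction * n))
    pairs = rng.integers(0, n, size=(n_art, 2))
    V = sp.csr_matrix(matrix.values)
    art = V[pairs[:, 0]] + V[pairs[:, 1]]
    joint = sp.vstack([V, art]).tocsr()
    joint_m = NucleusFeatureMatrix(
        joint,
        list(matrix.nuclei) + [f"art_{i}" for i in range(n_art)],
        matrix.features,
        matrix.feature_kind,
    )
    emb = fit_lsi(tfidf_transform(joint_m), n_components=min(n_components, joint.shape[0] - 1),
                  seed=seed)
    Z = emb.components
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z)
    _, idx = nn.kneighbors(Z[:n])
    is_art = idx[:, 1:] >= n  # drop self (column 0)
    score = is_art.mean(axis=1)
    if expected_rate <= 0:
        called = np.zeros(n, dtype=bool)
    else:
        n_call = int(round(expected_rate * n))
        order = np.argsort(-score, kind="mergesort")
        called = np.zeros(n, dtype=bool)
        called[order[:n_call]] = True
    out = pd.DataFrame(
        {"doublet_score": score, "is_doublet": called}, index=matrix.nuclei
    )
    out.attrs["n_artificial"] = n_art
    return out


def infer_sex(
    fragments: FragmentTable, y_chrom: str = "chrY", chrom_names=None
) -> str:
    """Call sample sex from the Y-chromosome fragment fraction (> 0.05% male)."""
    if chrom_names is not None and y_chrom not in chrom_names:
        warnings.warn(f"{y_chrom} absent from genome table; sex ambiguous")
        return "ambiguous"
    df = fragments.records
    total = df["count"].sum()
    if total == 0:
        return "ambiguous"
    y = df.loc[df["chrom"] == y_chrom, "count"].sum()
    return "male" if y / total > Y_FRACTION_MALE else "female"


def qc_filter(qc: pd.DataFrame, is_multiome: bool = False) -> pd.Series:
    """Pass mask over nuclei given the fixed QC thresholds.

    ATAC: not a doublet, 5,000 < fragments < 100,000, TSS fraction > 20%.
    Multiome additionally: > 1,000 RNA UMIs and >= 10% unspliced UMIs.
    """
    required = ["n_fragments", "tss_fraction", "is_doublet"]
    if is_multiome:
        required += ["rna_umis", "unspliced_fraction"]
    missing = [c for c in required if c not in qc.columns]
    if missing:
        raise ValueError(f"QC table missing columns: {missing}")
    ok = (
        ~qc["is_doublet"].astype(bool)
        & (qc["n_fragments"] > FRAGMENT_MIN)
        & (qc["n_fragments"] < FRAGMENT_MAX)
        & (qc["tss_fraction"] > TSS_FRACTION_MIN)
    )
    if is_multiome:
        ok &= (qc["rna_umis"] > RNA_UMI_MIN) & (qc["unspliced_fraction"] >= UNSPLICED_MIN)
    return ok
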