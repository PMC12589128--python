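"""Preclustering, split-and-pool pseudobulk peak calling and 400-bp
consensus peaks.

The caller is a simplified fixed-parameter analogue of the usual
pseudobulk workflow: every fragment end is shifted by -100 and extended
200 bp, the base-pair pileup is tested against a global Poisson rate, and
BH-significant bases are merged into peaks.  Peaks reproducible between
two random pseudobulk replicates are re-centred and fixed at 400 bp to
form the consensus set.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._types import ConsensusPeakSet, FragmentTable, PeakSet
from .dimred import SEX_CHROMS, fit_lsi, tfidf_transform
from .io import overlaps
from .synth import bin_matrix

PEAK_WIDTH = 400
MERGE_GAP = 30
PSEUDOBULK_CAP = 25_000_000


def precluster(
    fragments: FragmentTable,
    bin_size: int = 20_000,
    chrom_lengths: dict[str, int] | None = None,
    top_fraction: float = 0.20,
    max_detection: float = 0.60,
    k: int = 25,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Broad cluster labels from genomic-bin LSI.

    Bins are temporary features: the top ``top_fraction`` of autosomal bins
    by coverage are kept, excluding bins detected in more than
    ``max_detection`` of nuclei, then TF-IDF + LSI + kNN + Louvain.
    Returns labels aligned to the sorted barcode order of the bin matrix.
    """
    from . import cluster_markers as cm

    if fragments.records["barcode"].nunique() < 2:
        raise ValueError("need at least 2 nuclei")
    if chrom_lengths is None:
        chrom_lengths = (
            fragments.records.groupby("chrom")["end"].max().astype(int).to_dict()
        )
    mat = bin_matrix(fragments, bin_size, chrom_lengths)
    cov = np.asarray(mat.values.sum(axis=0)).ravel()
    det = np.asarray((mat.values > 0).mean(axis=0)).ravel()
    auto = np.array(
        [f.rsplit(":", 1)[0] not in SEX_CHROMS for f in mat.features]
    )
    eligible = np.flatnonzero(auto & (det <= max_detection) & (cov > 0))
    if len(eligible) == 0:
        warnings.warn("no bins under the detection ceiling; ignoring it")
        eligible = np.flatnonzero(auto & (cov > 0))
    n_keep = max(2, int(round(top_fraction * auto.sum())))
    if len(eligible) < n_keep:
        warnings.warn("fewer eligible bins than requested; using all")
        n_keep = len(eligible)
    keep = eligible[np.argsort(-cov[eligible], kind="mergesort")[:n_keep]]
    sub = mat.values[:, np.sort(keep)]
    from ._types import NucleusFeatureMatrix

    sel = NucleusFeatureMatrix(
        sub, mat.nuclei, [mat.features[i] for i in np.sort(keep)], "bin"
    )
    emb = fit_lsi(tfidf_transform(sel), n_components=min(40, sub.shape[0] - 1), seed=seed)
    g = cm.build_knn(emb, k=min(k, emb.components.shape[0] - 1))
    return cm.louvain_cluster(g, resolution=resolution, seed=seed).labels


def make_pseudobulks(
    fragments: FragmentTable,
    labels,
    cap: int = PSEUDOBULK_CAP,
    seed: int = 0,
) -> dict[int, tuple[FragmentTable, FragmentTable]]:
    """Two pseudobulk replicate fragment pools per cluster.

    ``labels`` maps barcode -> cluster.  Nuclei of each cluster are
    randomly halved; each half's fragments are pooled and pools above
    ``cap`` fragments are downsampled uniformly without replacement.
    """
    labels = dict(labels) if not isinstance(labels, dict) else labels
    rng = np.random.default_rng(seed)
    df = fragments.records
    out: dict[int, tuple[FragmentTable, FragmentTable]] = {}
    for cluster in sorted(set(labels.values())):
        nuclei = sorted(b for b, c in labels.items() if c == cluster)
        if not nuclei:
            raise ValueError(f"cluster {cluster} is empty")
        if len(nuclei) == 1:
            warnings.warn(f"cluster {cluster} has one nucleus; replicates share it")
            halves = [nuclei, nuclei]
        else:
            perm = rng.permutation(len(nuclei))
            half = len(nuclei) // 2
            halves = [
                [nuclei[i] for i in perm[:half]],
                [nuclei[i] for i in perm[half:]],
            ]
        reps = []
        for h in halves:
            pool = df[df["barcode"].isin(set(h))].reset_index(drop=True)
            if len(pool) > cap:
                keep = rng.choice(len(pool), size=cap, replace=False)
                pool = pool.iloc[np.sort(keep)].reset_index(drop=True)
            reps.append(FragmentTable(pool, fragments.sample_id, sorted=False))
        out[cluster] = (reps[0], reps[1])
    return out


def call_peaks(
    pool: FragmentTable,
    genome_size: int,
    shift: int = 100,
    ext: int = 200,
    qval: float = 0.05,
    merge_gap: int = MERGE_GAP,
) -> PeakSet:
    """Poisson pileup peak caller with fixed shift/extension.

    Each fragment end is an insertion event placed at ``position - shift``
    and extended ``ext`` bases.  The per-base pileup is compared with the
    global rate lambda = total extended coverage / genome_size; per-base
    Poisson upper-tail p-values are BH-adjusted over the genome and bases
    with q < ``qval`` are merged into peaks (gap <= ``merge_gap``).  The
    summit is the leftmost pileup argmax.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    df = pool.records
    if not len(df):
        return PeakSet(pd.DataFrame(columns=["chrom", "start", "end", "summit"]))
    pileups: dict[str, np.ndarray] = {}
    total_cov = 0
    for chrom, grp in df.groupby("chrom", observed=True):
        events = np.concatenate(
            [grp["start"].to_numpy(), grp["end"].to_numpy() - 1]
        )
        counts = np.concatenate([grp["count"].to_numpy()] * 2)
        starts = np.maximum(events - shift, 0)
        ends = starts + ext
        size = int(ends.max()) + 1
        diff = np.zeros(size + 1)
        np.add.at(diff, starts, counts)
        np.add.at(diff, ends, -counts)
        pileups[chrom] = np.cumsum(diff)[:-1]
        total_cov += int((counts * (ends - starts)).sum())
    lam = total_cov / genome_size

    # BH over genome_size bases using the pileup-level histogram
    levels = np.unique(np.concatenate([np.unique(p) for p in pileups.values()]))
    level_counts = {
        lv: sum(int((p == lv).sum()) for p in pileups.values()) for lv in levels
    }
    covered = sum(level_counts[lv] for lv in levels if lv > 0)
    n_zero = genome_size - covered  # uncovered bases have pileup 0
    pvals = {lv: stats.poisson.sf(lv - 1, lam) if lv > 0 else 1.0 for lv in levels}
    # rank of a level's p-value = number of bases with p <= it (higher pileup);
    # step-up: q = cumulative min of p*m/rank taken from the largest p downward
    order = sorted(levels, reverse=True)
    cum = 0
    raw = []
    for lv in order:
        cum += level_counts[lv] + (n_zero if lv == 0 else 0)
        raw.append(pvals[lv] * genome_size / cum)
    qmap = {}
    best = np.inf
    for lv, q in zip(reversed(order), reversed(raw)):
        best = min(best, q)
        qmap[lv] = best
    sig_levels = [lv for lv in levels if lv > 0 and qmap[lv] < qval]
    if not sig_levels:
        return PeakSet(pd.DataFrame(columns=["chrom", "start", "end", "summit"]))
    threshold = min(sig_levels)

    rows = []
    for chrom in sorted(pileups):
        p = pileups[chrom]
        sig = p >= threshold
        if not sig.any():
            continue
        idx = np.flatnonzero(sig)
        breaks = np.flatnonzero(np.diff(idx) > merge_gap + 1)
        starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
        for s, e in zip(starts, ends):
            summit = s + int(np.argmax(p[s:e]))
            rows.append((chrom, int(s), int(e), summit))
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "summit"]))


def _extend_to_width(
    peaks: pd.DataFrame, anchor: np.ndarray, width: int,
    chrom_lengths: dict[str, int] | None,
) -> pd.DataFrame:
    start = anchor - width // 2
    end = start + width
    out = peaks.copy()
    out["start"], out["end"] = start, end
    keep = out["start"] >= 0
    if chrom_lengths:
        lim = out["chrom"].map(chrom_lengths)
        keep &= out["end"] <= lim.fillna(np.inf)
    return out.loc[keep].reset_index(drop=True)  # clipped peaks discarded


def reproducible_peaks(
    rep1: PeakSet, rep2: PeakSet, chrom_lengths: dict[str, int] | None = None
) -> PeakSet:
    """Peaks of rep1, fixed at 400 bp around the summit, that overlap rep2."""
    if not len(rep1) or not len(rep2):
        return PeakSet(pd.DataFrame(columns=["chrom", "start", "end", "summit"]))
    p1 = _extend_to_width(
        rep1.peaks, rep1.peaks["summit"].to_numpy(), PEAK_WIDTH, chrom_lengths
    )
    keep = overlaps(p1, rep2.peaks)
    return PeakSet(p1.loc[keep].reset_index(drop=True))


def consensus_peaks(
    cluster_peaksets: list[PeakSet],
    blacklist: pd.DataFrame | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> ConsensusPeakSet:
    """Pool per-cluster peaks into a fixed-width consensus set.

    Pooled peaks are grouped into connected components of pairwise overlap;
    each group is replaced by a 400-bp peak centred on the floor-midpoint
    of the group's merged span.  Consensus peaks overlapping the blacklist
    or extending beyond chromosome bounds are removed.
    """
    frames = [ps.peaks.assign(source=i) for i, ps in enumerate(cluster_peaksets) if len(ps)]
    if not frames:
        raise ValueError("need at least one non-empty peak set")
    pooled = pd.concat(frames, ignore_index=True).sort_values(
        ["chrom", "start", "end"], kind="mergesort"
    )
    rows = []
    sources = []
    for chrom, grp in pooled.groupby("chrom"):
        span_start = span_end = None
        members: set[int] = set()
        for s, e, src in zip(grp["start"], grp["end"], grp["source"]):
            if span_end is None or s < span_end:  # overlaps current component
                span_start = s if span_start is None else span_start
                span_end = e if span_end is None else max(span_end, e)
                members.add(int(src))
            else:
                rows.append((chrom, span_start, span_end))
                sources.append(sorted(members))
                span_start, span_end, members = s, e, {int(src)}
        if span_end is not None:
            rows.append((chrom, span_start, span_end))
            sources.append(sorted(members))
    centre = np.array([(s + e) // 2 for _, s, e in rows])
    out = pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "start": centre - PEAK_WIDTH // 2,
            "end": centre - PEAK_WIDTH // 2 + PEAK_WIDTH,
        }
    )
    keep = out["start"] >= 0
    if chrom_lengths:
        lim = out["chrom"].map(chrom_lengths)
        keep &= out["end"] <= lim.fillna(np.inf)
    if blacklist is not None and len(blacklist):
        keep &= ~overlaps(out, blacklist)
    keep = keep.to_numpy()
    out = out.loc[keep].reset_index(drop=True)
    out["name"] = [f"peak_{i}" for i in range(len(out))]
    src_kept = [s for s, k in zip(sources, keep) if k]
    return ConsensusPeakSet(out, source_clusters=src_kept)


def annotate_peaks(
    consensus: ConsensusPeakSet,
    tss: pd.DataFrame | None,
    gene_model: pd.DataFrame | None = None,
    promoter_distance: int = 2000,
) -> pd.DataFrame:
    """Promoter/distal and exonic/intronic/intergenic annotation per peak.

    A peak is a promoter when its centre lies within ``promoter_distance``
    bp of any TSS, else distal.  Genic category follows the precedence
    exon > intron > intergenic on any overlap.  ``gene_model`` needs a
    ``kind`` column with values 'exon' / 'intron'.
    """
    peaks = consensus.peaks
    centre = (peaks["start"].to_numpy() + peaks["end"].to_numpy()) // 2
    if tss is None or not len(tss):
        warnings.warn("no TSS provided; all peaks annotated distal")
        promoter = np.zeros(len(peaks), dtype=bool)
    else:
        promoter = np.zeros(len(peaks), dtype=bool)
        for chrom, grp in tss.groupby("chrom"):
            m = (peaks["chrom"] == chrom).to_numpy()
            if not m.any():
                continue
            starts = np.sort(grp["start"].to_numpy())
            c = centre[m]
            j = np.searchsorted(starts, c)
            left = np.abs(c - starts[np.clip(j - 1, 0, len(starts) - 1)])
            right = np.abs(starts[np.clip(j, 0, len(starts) - 1)] - c)
            promoter[m] = np.minimum(left, right) <= promoter_distance
    genic = np.full(len(peaks), "intergenic", dtype=object)
    if gene_model is not None and len(gene_model):
        for kind in ("intron", "exon"):  # exon applied last wins precedence
            sub = gene_model[gene_model["kind"] == kind]
            if len(sub):
                hit = overlaps(peaks, sub)
                genic[hit] = "intronic" if kind == "intron" else "exonic"
    return pd.DataFrame(
        {
            "name": peaks["name"] if "name" in peaks else np.arange(len(peaks)),
            "promoter_distal": np.where(promoter, "promoter", "distal"),
            "genic": genic,
        }
    )
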