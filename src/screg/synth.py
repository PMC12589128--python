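"""Synthetic single-cell chromatin fixtures with known ground truth.

Generates random genomes, 400-bp enhancer regions carrying planted
class-specific motifs, per-nucleus fragment tables with cluster structure,
batch effects and true doublets, and multiome RNA whose expression covaries
with linked regions.  Every stage of the pipeline can be exercised against
the recorded truth without external data.

What is emulated: clustered nuclei with cluster-specific accessible
regions, log-normal depth variation, multiplicative per-batch jitter on
region weights, doublets formed as unions of two parent profiles, and
region-linked gene expression.  What is not: realistic fragment-length
periodicity, chromatin contact structure, or sequencing error.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._types import FragmentTable, NucleusFeatureMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class GenomeFixture:
    """A random genome: i.i.d. bases at a target GC fraction."""

    chrom_names: list[str]
    chrom_lengths: list[int]
    sequence: dict[str, str]
    seed: int

    def __post_init__(self) -> None:
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if len(self.sequence[name]) != length:
                raise ValueError(f"{name}: sequence length != declared length")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    genome: GenomeFixture
    regions: pd.DataFrame  # chrom, start, end, name, class
    class_of_region: dict[str, int]
    planted_motifs: dict[int, dict]  # class -> {consensus, positions: [(region, offset)]}
    cluster_of_nucleus: dict[str, int] = field(default_factory=dict)
    doublet_flags: dict[str, bool] = field(default_factory=dict)
    batch_of_nucleus: dict[str, int] = field(default_factory=dict)
    is_multiome: dict[str, bool] = field(default_factory=dict)
    true_links: set = field(default_factory=set)  # (region_name, gene)
    gene_tss: pd.DataFrame | None = None


@dataclass
class MultiomeRna:
    """Simulated multiome RNA counts with the spliced/unspliced split."""

    matrix: NucleusFeatureMatrix
    unspliced_fraction: pd.Series  # per multiome nucleus


def make_genome(n_chrom: int, length: int, gc: float = 0.41, seed: int = 0) -> GenomeFixture:
    """Draw ``n_chrom`` chromosomes of ``length`` i.i.d. bases at GC fraction ``gc``."""
    if length < 10_000:
        raise ValueError("chromosome length must be >= 10,000")
    if not 0 < gc < 1:
        raise ValueError("gc must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs = {}
    for name in names:
        idx = rng.choice(4, size=length, p=p)
        seqs[name] = "".join(_BASES[idx])
    return GenomeFixture(names, [length] * n_chrom, seqs, seed)


def _random_motif(rng: np.random.Generator, motif_len: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=motif_len)])


def plant_enhancers(
    genome: GenomeFixture,
    n_classes: int,
    regions_per_class: int,
    motif_len: int = 8,
    seed: int = 0,
    region_width: int = 400,
) -> GroundTruth:
    """Carve non-overlapping 400-bp regions and plant class-specific motifs.

    Each class receives a distinct random consensus; each of its regions
    carries 1-3 copies, each either exact or with a single mismatch.
    """
    if motif_len < 6:
        raise ValueError("motif_len must be >= 6")
    rng = np.random.default_rng(seed)
    n_regions = n_classes * regions_per_class
    # non-overlapping placement on a regular grid with jitter
    slots: list[tuple[str, int]] = []
    margin = 1000
    pitch = region_width * 3
    for name, length in zip(genome.chrom_names, genome.chrom_lengths):
        pos = margin
        while pos + region_width + margin < length:
            slots.append((name, pos))
            pos += pitch
    if len(slots) < n_regions:
        raise ValueError(
            f"genome too small: {len(slots)} region slots < {n_regions} requested"
        )
    chosen = rng.choice(len(slots), size=n_regions, replace=False)
    chosen.sort()

    motifs: dict[int, dict] = {}
    consensi: set[str] = set()
    for cls in range(n_classes):
        m = _random_motif(rng, motif_len)
        while m in consensi:
            m = _random_motif(rng, motif_len)
        consensi.add(m)
        motifs[cls] = {"consensus": m, "positions": []}

    classes = np.repeat(np.arange(n_classes), regions_per_class)
    rng.shuffle(classes)
    seq_arrays = {n: np.array(list(genome.sequence[n])) for n in genome.chrom_names}
    rows = []
    class_of_region = {}
    for i, (slot, cls) in enumerate(zip(chosen, classes)):
        chrom, start = slots[slot]
        name = f"region_{i}"
        rows.append((chrom, start, start + region_width, name, int(cls)))
        class_of_region[name] = int(cls)
        consensus = motifs[int(cls)]["consensus"]
        n_copies = rng.integers(1, 4)
        used: list[int] = []
        for _ in range(n_copies):
            for _try in range(50):
                off = int(rng.integers(0, region_width - motif_len))
                if all(abs(off - u) >= motif_len for u in used):
                    break
            else:
                continue
            used.append(off)
            copy = list(consensus)
            if rng.random() < 0.5:  # single mismatch
                p = int(rng.integers(0, motif_len))
                copy[p] = str(rng.choice([b for b in "ACGT" if b != copy[p]]))
            seq_arrays[chrom][start + off : start + off + motif_len] = list("".join(copy))
            motifs[int(cls)]["positions"].append((name, off))
    for n in genome.chrom_names:
        genome.sequence[n] = "".join(seq_arrays[n])
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "class"])
    return GroundTruth(genome, regions, class_of_region, motifs)


def simulate_fragments(
    truth: GroundTruth,
    n_nuclei: int = 500,
    depth_mean: float = 2000.0,
    doublet_rate: float = 0.0,
    n_batches: int = 1,
    seed: int = 0,
    signal_fraction: float = 0.5,
    depth_sigma: float = 0.45,
    batch_sigma: float = 0.3,
    multiome_fraction: float = 0.3,
    frag_len: tuple[int, int] = (60, 180),
) -> FragmentTable:
    """Simulate a fragment table over the planted regions.

    Nuclei are assigned uniformly to one cluster per enhancer class; a
    ``signal_fraction`` of each nucleus's fragments falls inside its own
    cluster's regions (region weights jittered per batch), the rest uniform
    background.  Doublets draw half their fragments from each of two random
    parent nuclei's cluster profiles under an independent depth draw, and
    are flagged in the truth.
    """
    if n_nuclei <= 0:
        raise ValueError("n_nuclei must be positive")
    if not 0 <= doublet_rate < 0.5:
        raise ValueError("doublet_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n_classes = len(truth.planted_motifs)
    regions = truth.regions
    region_class = regions["class"].to_numpy()
    genome = truth.genome
    chrom_lengths = dict(zip(genome.chrom_names, genome.chrom_lengths))
    total_len = sum(genome.chrom_lengths)

    barcodes = [f"N{i:05d}" for i in range(n_nuclei)]
    clusters = rng.integers(0, n_classes, size=n_nuclei)
    batches = rng.integers(0, n_batches, size=n_nuclei)
    is_doublet = rng.random(n_nuclei) < doublet_rate
    is_multi = rng.random(n_nuclei) < multiome_fraction
    # log-normal depth with mean depth_mean
    mu = np.log(depth_mean) - depth_sigma**2 / 2
    depths = np.maximum(1, np.round(rng.lognormal(mu, depth_sigma, size=n_nuclei))).astype(int)

    # per-(batch, region) multiplicative weights
    batch_w = rng.lognormal(0.0, batch_sigma, size=(n_batches, len(regions)))

    rstart = regions["start"].to_numpy()
    rchrom = regions["chrom"].to_numpy()
    rwidth = (regions["end"] - regions["start"]).to_numpy()

    chrom_arr = np.array(genome.chrom_names)
    cum = np.concatenate([[0], np.cumsum(genome.chrom_lengths)])

    def draw_positions(cluster: int, batch: int, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (chrom index, start position) for n fragments."""
        in_sig = rng.random(n) < signal_fraction
        n_sig = int(in_sig.sum())
        chroms = np.empty(n, dtype=int)
        starts = np.empty(n, dtype=int)
        # background: uniform over concatenated genome
        n_bg = n - n_sig
        if n_bg:
            g = rng.integers(0, total_len - frag_len[1], size=n_bg)
            ci = np.searchsorted(cum, g, side="right") - 1
            chroms[~in_sig] = ci
            starts[~in_sig] = g - cum[ci]
        if n_sig:
            own = np.flatnonzero(region_class == cluster)
            w = batch_w[batch, own]
            ridx = own[rng.choice(len(own), size=n_sig, p=w / w.sum())]
            off = rng.integers(0, np.maximum(1, rwidth[ridx] - 50))
            name_to_i = {n_: i for i, n_ in enumerate(genome.chrom_names)}
            chroms[in_sig] = np.array([name_to_i[c] for c in rchrom[ridx]])
            starts[in_sig] = rstart[ridx] + off
        return chroms, starts

    chroms_all, starts_all, ends_all, bc_all = [], [], [], []
    for i in range(n_nuclei):
        d = depths[i]
        if is_doublet[i]:
            other = int(rng.integers(0, n_nuclei))
            d1 = d // 2
            c1, s1 = draw_positions(int(clusters[i]), int(batches[i]), d1)
            c2, s2 = draw_positions(int(clusters[other]), int(batches[i]), d - d1)
            ci = np.concatenate([c1, c2])
            st = np.concatenate([s1, s2])
        else:
            ci, st = draw_positions(int(clusters[i]), int(batches[i]), d)
        ln = rng.integers(frag_len[0], frag_len[1], size=d)
        en = st + ln
        for j, name in enumerate(genome.chrom_names):
            lim = chrom_lengths[name]
            en[(ci == j) & (en > lim)] = lim
        chroms_all.append(ci)
        starts_all.append(st)
        ends_all.append(en)
        bc_all.append(np.full(d, i))
    df = pd.DataFrame(
        {
            "chrom": chrom_arr[np.concatenate(chroms_all)],
            "start": np.concatenate(starts_all),
            "end": np.concatenate(ends_all),
            "barcode": np.array(barcodes)[np.concatenate(bc_all)],
            "count": 1,
        }
    )
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    truth.cluster_of_nucleus = dict(zip(barcodes, clusters.tolist()))
    truth.doublet_flags = dict(zip(barcodes, is_doublet.tolist()))
    truth.batch_of_nucleus = dict(zip(barcodes, batches.tolist()))
    truth.is_multiome = dict(zip(barcodes, is_multi.tolist()))
    return FragmentTable(df, sample_id="synth", sorted=True)


def simulate_multiome_rna(
    truth: GroundTruth,
    fragments: FragmentTable,
    n_genes: int = 100,
    linked_fraction: float = 0.5,
    seed: int = 0,
    base_rate: float = 2.0,
    link_slope: float = 3.0,
    umi_mean: float = 4000.0,
) -> MultiomeRna:
    """Simulate multiome RNA counts; linked genes track region accessibility.

    A ``linked_fraction`` of genes each get one true link to a random
    region: expression is Poisson with rate increasing linearly in that
    region's per-nucleus fragment count.  Unlinked genes are independent
    Poisson.  Gene TSS coordinates are recorded (linked genes within 100 kb
    of their region) and an unspliced fraction is drawn per nucleus.
    """
    if not 0 <= linked_fraction <= 1:
        raise ValueError("linked_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    multi = [b for b, m in truth.is_multiome.items() if m]
    if not multi:
        raise ValueError("no nuclei marked multiome")
    regions = truth.regions
    # per-nucleus accessibility of each region, for multiome nuclei
    frag = fragments.records
    frag = frag[frag["barcode"].isin(set(multi))]
    acc = np.zeros((len(multi), len(regions)))
    bc_index = {b: i for i, b in enumerate(multi)}
    for r, (chrom, start, end) in enumerate(
        zip(regions["chrom"], regions["start"], regions["end"])
    ):
        sub = frag[(frag["chrom"] == chrom) & (frag["start"] < end) & (frag["end"] > start)]
        for b, cnt in sub.groupby("barcode", observed=True)["count"].sum().items():
            acc[bc_index[b], r] += cnt

    n_linked = int(round(n_genes * linked_fraction))
    genes = [f"gene_{g}" for g in range(n_genes)]
    linked_regions = rng.choice(len(regions), size=n_linked, replace=n_linked > len(regions))
    true_links = set()
    tss_rows = []
    chrom_lengths = dict(zip(truth.genome.chrom_names, truth.genome.chrom_lengths))
    lam = np.zeros((len(multi), n_genes))
    for g in range(n_genes):
        if g < n_linked:
            r = int(linked_regions[g])
            rname = regions["name"].iloc[r]
            true_links.add((rname, genes[g]))
            a = acc[:, r]
            scale = a.mean() + 1e-9
            lam[:, g] = base_rate + link_slope * a / scale
            chrom = regions["chrom"].iloc[r]
            centre = int((regions["start"].iloc[r] + regions["end"].iloc[r]) // 2)
            tss = centre + int(rng.integers(-100_000, 100_000))
            tss = int(np.clip(tss, 0, chrom_lengths[chrom] - 1))
        else:
            lam[:, g] = rng.lognormal(np.log(base_rate), 0.3)
            chrom = str(rng.choice(truth.genome.chrom_names))
            tss = int(rng.integers(0, chrom_lengths[chrom]))
        tss_rows.append((chrom, tss, tss + 1, genes[g]))
    counts = rng.poisson(lam)
    # scale rows to a log-normal UMI total around umi_mean
    target = rng.lognormal(np.log(umi_mean), 0.3, size=len(multi))
    row_tot = counts.sum(axis=1)
    keep_p = np.clip(target / np.maximum(row_tot, 1), 0, None)
    scaled = rng.poisson(counts * keep_p[:, None]).astype(int)

    truth.true_links = true_links
    truth.gene_tss = pd.DataFrame(tss_rows, columns=["chrom", "start", "end", "name"])
    unspliced = pd.Series(rng.beta(5, 15, size=len(multi)), index=multi)
    import scipy.sparse as sp

    mat = NucleusFeatureMatrix(sp.csr_matrix(scaled), multi, genes, feature_kind="gene")
    return MultiomeRna(mat, unspliced)


def bin_matrix(
    fragments: FragmentTable, bin_size: int, chrom_lengths: dict[str, int]
) -> NucleusFeatureMatrix:
    """Count fragments per nucleus per fixed genomic bin (by fragment midpoint)."""
    import scipy.sparse as sp

    df = fragments.records
    barcodes = sorted(df["barcode"].unique())
    bidx = {b: i for i, b in enumerate(barcodes)}
    features = []
    offsets = {}
    off = 0
    for chrom in sorted(chrom_lengths):
        n_bins = -(-chrom_lengths[chrom] // bin_size)
        offsets[chrom] = off
        for k in range(n_bins):
            features.append(f"{chrom}:{k * bin_size}-{min((k + 1) * bin_size, chrom_lengths[chrom])}")
        off += n_bins
    mid = ((df["start"] + df["end"]) // 2).to_numpy()
    rows = df["barcode"].map(bidx).to_numpy()
    cols = np.array([offsets[c] for c in df["chrom"]]) + mid // bin_size
    m = sp.coo_matrix(
        (df["count"].to_numpy(), (rows, cols)), shape=(len(barcodes), len(features))
    ).tocsr()
    return NucleusFeatureMatrix(m, barcodes, features, feature_kind="bin")


def peak_matrix(fragments: FragmentTable, peaks: pd.DataFrame) -> NucleusFeatureMatrix:
    """Count Tn5 insertion events per nucleus per peak.

    Both fragment ends are insertion events; each end falling inside a peak
    contributes ``count``.  Peaks are assumed non-overlapping within a
    chromosome (as consensus peaks are); an insertion is assigned to the
    peak whose half-open interval contains it.
    """
    import scipy.sparse as sp

    df = fragments.records
    barcodes = sorted(df["barcode"].unique())
    bidx = {b: i for i, b in enumerate(barcodes)}
    peaks = peaks.reset_index(drop=True)
    features = [f"{c}:{s}-{e}" for c, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"])]
    rows_all, cols_all, vals_all = [], [], []
    for chrom, grp in df.groupby("chrom", observed=True):
        psel = np.flatnonzero((peaks["chrom"] == chrom).to_numpy())
        if not len(psel):
            continue
        ps = peaks["start"].to_numpy()[psel]
        pe = peaks["end"].to_numpy()[psel]
        order = np.argsort(ps, kind="mergesort")
        ps, pe, pcol = ps[order], pe[order], psel[order]
        rows = grp["barcode"].map(bidx).to_numpy()
        cnt = grp["count"].to_numpy()
        for pos in (grp["start"].to_numpy(), grp["end"].to_numpy() - 1):
            j = np.searchsorted(ps, pos, side="right") - 1
            hit = (j >= 0) & (pos < pe[np.clip(j, 0, None)])
            rows_all.append(rows[hit])
            cols_all.append(pcol[j[hit]])
            vals_all.append(cnt[hit])
    if rows_all:
        m = sp.coo_matrix(
            (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
            shape=(len(barcodes), len(peaks)),
        ).tocsr()
    else:
        m = sp.csr_matrix((len(barcodes), len(peaks)), dtype=int)
    return NucleusFeatureMatrix(m, barcodes, features, feature_kind="peak")
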