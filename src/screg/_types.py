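"""Core in-memory containers shared across the pipeline.

Coordinates are 0-based, half-open (BED convention) throughout: an interval
``[start, end)`` covers bases ``start .. end-1``, and two intervals sharing
only a boundary base do not overlap.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


@dataclass
class FragmentTable:
    """Per-nucleus Tn5 fragment intervals.

    ``records`` is a DataFrame with columns chrom, start, end, barcode,
    count.  Both fragment ends are Tn5 insertion events.
    """

    records: pd.DataFrame
    sample_id: str = ""
    sorted: bool = False

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"fragment table missing columns: {missing}")
        if len(df) and not (df["start"].to_numpy() < df["end"].to_numpy()).all():
            raise ValueError("fragment start must be < end")
        if len(df) and (df["count"].to_numpy() < 1).any():
            raise ValueError("fragment count must be >= 1")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_barcodes(self) -> int:
        return self.records["barcode"].nunique()

    def sort(self) -> "FragmentTable":
        df = self.records.sort_values(["chrom", "start", "end"], kind="mergesort")
        return FragmentTable(df.reset_index(drop=True), self.sample_id, sorted=True)

    def subset_barcodes(self, barcodes) -> "FragmentTable":
        keep = self.records["barcode"].isin(set(barcodes))
        return FragmentTable(
            self.records.loc[keep].reset_index(drop=True), self.sample_id, self.sorted
        )


@dataclass
class NucleusFeatureMatrix:
    """Sparse nucleus-by-feature counts with label metadata.

    ``features`` entries are ``chrom:start-end`` strings for genomic
    features (bins/peaks) or plain gene names for gene features.
    """

    values: sp.csr_matrix
    nuclei: list[str]
    features: list[str]
    feature_kind: str = "bin"  # bin | peak | gene
    normalization: str = "raw"  # raw | cpm | tfidf

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.nuclei), len(self.features)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.nuclei)} nuclei x {len(self.features)} features"
            )
        if self.normalization == "raw" and self.values.nnz:
            d = self.values.data
            if (d < 0).any() or not np.allclose(d, np.round(d)):
                raise ValueError("raw counts must be non-negative integers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def depth(self) -> np.ndarray:
        """Total counts per nucleus."""
        return np.asarray(self.values.sum(axis=1)).ravel()

    def feature_intervals(self) -> pd.DataFrame:
        """Parse ``chrom:start-end`` feature ids into an interval frame."""
        rows = []
        for f in self.features:
            chrom, rng = f.rsplit(":", 1)
            start, end = rng.split("-")
            rows.append((chrom, int(start), int(end)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def interval_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a BED-like interval frame in place."""
    if (df["start"].to_numpy() < 0).any() or (df["end"].to_numpy() < 0).any():
        raise ValueError("negative coordinate in interval set")
    if (df["start"].to_numpy() >= df["end"].to_numpy()).any():
        raise ValueError("interval start must be < end")
    return df


@dataclass
class PeakSet:
    """Called peaks with optional summits (one frame: chrom,start,end[,summit])."""

    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.peaks):
            interval_frame(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class ConsensusPeakSet:
    """Fixed-width (400 bp) consensus accessible regions.

    ``peaks`` columns: chrom, start, end, name; ``annotation`` (optional)
    columns: promoter_distal, genic.
    """

    peaks: pd.DataFrame
    width: int = 400
    source_clusters: list[list[int]] | None = None
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.peaks):
            interval_frame(self.peaks)
            w = self.peaks["end"].to_numpy() - self.peaks["start"].to_numpy()
            if not (w == self.width).all():
                raise ValueError(f"all consensus peaks must be {self.width} bp wide")

    def __len__(self) -> int:
        return len(self.peaks)

    def ids(self) -> list[str]:
        return [
            f"{c}:{s}-{e}"
            for c, s, e in zip(self.peaks["chrom"], self.peaks["start"], self.peaks["end"])
        ]


@dataclass
class LsiEmbedding:
    """Reduced LSI components per nucleus after component filtering."""

    components: np.ndarray  # nuclei x d
    nuclei: list[str]
    kept_components: list[int]
    feature_ids: list[str] = field(default_factory=list)
    round: int = 1
    batch_corrected: bool = False

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape[0] != len(self.nuclei):
            raise ValueError("component rows must match nuclei")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass
class ClusterPartition:
    """Nucleus-to-cluster assignment from graph clustering."""

    labels: np.ndarray
    modularity: float = float("nan")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size == 0:
            raise ValueError("empty partition")

    @property
    def k(self) -> int:
        return int(len(np.unique(self.labels)))


@dataclass
class ResidualMatrix:
    """Cluster-by-feature Pearson residuals under the dispersion-theta null."""

    Z: np.ndarray  # clusters x features
    X: np.ndarray  # observed cluster totals
    mu_hat: np.ndarray
    theta: float
    c_tot: np.ndarray
    g_frac: np.ndarray
    clusters: list[int]
    features: list[str]


@dataclass
class AnchorNet:
    """k nearest multiome neighbours and normalized weights per nucleus."""

    neighbours: np.ndarray  # n x k, indices into multiome_ids
    weights: np.ndarray  # n x k, rows sum to 1
    nuclei: list[str]  # all nuclei (ATAC-only and multiome)
    multiome_ids: list[str]

    def __post_init__(self) -> None:
        s = self.weights.sum(axis=1)
        if not np.allclose(s, 1.0, atol=1e-9):
            raise ValueError("anchor weights must sum to 1 per nucleus")


@dataclass
class CoaccessLinkSet:
    """Scored region-region or region-gene links.

    ``links`` columns: a, b, score, distance, n_windows.
    """

    links: pd.DataFrame
    kind: str = "region-region"  # region-region | region-tss | region-gene-expression
    cutoff: float | None = None

    def __len__(self) -> int:
        return len(self.links)
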