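"""Readers and writers for fragments, intervals, TSS tables and sparse matrices.

All genomic text formats are plain TSV/BED/MTX with optional gzip for
fragment files.  Interval semantics are 0-based half-open everywhere.
"""
from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from ._types import FragmentTable, NucleusFeatureMatrix, interval_frame


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fragments(path, sample_id: str | None = None) -> FragmentTable:
    """Read a fragment file (chrom, start, end, barcode[, count]).

    ``count`` defaults to 1 when the column is absent.  Barcodes are
    prefixed with the sample id (``sample#barcode``) when one is given, so
    that pooling across samples cannot collide.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (4, 5):
                raise ValueError(
                    f"{path}:{lineno}: expected 4-5 tab-separated fields, got {len(parts)}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
                count = int(parts[4]) if len(parts) == 5 else 1
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate/count") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            rows.append((parts[0], start, end, parts[3], count))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])
    if sample_id:
        df["barcode"] = sample_id + "#" + df["barcode"]
    return FragmentTable(df, sample_id=sample_id or "", sorted=False)


def write_fragments(table: FragmentTable, path) -> None:
    path = Path(path)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for row in table.records.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.barcode}\t{row.count}\n")


def read_intervals(path, sort: bool = False) -> pd.DataFrame:
    """Read BED3+ intervals into a frame with chrom, start, end, name."""
    path = Path(path)
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            name = parts[3] if len(parts) > 3 else f"iv{lineno}"
            rows.append((parts[0], int(parts[1]), int(parts[2]), name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    interval_frame(df)
    if sort:
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return df


def write_intervals(intervals: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in intervals.columns else [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def overlaps(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Boolean mask over rows of ``a``: overlaps any interval in ``b`` (half-open)."""
    mask = np.zeros(len(a), dtype=bool)
    if not len(a) or not len(b):
        return mask
    for chrom, bgrp in b.groupby("chrom"):
        sel = np.flatnonzero((a["chrom"] == chrom).to_numpy())
        if sel.size == 0:
            continue
        astart = a["start"].to_numpy()[sel]
        aend = a["end"].to_numpy()[sel]
        bstart = np.sort(bgrp["start"].to_numpy())
        # order intervals by start; an a-interval overlaps some b iff any b with
        # b.start < a.end has b.end > a.start — check candidates via sorted ends
        bs = bgrp["start"].to_numpy()
        be = bgrp["end"].to_numpy()
        order = np.argsort(bs, kind="mergesort")
        bs, be = bs[order], be[order]
        # cumulative max of ends lets us avoid O(n*m) in the common sorted case,
        # but interval counts here are modest: vectorized all-pairs per chrom
        hit = (astart[:, None] < be[None, :]) & (aend[:, None] > bs[None, :])
        mask[sel] = hit.any(axis=1)
    return mask


def remove_blacklisted(intervals: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    keep = ~overlaps(intervals, blacklist)
    return intervals.loc[keep].reset_index(drop=True)


def read_matrix(mtx_path, nuclei_path=None, features_path=None,
                feature_kind: str = "bin") -> NucleusFeatureMatrix:
    """Read an MTX triplet with two sidecar label files.

    Sidecars default to ``<stem>.nuclei.tsv`` / ``<stem>.features.tsv``.
    Duplicate (i, j) entries are summed (MTX convention).
    """
    mtx_path = Path(mtx_path)
    stem = str(mtx_path)[: -len(".mtx")] if str(mtx_path).endswith(".mtx") else str(mtx_path)
    nuclei_path = Path(nuclei_path) if nuclei_path else Path(stem + ".nuclei.tsv")
    features_path = Path(features_path) if features_path else Path(stem + ".features.tsv")
    m = sio.mmread(mtx_path).tocsr()  # mmread sums duplicate triplets
    nuclei = nuclei_path.read_text().splitlines()
    features = features_path.read_text().splitlines()
    if m.shape != (len(nuclei), len(features)):
        raise ValueError(
            f"matrix {m.shape} does not match sidecars ({len(nuclei)}, {len(features)})"
        )
    return NucleusFeatureMatrix(m, nuclei, features, feature_kind=feature_kind)


def write_matrix(matrix: NucleusFeatureMatrix, mtx_path) -> None:
    mtx_path = Path(mtx_path)
    stem = str(mtx_path)[: -len(".mtx")] if str(mtx_path).endswith(".mtx") else str(mtx_path)
    sio.mmwrite(str(mtx_path), sp.coo_matrix(matrix.values))
    Path(stem + ".nuclei.tsv").write_text("\n".join(matrix.nuclei) + "\n" if matrix.nuclei else "")
    Path(stem + ".features.tsv").write_text(
        "\n".join(matrix.features) + "\n" if matrix.features else ""
    )


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a name -> uppercase sequence dict."""
    from Bio import SeqIO

    with _open_text(Path(path)) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    seqio_write(records, str(path), "fasta")


def fetch_sequence(seqs: dict[str, str], chrom: str, start: int, end: int) -> str:
    """Fetch [start, end) from an in-memory genome; errors outside bounds."""
    seq = seqs[chrom]
    if start < 0 or end > len(seq):
        raise ValueError(f"{chrom}:{start}-{end} outside chromosome bounds")
    return seq[start:end]
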