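"""Greedy seqlet discovery from attribution tracks.

High-attribution 15-bp windows (above mean + 2 sd of a per-track shuffled
null) are extracted as seqlets and extended by 5-bp flanks.  Seqlets are
greedily clustered by normalized cross-correlation of their hypothetical
score matrices, compared over the highest-signal core columns in both
orientations and at small alignment offsets; each surviving cluster is
summarized by an averaged contribution-weight matrix (CWM).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attribution import AttributionTrack


@dataclass
class Seqlet:
    track_index: int
    start: int  # flank-extended window start within the track
    end: int
    score: float
    hypothetical: np.ndarray  # 4 x width
    actual: np.ndarray


@dataclass
class SeqletCluster:
    seqlets: list[Seqlet]
    cwm: np.ndarray  # averaged contribution-weight matrix, 4 x width

    @property
    def size(self) -> int:
        return len(self.seqlets)

    def consensus(self, length: int | None = None) -> str:
        """Highest-|CWM| base per column, optionally over the best sub-window."""
        bases = np.array(list("ACGT"))
        mat = self.cwm
        if length is not None and length < mat.shape[1]:
            info = np.abs(mat).sum(axis=0)
            sums = np.convolve(info, np.ones(length), mode="valid")
            s = int(np.argmax(sums))
            mat = mat[:, s : s + length]
        return "".join(bases[np.abs(mat).argmax(axis=0)])


def _revcomp(mat: np.ndarray) -> np.ndarray:
    # channel order ACGT: complement is the reversed channel axis
    return mat[::-1, ::-1]


def _core_start(mat: np.ndarray, width: int) -> int:
    """Start of the highest-|signal| sub-window."""
    if mat.shape[1] <= width:
        return 0
    info = np.abs(mat).sum(axis=0)
    return int(np.argmax(np.convolve(info, np.ones(width), mode="valid")))


def _core_ncc(
    a: np.ndarray, b: np.ndarray, core_width: int, max_offset: int = 4
) -> tuple[float, int, bool]:
    """Max NCC between high-signal cores; returns (ncc, shift of b, rc).

    ``shift`` maps b's coordinates into a's: column p of b corresponds to
    column p + shift of a.
    """
    sa = _core_start(a, core_width)
    ca = a[:, sa : sa + core_width]
    best, best_shift, best_rc = -np.inf, 0, False
    for rc in (False, True):
        bb = _revcomp(b) if rc else b
        sb = _core_start(bb, core_width)
        cb = bb[:, sb : sb + core_width]
        for off in range(-max_offset, max_offset + 1):
            if off >= 0:
                A, B = ca[:, off:], cb[:, : cb.shape[1] - off]
            else:
                A, B = ca[:, : ca.shape[1] + off], cb[:, -off:]
            w = min(A.shape[1], B.shape[1])
            if w < core_width - max_offset:
                continue
            A, B = A[:, :w].ravel(), B[:, :w].ravel()
            na, nb = np.linalg.norm(A), np.linalg.norm(B)
            if na == 0 or nb == 0:
                continue
            v = float(A @ B / (na * nb))
            if v > best:
                # b core col t ~ a core col off+t  =>  shift = sa + off - sb
                best, best_shift, best_rc = v, sa + off - sb, rc
    return best, best_shift, best_rc


def _extract_seqlets(
    track: AttributionTrack,
    track_index: int,
    window: int,
    flank: int,
    rng: np.random.Generator,
    n_null: int = 50,
) -> list[Seqlet]:
    per_pos = np.abs(track.actual).sum(axis=0)
    L = len(per_pos)
    if L < window:
        return []
    kernel = np.ones(window)
    sums = np.convolve(per_pos, kernel, mode="valid")
    null = np.concatenate(
        [np.convolve(per_pos[rng.permutation(L)], kernel, mode="valid")
         for _ in range(n_null)]
    )
    threshold = null.mean() + 2 * null.std()
    out = []
    taken = np.zeros(L, dtype=bool)
    for s in np.argsort(-sums, kind="mergesort"):
        if sums[s] <= threshold:
            break
        if taken[s : s + window].any():
            continue
        taken[s : s + window] = True
        a = max(0, s - flank)
        b = min(L, s + window + flank)
        out.append(
            Seqlet(
                track_index=track_index,
                start=int(a),
                end=int(b),
                score=float(sums[s]),
                hypothetical=track.hypothetical[:, a:b],
                actual=track.actual[:, a:b],
            )
        )
    return out


def discover_seqlets(
    tracks: list[AttributionTrack],
    window: int = 15,
    flank: int = 5,
    min_cluster: int = 30,
    ncc_threshold: float = 0.8,
    core_width: int = 9,
    seed: int = 0,
) -> list[SeqletCluster]:
    """Extract and greedily cluster seqlets from attribution tracks.

    Clusters are seeded by the highest-scoring unassigned seqlet; a
    candidate joins when the NCC of its hypothetical-score core with the
    seed's reaches ``ncc_threshold`` in either orientation.  Clusters
    smaller than ``min_cluster`` are dropped; members' actual-score
    matrices are averaged (core-aligned) into the cluster CWM.
    """
    if not tracks:
        raise ValueError("need at least one track")
    rng = np.random.default_rng(seed)
    seqlets: list[Seqlet] = []
    for i, t in enumerate(tracks):
        seqlets.extend(_extract_seqlets(t, i, window, flank, rng))
    if not seqlets:
        import warnings

        warnings.warn("no windows passed the attribution threshold")
        return []
    seqlets.sort(key=lambda s: -s.score)
    width = window + 2 * flank
    assigned = np.zeros(len(seqlets), dtype=bool)
    clusters: list[SeqletCluster] = []
    for i, seed_s in enumerate(seqlets):
        if assigned[i]:
            continue
        assigned[i] = True
        members = [seed_s]
        canvas = [_place(seed_s.actual, 0, width)]
        for j in range(i + 1, len(seqlets)):
            if assigned[j]:
                continue
            v, shift, rc = _core_ncc(
                seed_s.hypothetical, seqlets[j].hypothetical, core_width
            )
            if v >= ncc_threshold:
                assigned[j] = True
                members.append(seqlets[j])
                act = seqlets[j].actual
                if rc:
                    act = _revcomp(act)
                canvas.append(_place(act, shift, width))
        if len(members) >= min_cluster:
            stack = np.stack(canvas)
            support = (np.abs(stack).sum(axis=1) > 0).sum(axis=0)
            cwm = stack.sum(axis=0) / np.maximum(support, 1)[None, :]
            clusters.append(SeqletCluster(members, cwm))
    clusters.sort(key=lambda c: -c.size)
    return clusters


def _place(mat: np.ndarray, shift: int, width: int) -> np.ndarray:
    """Place ``mat`` on a zero canvas with its columns moved by ``shift``."""
    out = np.zeros((4, width))
    src_lo = max(0, -shift)
    src_hi = min(mat.shape[1], width - shift)
    if src_hi > src_lo:
        out[:, src_lo + shift : src_hi + shift] = mat[:, src_lo:src_hi]
    return out
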