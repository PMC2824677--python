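"""Candidate overlap detection by shared-k-mer seeding plus alignment.

Read pairs sharing at least one canonical seed k-mer are aligned around the
seed-implied offset(s); a candidate is kept when the overlapping region spans
at least ``min_overlap`` alignment columns with a disagreement rate
(mismatches + gap bases over columns) of at most ``max_error``.  Defaults
follow standard hash-overlap practice: minimum overlap 30 bases, maximum
disagreement 6%.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import edlib

from ._kmercode import canonical_codes, encode_bases
from .io_formats import OverlapCandidate, SequenceRecord
from .sequtil import FLIPPED, SAME, CigarStats, cigar_stats, revcomp

DEFAULT_SEED_K = 14
DEFAULT_MIN_OVERLAP = 30
DEFAULT_MAX_ERROR = 0.06

#: Only every INDEX_STRIDE-th position of a read is indexed (every position is
#: still queried), so any exact shared stretch of at least
#: seed_k + INDEX_STRIDE - 1 bases is guaranteed to produce a seed.
INDEX_STRIDE = 8


def index_kmers(reads: Sequence[SequenceRecord], k: int,
                stride: int = 1) -> dict[int, list[tuple[int, int, bool]]]:
    """Map canonical k-mer codes to their (read index, position, is_forward)
    occurrences.  K-mers containing N are skipped."""
    if not reads:
        raise ValueError("no reads to index")
    shortest = min(len(r.seq) for r in reads)
    if k > shortest:
        raise ValueError(f"k={k} exceeds the shortest read length ({shortest})")
    index: dict[int, list[tuple[int, int, bool]]] = defaultdict(list)
    for ridx, read in enumerate(reads):
        codes, is_fwd, valid = canonical_codes(encode_bases(read.seq), k)
        for pos in range(0, codes.size, stride):
            if valid[pos]:
                index[int(codes[pos])].append((ridx, pos, bool(is_fwd[pos])))
    return dict(index)


def _evaluate_diagonal(seq_a: str, seq_b: str, d: int,
                       band: int | None = None,
                       ) -> tuple[int, int, CigarStats] | None:
    """Best alignment of the overlap implied by placing seq_b at offset ``d``
    in seq_a's frame.  Returns (a_hang, b_hang, stats) or None.

    ``band`` widens the window in which the alignment end points may float
    around the seed-implied position; the default scales with read length.
    """
    if d < 0:
        res = _evaluate_diagonal(seq_b, seq_a, -d, band)
        if res is None:
            return None
        ah, bh, st = res
        return -ah, -bh, st
    la, lb = len(seq_a), len(seq_b)
    avail = la - d
    if avail <= 0:
        return None
    if lb < avail:
        # containment: seq_b ends inside seq_a; let both ends float in a window
        pad = band if band is not None else 10 + lb // 10
        ws = max(0, d - pad)
        we = min(la, d + lb + pad)
        res = edlib.align(seq_b, seq_a[ws:we], mode="HW", task="path")
        start, end = res["locations"][0]
        st = cigar_stats(res["cigar"])
        return ws + start, (ws + end + 1) - la, st
    # dovetail (or flush): seq_b extends to or past seq_a's end
    res = edlib.align(seq_a[d:], seq_b, mode="SHW", task="path")
    end = res["locations"][0][1]
    st = cigar_stats(res["cigar"])
    return d, lb - (end + 1), st


def align_overlap(read_a: SequenceRecord, read_b: SequenceRecord,
                  orientation: str, offset: int,
                  band: int | None = None,
                  ) -> OverlapCandidate | None:
    """Alignment statistics for the overlap implied by an offset.

    ``offset`` is readB's (oriented) start relative to readA's start.  Returns
    an OverlapCandidate carrying the optimal alignment statistics of the
    implied overlapping substrings, or None if no overlap is implied.
    """
    if abs(offset) >= len(read_a.seq) and offset >= 0:
        raise ValueError("offset places readB entirely past readA")
    seq_b = read_b.seq if orientation == SAME else revcomp(read_b.seq)
    res = _evaluate_diagonal(read_a.seq, seq_b, offset, band)
    if res is None:
        return None
    ah, bh, st = res
    return OverlapCandidate(read_a.id, read_b.id, orientation, ah, bh,
                            st.columns, st.matches, st.mismatches,
                            st.gap_events, st.gap_bases)


def candidate_rank(c: OverlapCandidate) -> tuple:
    """Deterministic preference order among candidates for one
    pair/orientation: highest alignment score (matches - mismatches - gap
    bases), then smallest |a_hang|, then fewest gap events."""
    score = c.matches - c.mismatches - c.gap_bases
    return (-score, abs(c.a_hang), c.gap_events)


def _better(a: OverlapCandidate, b: OverlapCandidate) -> OverlapCandidate:
    return a if candidate_rank(a) <= candidate_rank(b) else b


def _cluster_representatives(diags: list[int], merge_gap: int = 30) -> list[int]:
    """Collapse sorted diagonals into clusters; return up to three
    representative offsets (first, middle, last) per cluster."""
    reps: list[int] = []
    diags = sorted(set(diags))
    start = 0
    for i in range(1, len(diags) + 1):
        if i == len(diags) or diags[i] - diags[i - 1] > merge_gap:
            cluster = diags[start:i]
            picks = {cluster[0], cluster[len(cluster) // 2], cluster[-1]}
            reps.extend(sorted(picks))
            start = i
    return reps


def find_overlap_candidates(reads: Sequence[SequenceRecord],
                            seed_k: int = DEFAULT_SEED_K,
                            min_overlap: int = DEFAULT_MIN_OVERLAP,
                            max_error: float = DEFAULT_MAX_ERROR,
                            index_stride: int = INDEX_STRIDE,
                            ) -> list[OverlapCandidate]:
    """All candidate overlaps among ``reads``, canonicalized and deduplicated
    (at most one candidate per pair and orientation)."""
    if not reads:
        return []
    shortest = min(len(r.seq) for r in reads)
    if seed_k > shortest:
        raise ValueError(f"seed_k={seed_k} exceeds shortest read ({shortest} bp)")

    per_read = [canonical_codes(encode_bases(r.seq), seed_k) for r in reads]
    lengths = [len(r.seq) for r in reads]

    # sparse index, dense query
    index: dict[int, list[tuple[int, int, bool]]] = defaultdict(list)
    for ridx, (codes, is_fwd, valid) in enumerate(per_read):
        for pos in range(0, codes.size, index_stride):
            if valid[pos]:
                index[int(codes[pos])].append((ridx, pos, bool(is_fwd[pos])))

    diag_sets: dict[tuple[int, int, str], set[int]] = defaultdict(set)
    for qidx, (codes, is_fwd, valid) in enumerate(per_read):
        for qpos in range(codes.size):
            if not valid[qpos]:
                continue
            bucket = index.get(int(codes[qpos]))
            if not bucket:
                continue
            qf = bool(is_fwd[qpos])
            for ridx, rpos, rf in bucket:
                if ridx == qidx:
                    continue
                if qidx < ridx:
                    i, pi, fi, j, pj, fj = qidx, qpos, qf, ridx, rpos, rf
                else:
                    i, pi, fi, j, pj, fj = ridx, rpos, rf, qidx, qpos, qf
                if fi == fj:
                    orient = SAME
                    d = pi - pj
                else:
                    orient = FLIPPED
                    d = pi - (lengths[j] - seed_k - pj)
                diag_sets[(i, j, orient)].add(d)

    best: dict[tuple[str, str, str], OverlapCandidate] = {}
    oriented_cache: dict[int, str] = {}
    for (i, j, orient), diags in diag_sets.items():
        seq_a = reads[i].seq
        if orient == SAME:
            seq_b = reads[j].seq
        else:
            seq_b = oriented_cache.get(j)
            if seq_b is None:
                seq_b = oriented_cache[j] = revcomp(reads[j].seq)
        chosen: OverlapCandidate | None = None
        for d in _cluster_representatives(list(diags)):
            res = _evaluate_diagonal(seq_a, seq_b, d)
            if res is None:
                continue
            ah, bh, st = res
            if st.columns < min_overlap or st.error_rate > max_error:
                continue
            cand = OverlapCandidate(reads[i].id, reads[j].id, orient, ah, bh,
                                    st.columns, st.matches, st.mismatches,
                                    st.gap_events, st.gap_bases)
            chosen = cand if chosen is None else _better(chosen, cand)
        if chosen is not None:
            cand = chosen.canonical()
            if cand.key in best:
                cand = _better(best[cand.key], cand)
            best[cand.key] = cand
    return [best[k] for k in sorted(best)]
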