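"""Comparative-genomics overlap score from mapping reads to related genomes.

Both reads of a candidate overlap are mapped to a panel of related genomes
with a seed-and-extend mapper (16-mer seeds, minimum 80% identity and 80%
read coverage by default).  Every combination of placements is classified as
*overlapping* (consistent strands, relative offset matching the candidate's
hang within a tolerance) or *non-overlapping*; a combination's score is the
total number of matching bases of its two hits.  The final signed score is

    +log2(max_s_ovl - max_s_nonovl + 1)   if max_s_ovl > max_s_nonovl
    -log2(max_s_nonovl - max_s_ovl + 1)   if max_s_nonovl > max_s_ovl
     0                                    on a tie,

taken over all genomes of the panel, and undefined (missing) when either
read fails to map anywhere.  True overlaps tend to co-locate in related
genomes (positive score); repeat-induced false overlaps place their reads at
different repeat copies whose flanks match better separately (negative
score).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from ._kmercode import canonical_codes, encode_bases
from .io_formats import OverlapCandidate, SequenceRecord
from .sequtil import SAME, cigar_query_span, cigar_stats, revcomp

DEFAULT_MERSIZE = 16
DEFAULT_MIN_IDENTITY = 0.80
DEFAULT_MIN_COVERAGE = 0.80
DEFAULT_TOLERANCE = 30

OVERLAPPING = "overlapping"
NON_OVERLAPPING = "non-overlapping"


@dataclass(frozen=True)
class ReferenceHit:
    """One placement of a read on a reference genome (forward-frame,
    0-based half-open coordinates; for strand '-', the reverse complement of
    the read aligns forward to the interval)."""

    read_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    matching_bases: int
    identity: float
    coverage: float


@dataclass
class ComparativeEvidence:
    """Combination maxima and final score for one overlap candidate."""

    readA_id: str
    readB_id: str
    orientation: str
    max_s_ovl: int | None
    max_s_nonovl: int | None
    score: float | None  # None = undefined (a read did not map anywhere)


class GenomeIndex:
    """Sorted-array canonical k-mer index of one genome for read mapping."""

    def __init__(self, genome: SequenceRecord, mersize: int = DEFAULT_MERSIZE):
        self.genome = genome
        self.mersize = mersize
        codes, is_fwd, valid = canonical_codes(encode_bases(genome.seq), mersize)
        positions = np.nonzero(valid)[0]
        codes = codes[positions]
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._positions = positions[order]
        self._is_fwd = is_fwd[positions][order]

    def lookup(self, code: int) -> tuple[np.ndarray, np.ndarray]:
        """(positions, is_forward) of all occurrences of a canonical code."""
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return self._positions[lo:hi], self._is_fwd[lo:hi]

    def lookup_many(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Occurrence ranges (lo, hi) for an array of canonical codes."""
        lo = np.searchsorted(self._codes, codes, side="left")
        hi = np.searchsorted(self._codes, codes, side="right")
        return lo, hi


def map_read_to_genome(read: SequenceRecord,
                       genome: SequenceRecord | GenomeIndex,
                       mersize: int = DEFAULT_MERSIZE,
                       min_identity: float = DEFAULT_MIN_IDENTITY,
                       min_coverage: float = DEFAULT_MIN_COVERAGE,
                       ) -> list[ReferenceHit]:
    """Seed-and-extend mapping of a read to both strands of a genome.

    Seed groups on a common diagonal are extended with a full alignment of
    the read against the implied genome window; hits below the identity or
    coverage thresholds are discarded.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, mersize)
    gseq = index.genome.seq
    glen = len(gseq)
    rlen = len(read.seq)
    codes, r_is_fwd, valid = canonical_codes(encode_bases(read.seq), index.mersize)

    # seed -> projected genome start of the read, per strand
    proj: dict[str, list[int]] = {"+": [], "-": []}
    vpos = np.nonzero(valid)[0]
    lo, hi = index.lookup_many(codes[vpos])
    for pos, l, h in zip(vpos.tolist(), lo.tolist(), hi.tolist()):
        if l == h:
            continue
        gpos = index._positions[l:h]
        same_strand = index._is_fwd[l:h] == bool(r_is_fwd[pos])
        for g in gpos[same_strand]:
            proj["+"].append(int(g) - pos)
        for g in gpos[~same_strand]:
            proj["-"].append(int(g) - (rlen - index.mersize - pos))

    pad = 30 + rlen // 20
    raw_hits: list[ReferenceHit] = []
    for strand, starts in proj.items():
        if not starts:
            continue
        query = read.seq if strand == "+" else revcomp(read.seq)
        for s0 in _cluster_starts(starts):
            ws = max(0, s0 - pad)
            we = min(glen, s0 + rlen + pad)
            if we - ws < index.mersize:
                continue
            res = edlib.align(query, gseq[ws:we], mode="HW", task="path")
            if res["editDistance"] < 0:
                continue
            start, end = res["locations"][0]
            st = cigar_stats(res["cigar"])
            identity = st.matches / st.columns
            coverage = cigar_query_span(res["cigar"]) / rlen
            if identity < min_identity or coverage < min_coverage:
                continue
            raw_hits.append(ReferenceHit(read.id, index.genome.id, ws + start,
                                         ws + end + 1, strand, st.matches,
                                         identity, coverage))
    return _dedupe_hits(raw_hits)


def _cluster_starts(starts: list[int], gap: int = 50) -> list[int]:
    """Collapse projected start positions within ``gap`` bp into one
    representative (the median) per cluster."""
    reps = []
    starts = sorted(starts)
    begin = 0
    for i in range(1, len(starts) + 1):
        if i == len(starts) or starts[i] - starts[i - 1] > gap:
            cluster = starts[begin:i]
            reps.append(cluster[len(cluster) // 2])
            begin = i
    return reps


def _dedupe_hits(hits: list[ReferenceHit]) -> list[ReferenceHit]:
    """Keep the best-scoring hit among hits occupying overlapping intervals
    on the same strand."""
    hits = sorted(hits, key=lambda h: (-h.matching_bases, h.start, h.strand))
    kept: list[ReferenceHit] = []
    for h in hits:
        redundant = any(
            k.strand == h.strand and
            min(k.end, h.end) - max(k.start, h.start) > 0.5 * (h.end - h.start)
            for k in kept)
        if not redundant:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.start, h.strand))


def enumerate_combinations(hits_a: Sequence[ReferenceHit],
                           hits_b: Sequence[ReferenceHit],
                           candidate: OverlapCandidate,
                           tolerance: int = DEFAULT_TOLERANCE,
                           ) -> list[tuple[ReferenceHit, ReferenceHit, str, int]]:
    """Classify and score every placement combination of the two reads.

    A combination is *overlapping* when the strand relationship of the two
    hits matches the candidate's orientation and the implied relative offset
    matches the candidate's a_hang within ``tolerance``.  The score is the
    sum of the two hits' matching bases.
    """
    combos = []
    for ha in hits_a:
        for hb in hits_b:
            strands_consistent = ((ha.strand == hb.strand)
                                  == (candidate.orientation == SAME))
            offset = (hb.start - ha.start) if ha.strand == "+" else (ha.end - hb.end)
            co_located = strands_consistent and abs(offset - candidate.a_hang) <= tolerance
            cls = OVERLAPPING if co_located else NON_OVERLAPPING
            combos.append((ha, hb, cls, ha.matching_bases + hb.matching_bases))
    return combos


def comparative_score(max_s_ovl: int | None, max_s_nonovl: int | None) -> float | None:
    """Signed log2 margin between the best overlapping and best
    non-overlapping combination scores; None when both are absent.

    When only one class of combination exists the other maximum is taken as 0
    (no support).  A tie yields 0.
    """
    if max_s_ovl is None and max_s_nonovl is None:
        return None
    s_ovl = max_s_ovl or 0
    s_non = max_s_nonovl or 0
    if s_ovl == s_non:
        return 0.0
    if s_ovl > s_non:
        return math.log2(s_ovl - s_non + 1)
    return -math.log2(s_non - s_ovl + 1)


def comparative_evidence(candidate: OverlapCandidate,
                         hits_a_by_genome: dict[str, Sequence[ReferenceHit]],
                         hits_b_by_genome: dict[str, Sequence[ReferenceHit]],
                         tolerance: int = DEFAULT_TOLERANCE,
                         ) -> ComparativeEvidence:
    """Combine per-genome placement combinations into the final score.

    ``hits_*_by_genome`` map each panel genome id to that read's hits there.
    The score is undefined (None) when either read has no hit in any genome.
    """
    a_mapped = any(len(h) for h in hits_a_by_genome.values())
    b_mapped = any(len(h) for h in hits_b_by_genome.values())
    if not (a_mapped and b_mapped):
        return ComparativeEvidence(candidate.readA_id, candidate.readB_id,
                                   candidate.orientation, None, None, None)
    max_ovl: int | None = None
    max_non: int | None = None
    for genome_id in hits_a_by_genome:
        for _, _, cls, score in enumerate_combinations(
                hits_a_by_genome.get(genome_id, ()),
                hits_b_by_genome.get(genome_id, ()), candidate, tolerance):
            if cls == OVERLAPPING:
                max_ovl = score if max_ovl is None else max(max_ovl, score)
            else:
                max_non = score if max_non is None else max(max_non, score)
    score = comparative_score(max_ovl, max_non)
    if score is None:
        # both reads mapped but never to a common genome: no support either way
        score = 0.0
    return ComparativeEvidence(candidate.readA_id, candidate.readB_id,
                               candidate.orientation, max_ovl, max_non, score)


def estimate_genome_identity(a: SequenceRecord, b: SequenceRecord,
                             k: int = DEFAULT_MERSIZE) -> float:
    """Coarse whole-genome identity estimate from shared canonical k-mers.

    The fraction q of shared k-mers estimates per-base identity as q^(1/k)
    (a k-mer survives only if all k bases are unmutated).  Used to filter a
    genome panel by a maximum-identity cutoff.
    """
    sets = []
    for rec in (a, b):
        codes, _, valid = canonical_codes(encode_bases(rec.seq), k)
        sets.append(set(codes[valid].tolist()))
    shared = len(sets[0] & sets[1])
    denom = min(len(sets[0]), len(sets[1]))
    if denom == 0:
        return 0.0
    q = shared / denom
    return q ** (1.0 / k)
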