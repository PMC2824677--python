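"""Non-comparative overlap features: alignment statistics and k-mer frequencies.

Repeat-induced false overlaps sit in genomic sequence that is sampled more
deeply than unique sequence, so the k-mers inside their overlap regions occur
more often than the expected coverage predicts.  The features computed here
capture that signal: quartiles of the coverage-normalized frequencies of all
k-mers in the overlap region, the fraction of overrepresented k-mers
(normalized frequency > 1.5x the model mean), and the number of singleton
k-mers (raw count 1, typically sequencing errors), alongside the plain
alignment statistics (mismatch fraction, identity, length, gap events).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._kmercode import canonical_codes, encode_bases
from .io_formats import OverlapCandidate, SequenceRecord
from .sequtil import SAME, revcomp

DEFAULT_FEATURE_K = 16
OVERREPRESENTED_FACTOR = 1.5

NONCOMP_FEATURES = [
    "pct_mismatch", "pct_identity", "overlap_length", "n_mismatches",
    "n_gap_events", "kmer_q1", "kmer_q2", "kmer_q3",
    "pct_overrepresented", "n_singleton_kmers",
]


@dataclass
class KmerFrequencyModel:
    """Canonical k-mer counts over a read set.

    ``normalized frequency`` of a k-mer is its count divided by the expected
    sequencing coverage, so unique genome sequence sits near 1 and an n-copy
    repeat near n.  ``mean_frequency`` is the mean normalized frequency over
    distinct k-mers.
    """

    k: int
    counts: dict[int, int]
    expected_coverage: float
    mean_frequency: float

    def frequency(self, code: int) -> float:
        return self.counts.get(code, 0) / self.expected_coverage


def build_kmer_model(reads: Sequence[SequenceRecord], k: int = DEFAULT_FEATURE_K,
                     expected_coverage: float | None = None,
                     genome_size: int | None = None) -> KmerFrequencyModel:
    """Count all canonical k-mers in the reads.

    If ``expected_coverage`` is not given it is estimated as total read bases
    over the genome size; if the genome size is also unknown it is estimated
    by the number of distinct canonical k-mers observed.
    """
    counts: Counter[int] = Counter()
    total_bases = 0
    for read in reads:
        total_bases += len(read.seq)
        codes, _, valid = canonical_codes(encode_bases(read.seq), k)
        if codes.size:
            kept = codes[valid]
            uniq, cnt = np.unique(kept, return_counts=True)
            for code, c in zip(uniq.tolist(), cnt.tolist()):
                counts[code] += c
    if not counts:
        raise ValueError("no countable k-mers in the read set")
    if expected_coverage is None:
        if genome_size is None:
            genome_size = len(counts)
        expected_coverage = total_bases / genome_size
    if expected_coverage <= 0:
        raise ValueError("expected_coverage must be positive")
    total = sum(counts.values())
    mean_frequency = (total / len(counts)) / expected_coverage
    return KmerFrequencyModel(k, dict(counts), expected_coverage, mean_frequency)


def nearest_rank_quartiles(sorted_values: Sequence[float]) -> tuple[float, float, float]:
    """25th/50th/75th percentiles by the nearest-rank (lower) convention."""
    n = len(sorted_values)
    if n == 0:
        raise ValueError("empty value list")
    picks = [sorted_values[max(0, math.ceil(q * n) - 1)] for q in (0.25, 0.50, 0.75)]
    return tuple(picks)  # type: ignore[return-value]


def overlap_regions(candidate: OverlapCandidate, len_a: int, len_b: int,
                    ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Overlap intervals on readA and on the *oriented* readB (0-based,
    half-open), reconstructed from the hangs."""
    a_lo = max(0, candidate.a_hang)
    a_hi = len_a + min(0, candidate.b_hang)
    b_lo = max(0, -candidate.a_hang)
    b_hi = len_b + min(0, -candidate.b_hang) if candidate.b_hang < 0 else len_b - candidate.b_hang
    b_hi = min(len_b, max(b_lo, b_hi))
    return (a_lo, a_hi), (b_lo, b_hi)


def overlap_kmer_stats(candidate: OverlapCandidate, read_a: SequenceRecord,
                       read_b: SequenceRecord, model: KmerFrequencyModel,
                       ) -> dict[str, float]:
    """K-mer frequency statistics of an overlap region.

    K-mers are pooled from both reads' overlapping substrings (duplicates
    included), which keeps the statistic invariant under swapping the reads.
    Returns NaNs when the overlap is too short to contain a k-mer.
    """
    seq_b = read_b.seq if candidate.orientation == SAME else revcomp(read_b.seq)
    (a_lo, a_hi), (b_lo, b_hi) = overlap_regions(candidate, len(read_a.seq), len(seq_b))
    freqs: list[float] = []
    n_singleton = 0
    for seq, lo, hi in ((read_a.seq, a_lo, a_hi), (seq_b, b_lo, b_hi)):
        sub = seq[lo:hi]
        if len(sub) < model.k:
            continue
        codes, _, valid = canonical_codes(encode_bases(sub), model.k)
        for code in codes[valid].tolist():
            raw = model.counts.get(code, 0)
            freqs.append(raw / model.expected_coverage)
            if raw == 1:
                n_singleton += 1
    if not freqs:
        return {"kmer_q1": math.nan, "kmer_q2": math.nan, "kmer_q3": math.nan,
                "pct_overrepresented": math.nan, "n_singleton_kmers": math.nan}
    freqs.sort()
    q1, q2, q3 = nearest_rank_quartiles(freqs)
    threshold = OVERREPRESENTED_FACTOR * model.mean_frequency
    pct_over = sum(1 for f in freqs if f > threshold) / len(freqs)
    return {"kmer_q1": q1, "kmer_q2": q2, "kmer_q3": q3,
            "pct_overrepresented": pct_over, "n_singleton_kmers": n_singleton}


def alignment_features(candidate: OverlapCandidate) -> dict[str, float]:
    """Alignment-derived features of an overlap candidate."""
    if candidate.overlap_length <= 0:
        raise ValueError("candidate has zero overlap length")
    return {
        "pct_mismatch": candidate.mismatches / candidate.overlap_length,
        "pct_identity": candidate.matches / candidate.overlap_length,
        "overlap_length": float(candidate.overlap_length),
        "n_mismatches": float(candidate.mismatches),
        "n_gap_events": float(candidate.gap_events),
    }


def compute_noncomp_features(candidates: Sequence[OverlapCandidate],
                             reads: dict[str, SequenceRecord],
                             model: KmerFrequencyModel) -> pd.DataFrame:
    """Feature table (one row per candidate, candidate order preserved)."""
    rows = []
    for cand in candidates:
        row = {"readA_id": cand.readA_id, "readB_id": cand.readB_id,
               "orientation": cand.orientation}
        row.update(alignment_features(cand))
        row.update(overlap_kmer_stats(cand, reads[cand.readA_id],
                                      reads[cand.readB_id], model))
        rows.append(row)
    columns = ["readA_id", "readB_id", "orientation"] + NONCOMP_FEATURES
    return pd.DataFrame(rows, columns=columns)
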