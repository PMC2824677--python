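"""Independent brute-force oracles used to validate the fast implementations."""

from __future__ import annotations

import numpy as np
from numba import njit

from olcorrect.io_formats import OverlapCandidate, SequenceRecord
from olcorrect.sequtil import FLIPPED, SAME, CigarStats, revcomp


@njit(cache=True)
def _nw_table(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n, m = a.size, b.size
    dp = np.empty((n + 1, m + 1), dtype=np.int32)
    for i in range(n + 1):
        dp[i, 0] = i
    for j in range(m + 1):
        dp[0, j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = dp[i - 1, j - 1] + (0 if a[i - 1] == b[j - 1] else 1)
            if dp[i - 1, j] + 1 < best:
                best = dp[i - 1, j] + 1
            if dp[i, j - 1] + 1 < best:
                best = dp[i, j - 1] + 1
            dp[i, j] = best
    return dp


def nw_stats(a: str, b: str) -> CigarStats:
    """Unit-cost global alignment statistics by full dynamic programming.

    Traceback prefers the diagonal move on ties, then deletion.
    """
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    dp = _nw_table(av, bv)
    i, j = n, m
    matches = mismatches = gap_events = gap_bases = 0
    prev_gap = False
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dp[i, j] == dp[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            if a[i - 1] == b[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i, j = i - 1, j - 1
            prev_gap = False
        elif i > 0 and dp[i, j] == dp[i - 1, j] + 1:
            gap_bases += 1
            if not prev_gap:
                gap_events += 1
            prev_gap = True
            i -= 1
        else:
            gap_bases += 1
            if not prev_gap:
                gap_events += 1
            prev_gap = True
            j -= 1
    return CigarStats(matches, mismatches, gap_events, gap_bases)


def oracle_candidates(reads: list[SequenceRecord], min_overlap: int = 30,
                      max_error: float = 0.06) -> dict[tuple, OverlapCandidate]:
    """Exhaustive all-pairs, all-offsets overlap search.

    For every pair, orientation and offset, the implied overlapping
    substrings are aligned by full dynamic programming; candidates failing
    the length or error threshold are discarded and the best survivor per
    pair/orientation is kept (highest alignment score, then smallest
    |a_hang|, then fewest gap events).
    """
    best: dict[tuple, OverlapCandidate] = {}
    for i in range(len(reads)):
        for j in range(i + 1, len(reads)):
            la = len(reads[i].seq)
            for orient in (SAME, FLIPPED):
                a = reads[i].seq
                b = reads[j].seq if orient == SAME else revcomp(reads[j].seq)
                lb = len(b)
                chosen = None
                for d in range(-lb + 1, la):
                    sa = a[max(d, 0): min(la, d + lb)]
                    sb = b[max(-d, 0): min(lb, la - d)]
                    if max(len(sa), len(sb)) < min_overlap:
                        # alignment columns >= max substring length, and the
                        # gap columns needed to reach min_overlap would
                        # already exceed max_error at these thresholds
                        continue
                    st = nw_stats(sa, sb)
                    if st.columns < min_overlap or st.error_rate > max_error:
                        continue
                    cand = OverlapCandidate(reads[i].id, reads[j].id, orient,
                                            d, d + lb - la, st.columns,
                                            st.matches, st.mismatches,
                                            st.gap_events, st.gap_bases)
                    if chosen is None or _rank(cand) < _rank(chosen):
                        chosen = cand
                if chosen is not None:
                    cand = chosen.canonical()
                    if cand.key not in best or _rank(cand) < _rank(best[cand.key]):
                        best[cand.key] = cand
    return best


def _rank(c: OverlapCandidate) -> tuple:
    score = c.matches - c.mismatches - c.gap_bases
    return (-score, abs(c.a_hang), c.gap_events)


def oracle_n50(lengths: list[int], reference_length: int) -> int:
    """N50 by scanning every candidate threshold."""
    feasible = [t for t in lengths
                if sum(l for l in lengths if l >= t) >= reference_length / 2]
    return max(feasible) if feasible else 0
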