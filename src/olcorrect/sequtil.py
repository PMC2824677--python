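"""Small shared sequence helpers: reverse complement, canonical k-mers, CIGAR stats."""

from __future__ import annotations

import re
from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Orientation of the second read in an overlap: as given, or reverse-complemented.
SAME = "same"
FLIPPED = "flipped"


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def iter_kmers(seq: str, k: int):
    """Yield (position, k-mer) for every k-mer free of N."""
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            yield i, kmer


@dataclass(frozen=True)
class CigarStats:
    """Column counts of a pairwise alignment.

    ``columns`` is the total number of alignment columns
    (matches + mismatches + gap bases); ``gap_events`` counts maximal runs
    of insertion/deletion columns.
    """

    matches: int
    mismatches: int
    gap_events: int
    gap_bases: int

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gap_bases

    @property
    def error_rate(self) -> float:
        return (self.mismatches + self.gap_bases) / self.columns


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def cigar_stats(cigar: str) -> CigarStats:
    """Parse an extended CIGAR string ('=', 'X', 'I', 'D') into column counts."""
    matches = mismatches = gap_events = gap_bases = 0
    prev_gap = False
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            matches += n
            prev_gap = False
        elif op == "X":
            mismatches += n
            prev_gap = False
        elif op in ("I", "D"):
            gap_bases += n
            if not prev_gap:
                gap_events += 1
            prev_gap = True
        else:  # plain 'M' is ambiguous; callers must request extended CIGARs
            raise ValueError(f"ambiguous CIGAR op {op!r}; extended CIGAR required")
    return CigarStats(matches, mismatches, gap_events, gap_bases)


def cigar_query_span(cigar: str) -> int:
    """Number of query bases consumed by an extended CIGAR ('=', 'X', 'I')."""
    span = 0
    for num, op in _CIGAR_RE.findall(cigar):
        if op in ("=", "X", "I"):
            span += int(num)
    return span
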