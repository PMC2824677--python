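"""Label overlap candidates true or false from known read source coordinates.

A candidate is *true* when the two reads' source intervals lie on the same
genome, intersect by at least ``min_true_overlap`` bases, and have a strand
relationship consistent with the candidate's orientation (same strands for a
``same``-orientation candidate, opposite strands for ``flipped``).  Anything
else — in particular a pair of reads drawn from different copies of a repeat
— is a false overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import OverlapCandidate
from .sequtil import SAME
from .simulate import TruePlacement

DEFAULT_MIN_TRUE_OVERLAP = 30


@dataclass(frozen=True)
class OverlapLabel:
    readA_id: str
    readB_id: str
    orientation: str
    label: bool
    genomic_overlap_bp: int


def label_overlaps(candidates: Sequence[OverlapCandidate],
                   placements: Mapping[str, Sequence[TruePlacement]] | Sequence[TruePlacement],
                   min_true_overlap: int = DEFAULT_MIN_TRUE_OVERLAP,
                   ) -> list[OverlapLabel]:
    """One label per candidate, in candidate order.

    ``placements`` may be a list of TruePlacement or a mapping
    read_id -> placements.  Reads without any placement raise ValueError.
    """
    if not isinstance(placements, Mapping):
        by_read: dict[str, list[TruePlacement]] = {}
        for p in placements:
            by_read.setdefault(p.read_id, []).append(p)
    else:
        by_read = {k: list(v) for k, v in placements.items()}

    missing = sorted({rid for c in candidates for rid in (c.readA_id, c.readB_id)
                      if rid not in by_read})
    if missing:
        raise ValueError(f"reads without placements: {', '.join(missing)}")

    labels = []
    for cand in candidates:
        want_same_strand = cand.orientation == SAME
        best_bp = 0
        for pa in by_read[cand.readA_id]:
            for pb in by_read[cand.readB_id]:
                if pa.genome_id != pb.genome_id:
                    continue
                if (pa.strand == pb.strand) != want_same_strand:
                    continue
                inter = min(pa.end, pb.end) - max(pa.start, pb.start)
                best_bp = max(best_bp, inter)
        is_true = best_bp >= min_true_overlap
        labels.append(OverlapLabel(cand.readA_id, cand.readB_id, cand.orientation,
                                   is_true, max(best_bp, 0)))
    return labels


def labels_to_table(labels: Sequence[OverlapLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.readA_id, l.readB_id, l.orientation,
          "true" if l.label else "false", l.genomic_overlap_bp) for l in labels],
        columns=["readA_id", "readB_id", "orientation", "label", "genomic_overlap_bp"],
    )


def labels_from_table(df: pd.DataFrame) -> list[OverlapLabel]:
    def as_bool(value) -> bool:
        # the TSV stores 'true'/'false'; some readers parse those to bool
        if isinstance(value, (bool,)) or hasattr(value, "item"):
            return bool(value)
        return str(value).strip().lower() == "true"

    return [OverlapLabel(r.readA_id, r.readB_id, r.orientation,
                         as_bool(r.label), int(r.genomic_overlap_bp))
            for r in df.itertuples(index=False)]
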