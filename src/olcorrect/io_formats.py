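"""FASTA readers/writers and the tabular overlap / feature / label / model formats.

All tables are tab-separated text with a single ``#``-prefixed header line
naming the columns, so they can be inspected and diffed with standard shell
tools.  Model files are joblib archives with a magic/version header.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequtil import FLIPPED, SAME

_VALID_CHARS = set("ACGTN")

MODEL_MAGIC = "olcorrect-model"
MODEL_VERSION = 1


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (a read, a genome, or a contig)."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OverlapCandidate:
    """A putative overlap between two reads.

    Layout convention (AMOS-style): in readA's frame, the oriented readB
    starts at ``a_hang`` and ends ``b_hang`` bases past readA's end.  If
    ``orientation`` is ``flipped`` the hangs refer to the reverse complement
    of readB.  ``overlap_length`` is the alignment column count of the
    overlapping region, so ``matches + mismatches + gap_bases ==
    overlap_length``.
    """

    readA_id: str
    readB_id: str
    orientation: str  # SAME or FLIPPED
    a_hang: int
    b_hang: int
    overlap_length: int
    matches: int
    mismatches: int
    gap_events: int
    gap_bases: int = 0

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.readA_id, self.readB_id, self.orientation)

    @property
    def error_rate(self) -> float:
        return (self.mismatches + self.gap_bases) / self.overlap_length

    def swapped(self) -> "OverlapCandidate":
        """The same overlap expressed from readB's point of view."""
        if self.orientation == SAME:
            a, b = -self.a_hang, -self.b_hang
        else:  # flipping the layout of an innie overlap swaps the hangs
            a, b = self.b_hang, self.a_hang
        return replace(self, readA_id=self.readB_id, readB_id=self.readA_id,
                       a_hang=a, b_hang=b)

    def canonical(self) -> "OverlapCandidate":
        """Express the overlap with the lexicographically smaller id as readA."""
        return self if self.readA_id <= self.readB_id else self.swapped()


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly wrapped) multi-record FASTA file.

    Sequences are uppercased and U is mapped to T.  Duplicate ids, empty
    sequences and non-A/C/G/T/N characters raise ``ValueError``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
        for i, c in enumerate(seq):
            if c not in _VALID_CHARS:
                raise ValueError(
                    f"invalid character {c!r} at position {i} of record {rec.id!r}"
                )
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


_OVERLAP_COLUMNS = (
    "readA_id", "readB_id", "orientation", "a_hang", "b_hang",
    "overlap_length", "matches", "mismatches", "gap_events", "gap_bases",
)
_INT_COLUMNS = _OVERLAP_COLUMNS[3:]


def write_overlap_table(candidates: Sequence[OverlapCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_OVERLAP_COLUMNS) + "\n")
        for c in candidates:
            fh.write("\t".join(str(getattr(c, col)) for col in _OVERLAP_COLUMNS) + "\n")


def read_overlap_table(path, min_overlap: int = 0) -> list[OverlapCandidate]:
    """Read an overlap TSV, validating row syntax and table invariants."""
    candidates: list[OverlapCandidate] = []
    seen: set[tuple] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(_OVERLAP_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(_OVERLAP_COLUMNS)} columns, got {len(parts)}")
            row = dict(zip(_OVERLAP_COLUMNS, parts))
            if row["orientation"] not in (SAME, FLIPPED):
                raise ValueError(f"{path}:{lineno}: bad orientation {row['orientation']!r}")
            try:
                for col in _INT_COLUMNS:
                    row[col] = int(row[col])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer field") from None
            c = OverlapCandidate(**row)
            if c.overlap_length < max(min_overlap, 0) or c.overlap_length <= 0:
                raise ValueError(f"{path}:{lineno}: overlap_length {c.overlap_length} "
                                 f"below minimum")
            if c.mismatches < 0 or c.gap_events < 0 or c.gap_bases < 0:
                raise ValueError(f"{path}:{lineno}: negative alignment count")
            if c.readA_id > c.readB_id:
                raise ValueError(f"{path}:{lineno}: table not canonical "
                                 f"({c.readA_id!r} > {c.readB_id!r})")
            if c.key in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pair {c.key}")
            seen.add(c.key)
            candidates.append(c)
    return candidates


PAIR_COLUMNS = ["readA_id", "readB_id", "orientation"]


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Write a feature (or label) table; NaN entries become the token 'NA'."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, na_rep="NA")


def read_feature_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '#'-prefixed header line")
        columns = header[1:].split("\t")
        df = pd.read_csv(fh, sep="\t", names=columns, na_values=["NA"],
                         keep_default_na=False)
    return df


def save_model(model, path) -> None:
    """Serialize a trained overlap classifier with a magic/version header."""
    joblib.dump({"magic": MODEL_MAGIC, "version": MODEL_VERSION, "model": model}, path)


def load_model(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file {path} does not exist")
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"corrupt model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("magic") != MODEL_MAGIC:
        raise ValueError(f"{path} is not an overlap-classifier model file")
    if payload.get("version") != MODEL_VERSION:
        raise ValueError(f"unsupported model version {payload.get('version')} in {path}")
    return payload["model"]
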