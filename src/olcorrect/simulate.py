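"""Synthetic genomes, related strains, and shotgun reads with known coordinates.

The generator emulates the ingredients the overlap-correction problem needs:
a genome carrying exact and diverged repeat families (the source of false
overlaps), a panel of related genomes at controllable percent identity (the
source of comparative evidence), and reads sampled at a chosen fold coverage
with substitution/indel errors, each carrying its error-free source interval
as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import SequenceRecord
from .sequtil import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MIN_READ_LENGTH = 50


@dataclass(frozen=True)
class RepeatSpec:
    """One repeat family: ``copy_number`` copies of a ``unit_length`` bp unit,
    each copy independently substituted at ``divergence`` per base."""

    unit_length: int
    copy_number: int
    divergence: float = 0.0


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the standard benchmark: a 200 kb genome with a 1.5 kb x 6
    repeat family at 1% divergence plus a 400 bp x 10 exact family, related
    genomes at 8% and 9% divergence, 10x coverage of 400 +/- 40 bp reads
    with 1% substitution and 0.3% indel error.
    """

    genome_length: int = 200_000
    repeat_specs: list[RepeatSpec] = field(default_factory=lambda: [
        RepeatSpec(1500, 6, 0.01),
        RepeatSpec(400, 10, 0.0),
    ])
    related_genomes: list[float] = field(default_factory=lambda: [0.08, 0.09])
    coverage: float = 10.0
    read_length_mean: float = 400.0
    read_length_sd: float = 40.0
    substitution_rate: float = 0.01
    indel_rate: float = 0.003
    seed: int = 0

    def validate(self) -> None:
        for rate in (self.substitution_rate, self.indel_rate, *self.related_genomes):
            if not 0 <= rate < 1:
                raise ValueError(f"rate {rate} outside [0, 1)")
        for spec in self.repeat_specs:
            if spec.unit_length >= self.genome_length:
                raise ValueError("repeat unit longer than genome")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    def to_file(self, path) -> None:
        """Write the configuration as a flat key = value file.

        ``repeat_specs`` are encoded as comma-separated
        unit_length:copy_number:divergence triples and ``related_genomes``
        as comma-separated divergences.
        """
        with open(path, "w") as fh:
            fh.write(f"genome_length = {self.genome_length}\n")
            fh.write("repeat_specs = " + ",".join(
                f"{s.unit_length}:{s.copy_number}:{s.divergence:g}"
                for s in self.repeat_specs) + "\n")
            fh.write("related_genomes = " + ",".join(
                f"{d:g}" for d in self.related_genomes) + "\n")
            for key in ("coverage", "read_length_mean", "read_length_sd",
                        "substitution_rate", "indel_rate", "seed"):
                fh.write(f"{key} = {getattr(self, key):g}\n")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        values: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key == "repeat_specs":
                    specs = []
                    for item in filter(None, raw.split(",")):
                        unit, copies, div = item.split(":")
                        specs.append(RepeatSpec(int(unit), int(copies),
                                                float(div)))
                    values[key] = specs
                elif key == "related_genomes":
                    values[key] = [float(x) for x in filter(None, raw.split(","))]
                elif key in ("genome_length", "seed"):
                    values[key] = int(float(raw))
                elif key in ("coverage", "read_length_mean", "read_length_sd",
                             "substitution_rate", "indel_rate"):
                    values[key] = float(raw)
                else:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        config = cls(**values)
        config.validate()
        return config


@dataclass(frozen=True)
class TruePlacement:
    """Error-free source interval of a read (0-based, half-open, forward frame).

    For strand '-', the read sequence is the reverse complement of
    ``genome[start:end]``.
    """

    read_id: str
    genome_id: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class RepeatCopy:
    family: int
    start: int
    end: int


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _substitute(rng: np.random.Generator, arr: np.ndarray, rate: float) -> tuple[np.ndarray, int]:
    """Substitute each base independently at ``rate``, always to a different base."""
    arr = arr.copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr, hit.size


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate_genome(config: SimConfig,
                    rng: np.random.Generator | None = None,
                    genome_id: str = "genome",
                    ) -> tuple[SequenceRecord, list[RepeatCopy]]:
    """Random uniform-composition genome with the configured repeat copies
    pasted at non-overlapping positions.  Fully reproducible from the seed."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genome = _random_seq(rng, config.genome_length)

    occupied: list[tuple[int, int]] = []
    copies: list[RepeatCopy] = []
    for fam_idx, spec in enumerate(config.repeat_specs):
        unit = _random_seq(rng, spec.unit_length)
        for _ in range(spec.copy_number):
            placed = False
            for _attempt in range(1000):
                start = int(rng.integers(0, config.genome_length - spec.unit_length))
                end = start + spec.unit_length
                if all(end <= s or start >= e for s, e in occupied):
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place repeat family {fam_idx} without overlap; "
                    f"reduce copy_number or unit_length")
            copy_seq, _ = _substitute(rng, unit, spec.divergence)
            genome[start:end] = copy_seq
            occupied.append((start, end))
            copies.append(RepeatCopy(fam_idx, start, end))
    return SequenceRecord(genome_id, _to_str(genome)), sorted(copies, key=lambda c: c.start)


def derive_related_genome(genome: SequenceRecord, divergence: float,
                          rng: np.random.Generator | int,
                          genome_id: str | None = None,
                          indel_fraction: float = 0.01,
                          ) -> tuple[SequenceRecord, float]:
    """Mutate a genome to a related strain at the given divergence.

    Substitutions are applied per base at ``divergence``; length-1 indels at
    ``divergence * indel_fraction``.  Returns the derived genome and the
    realized identity (fraction of unmutated positions).
    """
    if not 0 <= divergence < 0.5:
        raise ValueError("divergence must be in [0, 0.5)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    arr = np.frombuffer(genome.seq.encode("ascii"), dtype=np.uint8)
    arr, n_sub = _substitute(rng, arr, divergence)
    indel_rate = divergence * indel_fraction
    n_indel = 0
    if indel_rate > 0:
        pos = np.nonzero(rng.random(arr.size) < indel_rate)[0]
        n_indel = pos.size
        if n_indel:
            pieces: list[np.ndarray] = []
            prev = 0
            for p in pos:
                pieces.append(arr[prev:p])
                if rng.random() < 0.5:  # deletion of this base
                    pass
                else:  # insertion before this base
                    pieces.append(_random_seq(rng, 1))
                    pieces.append(arr[p:p + 1])
                prev = p + 1
            pieces.append(arr[prev:])
            arr = np.concatenate(pieces)
    identity = 1.0 - (n_sub + n_indel) / len(genome.seq)
    if genome_id is None:
        genome_id = f"{genome.id}_div{divergence:g}"
    return SequenceRecord(genome_id, _to_str(arr)), identity


def simulate_reads(genome: SequenceRecord, config: SimConfig,
                   rng: np.random.Generator | None = None,
                   id_prefix: str = "r",
                   ) -> tuple[list[SequenceRecord], list[TruePlacement]]:
    """Sample shotgun reads uniformly from both strands.

    Read lengths are normal(mean, sd) truncated to [50, genome length]; the
    number of reads is chosen so total sampled bases ~= coverage x genome
    length.  Substitution and indel errors are applied after extraction; the
    returned placements give each read's error-free source interval.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    glen = len(genome.seq)
    if _MIN_READ_LENGTH > glen:
        raise ValueError("genome shorter than the minimum read length")
    if config.read_length_mean > glen:
        raise ValueError("read length distribution incompatible with genome length")
    garr = np.frombuffer(genome.seq.encode("ascii"), dtype=np.uint8)

    n_reads = int(round(config.coverage * glen / config.read_length_mean))
    lengths = rng.normal(config.read_length_mean, config.read_length_sd, size=n_reads)
    lengths = np.clip(np.rint(lengths), _MIN_READ_LENGTH, glen).astype(int)

    reads: list[SequenceRecord] = []
    placements: list[TruePlacement] = []
    width = len(str(n_reads))
    for i, length in enumerate(lengths):
        start = int(rng.integers(0, glen - length + 1))
        end = start + int(length)
        strand = "+" if rng.random() < 0.5 else "-"
        frag = garr[start:end]
        seq = _to_str(frag)
        if strand == "-":
            seq = revcomp(seq)
        seq = _apply_read_errors(rng, seq, config.substitution_rate, config.indel_rate)
        read_id = f"{id_prefix}{i:0{width}d}"
        reads.append(SequenceRecord(read_id, seq))
        placements.append(TruePlacement(read_id, genome.id, start, end, strand))
    return reads, placements


def _apply_read_errors(rng: np.random.Generator, seq: str,
                       sub_rate: float, indel_rate: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if sub_rate > 0:
        arr, _ = _substitute(rng, arr, sub_rate)
    if indel_rate > 0:
        pos = np.nonzero(rng.random(arr.size) < indel_rate)[0]
        if pos.size:
            pieces: list[np.ndarray] = []
            prev = 0
            for p in pos:
                pieces.append(arr[prev:p])
                if rng.random() < 0.5:
                    pass  # delete this base
                else:
                    pieces.append(_random_seq(rng, 1))
                    pieces.append(arr[p:p + 1])
                prev = p + 1
            pieces.append(arr[prev:])
            arr = np.concatenate(pieces)
    return _to_str(arr)


def placements_to_table(placements: list[TruePlacement]):
    """TruePlacement rows as a DataFrame (for the on-disk TSV format)."""
    import pandas as pd

    return pd.DataFrame(
        [(p.read_id, p.genome_id, p.start, p.end, p.strand) for p in placements],
        columns=["read_id", "genome_id", "start", "end", "strand"],
    )


def placements_from_table(df) -> list[TruePlacement]:
    return [TruePlacement(r.read_id, r.genome_id, int(r.start), int(r.end), r.strand)
            for r in df.itertuples(index=False)]
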