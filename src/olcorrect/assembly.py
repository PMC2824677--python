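"""Minimal overlap-layout-consensus contigging and assembly evaluation.

The layout stage is deliberately conservative, in the spirit of a unitigger:
contained reads are set aside, transitive edges are removed (with a small
slack for indel drift), and contigs are maximal simple paths of reads with
unique in/out edges — any branch, such as one left behind by an uncorrected
repeat-induced overlap, terminates the contig.  Consensus splices reads
along the path at alignment-located junctions, which stays accurate in the
presence of indel errors.  Evaluation reports the reference-relative
N50 (shortest contig length at which contigs that long or longer sum to half
the reference length) and the percentage of reference positions covered by
at least one contig alignment.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np

from .comp_features import GenomeIndex, map_read_to_genome
from .io_formats import OverlapCandidate, SequenceRecord
from .sequtil import SAME, revcomp

logger = logging.getLogger(__name__)

DEFAULT_SLACK = 10


def filter_overlaps(candidates: Sequence[OverlapCandidate],
                    predictions) -> list[OverlapCandidate]:
    """Keep exactly the candidates predicted true, preserving order.

    ``predictions`` is either a sequence aligned with ``candidates`` or a
    mapping from candidate key to bool.
    """
    if isinstance(predictions, Mapping):
        missing = [c.key for c in candidates if c.key not in predictions]
        if missing:
            raise ValueError(f"missing predictions for {len(missing)} candidates, "
                             f"e.g. {missing[0]}")
        flags = [predictions[c.key] for c in candidates]
    else:
        if len(predictions) != len(candidates):
            raise ValueError(f"{len(candidates)} candidates but "
                             f"{len(predictions)} predictions")
        flags = list(predictions)
    retained = [c for c, keep in zip(candidates, flags) if keep]
    if candidates and not retained:
        logger.warning("all %d overlaps predicted false; nothing retained",
                       len(candidates))
    return retained


@dataclass
class OverlapGraph:
    """Reduced overlap graph with an absolute layout per connected component.

    ``placement`` maps each node to (offset, strand) in its component's
    frame; ``out_edges``/``in_edges`` are the direction-resolved dovetail
    adjacencies after transitive reduction.
    """

    nodes: set[str]
    edges: dict[tuple[str, str, str], OverlapCandidate]
    containment: dict[str, str]  # contained read -> container
    placement: dict[str, tuple[int, str]]
    out_edges: dict[str, list[str]]
    in_edges: dict[str, list[str]]
    offsets: dict[tuple[str, str], int] = field(default_factory=dict)
    n_transitive_removed: int = 0
    n_conflicting: int = 0

    def components(self) -> list[set[str]]:
        seen: set[str] = set()
        comps = []
        for start in sorted(self.nodes):
            if start in seen:
                continue
            comp = {start}
            queue = [start]
            while queue:
                u = queue.pop()
                for v in self.out_edges.get(u, []) + self.in_edges.get(u, []):
                    if v not in comp:
                        comp.add(v)
                        queue.append(v)
            seen |= comp
            comps.append(comp)
        return comps


def _implied_step(cand: OverlapCandidate, strand_a: str) -> tuple[int, str]:
    """(offset of readB relative to readA, strand of readB) in the absolute
    frame, given readA's absolute strand."""
    if strand_a == "+":
        off = cand.a_hang
        strand_b = "+" if cand.orientation == SAME else "-"
    else:
        off = -cand.b_hang
        strand_b = "-" if cand.orientation == SAME else "+"
    return off, strand_b


def build_graph(reads: Sequence[SequenceRecord],
                candidates: Sequence[OverlapCandidate],
                slack: int = DEFAULT_SLACK,
                require_confirmation: bool = False) -> OverlapGraph:
    """Containment removal, layout assignment, and transitive reduction.

    With ``require_confirmation``, an edge is kept only when some third read
    overlaps both of its endpoints at geometrically consistent offsets
    (a confirming triangle).  True overlaps are densely cross-confirmed at
    ordinary coverage, so this drops isolated spurious edges — for example
    the few repeat-induced overlaps that survive classification once their
    companions have been removed — while a dense uncorrected repeat tangle
    confirms itself and keeps its branches.
    """
    read_ids = {r.id for r in reads}
    for cand in candidates:
        if cand.readA_id not in read_ids or cand.readB_id not in read_ids:
            raise ValueError(f"candidate references unknown read: {cand.key}")

    containment: dict[str, str] = {}
    for cand in candidates:
        c = cand.canonical()
        b_contained = c.a_hang >= 0 and c.b_hang <= 0
        a_contained = c.a_hang <= 0 and c.b_hang >= 0
        if b_contained:  # on an identical span, contain the larger id
            containment.setdefault(c.readB_id, c.readA_id)
        elif a_contained:
            containment.setdefault(c.readA_id, c.readB_id)

    nodes = read_ids - set(containment)
    edges: dict[tuple[str, str, str], OverlapCandidate] = {}
    for cand in candidates:
        c = cand.canonical()
        if c.readA_id in containment or c.readB_id in containment:
            continue
        if (c.a_hang >= 0 and c.b_hang <= 0) or (c.a_hang <= 0 and c.b_hang >= 0):
            continue  # containment-shaped edge between non-contained reads
        if c.readA_id == c.readB_id:
            continue
        edges[c.key] = c

    # absolute layout by BFS; edges whose strand implication conflicts with
    # the assignment are dropped (repeat-induced inconsistencies)
    adj: dict[str, list[OverlapCandidate]] = defaultdict(list)
    for c in edges.values():
        adj[c.readA_id].append(c)
        adj[c.readB_id].append(c.swapped())
    placement: dict[str, tuple[int, str]] = {}
    for start in sorted(nodes):
        if start in placement:
            continue
        placement[start] = (0, "+")
        queue = [start]
        while queue:
            u = queue.pop(0)
            pos_u, s_u = placement[u]
            for e in sorted(adj.get(u, []), key=lambda c: c.readB_id):
                off, s_v = _implied_step(e, s_u)
                v = e.readB_id
                if v not in placement:
                    placement[v] = (pos_u + off, s_v)
                    queue.append(v)

    n_conflicting = 0
    consistent: dict[tuple[str, str, str], OverlapCandidate] = {}
    directed: dict[str, dict[str, tuple[int, tuple[str, str, str]]]] = defaultdict(dict)
    for key, c in edges.items():
        u, v = c.readA_id, c.readB_id
        _, s_u = placement[u]
        off, s_v = _implied_step(c, s_u)
        if placement[v][1] != s_v:
            n_conflicting += 1
            continue
        consistent[key] = c
        if off < 0 or (off == 0 and v < u):
            off, _ = _implied_step(c.swapped(), placement[v][1])
            u, v = v, u
        directed[u][v] = (max(off, 0), key)

    if require_confirmation:
        # iterate to a fixpoint: dropping an unsupported edge can leave a
        # companion spurious edge without its last confirming triangle
        while True:
            unconfirmed = _unconfirmed_edges(directed, slack=2 * slack)
            if not unconfirmed:
                break
            for u, v, key in unconfirmed:
                consistent.pop(key, None)
                directed[u].pop(v, None)

    # transitive reduction in the absolute frame
    transitive: set[tuple[str, str, str]] = set()
    for u, out in directed.items():
        targets = sorted(out.items(), key=lambda kv: kv[1][0])
        for x, (off_ux, key_ux) in targets:
            for w, (off_uw, _) in targets:
                if w == x or off_uw > off_ux:
                    continue
                hop = directed.get(w, {}).get(x)
                if hop is not None and abs(off_uw + hop[0] - off_ux) <= slack:
                    transitive.add(key_ux)
                    break
    for key in transitive:
        consistent.pop(key, None)

    out_edges: dict[str, list[str]] = defaultdict(list)
    in_edges: dict[str, list[str]] = defaultdict(list)
    offsets: dict[tuple[str, str], int] = {}
    for u, out in directed.items():
        for v, (off, key) in sorted(out.items()):
            if key in consistent:
                out_edges[u].append(v)
                in_edges[v].append(u)
                offsets[(u, v)] = off

    return OverlapGraph(nodes, consistent, containment, placement,
                        dict(out_edges), dict(in_edges), offsets,
                        len(transitive), n_conflicting)


def _unconfirmed_edges(directed: dict[str, dict[str, tuple[int, tuple]]],
                       slack: int) -> list[tuple[str, str, tuple]]:
    """Directed edges with no geometrically consistent confirming triangle."""
    incoming: dict[str, dict[str, int]] = defaultdict(dict)
    for u, out in directed.items():
        for v, (off, _) in out.items():
            incoming[v][u] = off

    def confirmed(u: str, v: str, off_uv: int) -> bool:
        out_u, out_v = directed.get(u, {}), directed.get(v, {})
        in_u, in_v = incoming.get(u, {}), incoming.get(v, {})
        for w, (off_uw, _) in out_u.items():  # w between u and v, or past v
            if w == v:
                continue
            if w in out_v and abs(off_uv + out_v[w][0] - off_uw) <= slack:
                return True
            if w in in_v and abs(off_uw + in_v[w] - off_uv) <= slack:
                return True
        for w, off_wu in in_u.items():  # w before u
            if w == v:
                continue
            if w in in_v and abs(off_wu + off_uv - in_v[w]) <= slack:
                return True
        return False

    dropped = []
    for u, out in directed.items():
        for v, (off, key) in out.items():
            if not confirmed(u, v, off):
                dropped.append((u, v, key))
    return dropped


@dataclass
class Contig:
    id: str
    seq: str
    layout: list[tuple[str, int, str]]  # (read_id, offset, strand)


def build_contigs(graph: OverlapGraph,
                  reads: Sequence[SequenceRecord]) -> list[Contig]:
    """Contigs from maximal non-branching paths, majority-vote consensus.

    Nodes with more than one inbound or outbound edge are branch points: they
    join no path and are emitted as single-read contigs.
    """
    seq_of = {r.id: r.seq for r in reads}

    def is_path_node(n: str) -> bool:
        return (len(graph.out_edges.get(n, [])) <= 1
                and len(graph.in_edges.get(n, [])) <= 1)

    used: set[str] = set()
    paths: list[list[str]] = []
    for n in sorted(graph.nodes):
        if n in used or not is_path_node(n):
            continue
        chain = [n]
        cur = n
        while True:  # walk left to the path start
            prevs = graph.in_edges.get(cur, [])
            if len(prevs) != 1 or not is_path_node(prevs[0]) or prevs[0] in chain:
                break
            cur = prevs[0]
            chain.insert(0, cur)
        cur = n
        while True:  # walk right to the path end
            nexts = graph.out_edges.get(cur, [])
            if len(nexts) != 1 or not is_path_node(nexts[0]) or nexts[0] in chain:
                break
            cur = nexts[0]
            chain.append(cur)
        if any(c in used for c in chain):
            continue
        used.update(chain)
        paths.append(chain)
    for n in sorted(graph.nodes - used):  # branch nodes
        paths.append([n])

    contigs = []
    paths.sort(key=lambda p: min(p))
    for idx, chain in enumerate(paths):
        seq, layout = _splice_chain(chain, seq_of, graph)
        contigs.append(Contig(f"contig{idx + 1:05d}", seq, layout))
    return contigs


def _splice_chain(chain: list[str], seq_of: dict[str, str],
                  graph: OverlapGraph,
                  ) -> tuple[str, list[tuple[str, int, str]]]:
    """Consensus of a non-branching path by overlap-aware splicing.

    Walking the path in edge order, each read's junction with the growing
    contig is located by aligning the contig's overlap-spanning suffix inside
    the read; the read's extension past the junction is appended.  This keeps
    every consensus base anchored to a single read, so indel errors cannot
    shift downstream columns as they would in a rigid per-column vote.
    """
    first = chain[0]

    def oriented(rid: str) -> str:
        seq = seq_of[rid]
        return seq if graph.placement[rid][1] == "+" else revcomp(seq)

    contig = oriented(first)
    layout = [(first, 0, graph.placement[first][1])]
    prev = first
    for rid in chain[1:]:
        seq = oriented(rid)
        # expected overlap of this read with the contig comes from the edge
        # geometry; undershoot it a little (layout drift) and cap it (cost)
        expected_ov = len(seq_of[prev]) - graph.offsets[(prev, rid)]
        ov = max(15, min(expected_ov - 10, 300, len(contig), len(seq) - 1))
        res = edlib.align(contig[-ov:], seq, mode="HW", task="locations")
        end = res["locations"][0][1]
        offset = len(contig) - (end + 1)
        if end + 1 < len(seq):
            contig += seq[end + 1:]
        layout.append((rid, max(offset, 0), graph.placement[rid][1]))
        prev = rid
    return contig, layout


def n50(contig_lengths: Sequence[int], reference_length: int) -> int:
    """Shortest contig length at which all contigs that long or longer sum to
    at least half the reference length; 0 if never reached."""
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    if any(l < 0 for l in contig_lengths):
        raise ValueError("negative contig length")
    half = reference_length / 2
    running = 0
    for length in sorted(contig_lengths, reverse=True):
        running += length
        if running >= half:
            return length
    return 0


@dataclass
class AssemblyReport:
    n_contigs: int
    contig_lengths: list[int]
    n50: int
    pct_genome_matched: float
    misassembled_contigs: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (f"contigs={self.n_contigs} N50={self.n50} "
                f"genome_matched={self.pct_genome_matched:.2f}% "
                f"misassembly_flags={len(self.misassembled_contigs)}")


def pct_genome_matched(contigs: Sequence[Contig | SequenceRecord],
                       reference: SequenceRecord,
                       min_match: int = 100,
                       min_identity: float = 0.95,
                       chunk: int = 1000,
                       index: GenomeIndex | None = None,
                       ) -> tuple[float, list[str]]:
    """Percentage of reference positions covered by contig alignments.

    Contigs are aligned in ~``chunk``-bp pieces (both strands, local
    alignments of at least ``min_match`` bp at ``min_identity``); each
    reference position is counted once.  Also returns ids of contigs whose
    piece alignments are non-colinear (split-alignment misassembly flags).
    """
    if not len(reference.seq):
        raise ValueError("empty reference")
    if index is None:
        index = GenomeIndex(reference)
    covered = np.zeros(len(reference.seq), dtype=bool)
    flagged = []
    for contig in contigs:
        cid = getattr(contig, "id", "contig")
        seq = contig.seq
        if len(seq) < min_match:
            continue
        n_pieces = max(1, round(len(seq) / chunk))
        bounds = np.linspace(0, len(seq), n_pieces + 1).astype(int)
        anchors = []  # (piece offset, best hit) per placed piece
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            piece = SequenceRecord(f"{cid}:{lo}", seq[lo:hi])
            hits = map_read_to_genome(piece, index, min_identity=min_identity,
                                      min_coverage=0.5)
            if not hits:
                continue
            best = max(hits, key=lambda h: h.matching_bases)
            for h in hits:
                covered[h.start:h.end] = True
            anchors.append((lo, best))
        for (lo1, h1), (lo2, h2) in zip(anchors, anchors[1:]):
            expected = lo2 - lo1
            gap = (h2.start - h1.start) if h1.strand == "+" else (h1.end - h2.end)
            if h1.strand != h2.strand or abs(gap - expected) > chunk:
                flagged.append(cid)
                break
    return 100.0 * covered.mean(), flagged


def evaluate_assembly(contigs: Sequence[Contig],
                      reference: SequenceRecord,
                      min_match: int = 100) -> AssemblyReport:
    lengths = sorted((len(c.seq) for c in contigs), reverse=True)
    pct, flagged = pct_genome_matched(contigs, reference, min_match=min_match)
    return AssemblyReport(
        n_contigs=len(contigs),
        contig_lengths=lengths,
        n50=n50(lengths, len(reference.seq)),
        pct_genome_matched=pct,
        misassembled_contigs=flagged,
    )
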