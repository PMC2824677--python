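import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olcorrect.assembly import (build_contigs, build_graph, filter_overlaps,
                                n50, pct_genome_matched)
from olcorrect.io_formats import OverlapCandidate, SequenceRecord
from olcorrect.overlapper import find_overlap_candidates
from olcorrect.sequtil import SAME
from olcorrect.simulate import SimConfig, simulate_genome, simulate_reads

from _oracles import oracle_n50


def _seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _tiling_reads(genome, length=200, step=80):
    reads = []
    for i, start in enumerate(range(0, len(genome) - length + 1, step)):
        reads.append(SequenceRecord(f"r{i:03d}", genome[start:start + length]))
    return reads


class TestFilterOverlaps:
    def _cands(self, n):
        return [OverlapCandidate(f"a{i}", f"b{i}", SAME, 10, 10, 50, 50, 0, 0, 0)
                for i in range(n)]

    def test_predicted_false_removed(self):
        cands = self._cands(10)
        kept = filter_overlaps(cands, [True] * 7 + [False] * 3)
        assert kept == cands[:7]

    def test_none_false_is_identity(self):
        cands = self._cands(5)
        assert filter_overlaps(cands, [True] * 5) == cands

    def test_all_false_gives_empty_with_warning(self, caplog):
        cands = self._cands(4)
        with caplog.at_level("WARNING"):
            assert filter_overlaps(cands, [False] * 4) == []
        assert "predicted false" in caplog.text

    def test_missing_prediction_raises(self):
        cands = self._cands(3)
        with pytest.raises(ValueError, match="predictions"):
            filter_overlaps(cands, [True])


class TestBuildGraph:
    def test_transitive_edge_removed(self, rng):
        genome = _seq(rng, 500)
        reads = [SequenceRecord("a", genome[0:200]),
                 SequenceRecord("b", genome[80:280]),
                 SequenceRecord("c", genome[160:360])]
        cands = find_overlap_candidates(reads)
        assert len(cands) == 3  # a-b, b-c and the transitive a-c
        graph = build_graph(reads, cands)
        assert len(graph.edges) == 2
        assert graph.n_transitive_removed == 1
        assert ("a", "c", SAME) not in graph.edges

    def test_identical_read_contained(self, rng):
        seq = _seq(rng, 150)
        reads = [SequenceRecord("a", seq), SequenceRecord("b", seq)]
        graph = build_graph(reads, find_overlap_candidates(reads))
        assert graph.containment == {"b": "a"}
        assert graph.nodes == {"a"}

    def test_two_disjoint_pairs_give_two_components(self, rng):
        g1, g2 = _seq(rng, 300), _seq(rng, 300)
        reads = [SequenceRecord("a", g1[:200]), SequenceRecord("b", g1[100:]),
                 SequenceRecord("c", g2[:200]), SequenceRecord("d", g2[100:])]
        graph = build_graph(reads, find_overlap_candidates(reads))
        comps = graph.components()
        assert sorted(sorted(c) for c in comps) == [["a", "b"], ["c", "d"]]

    def test_unknown_read_raises(self):
        cand = OverlapCandidate("a", "zz", SAME, 10, 10, 50, 50, 0, 0, 0)
        with pytest.raises(ValueError, match="unknown read"):
            build_graph([SequenceRecord("a", "ACGT" * 20)], [cand])


class TestBuildContigs:
    def test_error_free_tiling_reconstructs_source(self, rng):
        genome = _seq(rng, 5000)
        reads = _tiling_reads(genome)
        graph = build_graph(reads, find_overlap_candidates(reads))
        contigs = build_contigs(graph, reads)
        assert len(contigs) == 1
        assert contigs[0].seq in genome  # exact reconstruction

    def test_repeat_fixture_breaks_without_correction(self, rng):
        # a 2-copy exact repeat longer than any read, flanked by unique
        # sequence: repeat-induced overlaps leave branches that terminate
        # contigs, so the repeat region fragments relative to a clean tiling
        unit = _seq(rng, 400)
        genome = _seq(rng, 1000) + unit + _seq(rng, 1000) + unit + _seq(rng, 1000)
        reads = _tiling_reads(genome, length=300, step=60)
        cands = find_overlap_candidates(reads)
        graph = build_graph(reads, cands)
        contigs = build_contigs(graph, reads)
        assert len(contigs) > 1

    def test_empty_graph_gives_no_contigs(self):
        graph = build_graph([SequenceRecord("a", "ACGT" * 30)], [])
        contigs = build_contigs(graph, [SequenceRecord("a", "ACGT" * 30)])
        assert len(contigs) == 1  # isolated read becomes a singleton contig
        assert contigs[0].seq == "ACGT" * 30


class TestN50:
    def test_exactly_half(self):
        assert n50([50], 100) == 50

    def test_hand_worked_cumulative(self):
        # cumulative sums 50, 90, 120 first reach 100 at the third contig
        assert n50([50, 40, 30], 200) == 30

    def test_cannot_reach_half(self):
        assert n50([10], 100) == 0

    def test_negative_length_raises(self):
        with pytest.raises(ValueError):
            n50([-1, 50], 100)

    @given(st.lists(st.integers(0, 10_000), max_size=40),
           st.integers(1, 100_000))
    @settings(deadline=None, max_examples=1000)
    def test_matches_brute_force_threshold_scan(self, lengths, ref):
        assert n50(lengths, ref) == oracle_n50(lengths, ref)


class TestPctGenomeMatched:
    def test_contig_equal_to_reference(self, rng):
        ref = SequenceRecord("g", _seq(rng, 5000))
        pct, flagged = pct_genome_matched([SequenceRecord("c", ref.seq)], ref)
        assert pct == pytest.approx(100.0)
        assert flagged == []

    def test_half_reference_contig(self, rng):
        ref = SequenceRecord("g", _seq(rng, 5000))
        pct, _ = pct_genome_matched([SequenceRecord("c", ref.seq[:2500])], ref)
        assert pct == pytest.approx(50.0, abs=1.0)

    def test_duplicate_coverage_not_double_counted(self, rng):
        ref = SequenceRecord("g", _seq(rng, 5000))
        half = ref.seq[:2500]
        pct, _ = pct_genome_matched(
            [SequenceRecord("c1", half), SequenceRecord("c2", half)], ref)
        assert pct == pytest.approx(50.0, abs=1.0)

    def test_chimeric_contig_flagged(self, rng):
        ref = SequenceRecord("g", _seq(rng, 8000))
        chimera = ref.seq[:2000] + ref.seq[5000:7000]
        pct, flagged = pct_genome_matched([SequenceRecord("c", chimera)], ref)
        assert flagged == ["c"]


class TestTruthFilteredAssemblyImprovement:
    def test_removing_truth_false_overlaps_never_hurts_unique_regions(self, rng):
        """Filtering with ground-truth labels must not reduce reconstructed
        unique sequence relative to no filtering."""
        from olcorrect.ground_truth import label_overlaps
        from olcorrect.simulate import RepeatSpec
        cfg = SimConfig(genome_length=20_000,
                        repeat_specs=[RepeatSpec(600, 3, 0.0)],
                        related_genomes=[], coverage=8,
                        read_length_mean=300, read_length_sd=30,
                        substitution_rate=0.0, indel_rate=0.0, seed=17)
        genome, _ = simulate_genome(cfg)
        reads, placements = simulate_reads(genome, cfg)
        cands = find_overlap_candidates(reads)
        labels = [l.label for l in label_overlaps(cands, placements)]
        ref = genome

        def matched(cand_subset):
            graph = build_graph(reads, cand_subset)
            contigs = build_contigs(graph, reads)
            pct, _ = pct_genome_matched(contigs, ref)
            return pct

        assert matched(filter_overlaps(cands, labels)) >= matched(cands) - 1.0
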