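import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olcorrect.comp_features import (NON_OVERLAPPING, OVERLAPPING,
                                     ReferenceHit, comparative_evidence,
                                     comparative_score,
                                     enumerate_combinations,
                                     estimate_genome_identity,
                                     map_read_to_genome)
from olcorrect.io_formats import OverlapCandidate, SequenceRecord
from olcorrect.sequtil import FLIPPED, SAME, revcomp
from olcorrect.simulate import derive_related_genome


def _seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def hit(read_id, start, end, strand="+", matching=None):
    length = end - start
    return ReferenceHit(read_id, "g", start, end, strand,
                        matching if matching is not None else length,
                        1.0, 1.0)


def cand(a_hang=50, orientation=SAME):
    return OverlapCandidate("A", "B", orientation, a_hang, a_hang,
                            100, 100, 0, 0, 0)


class TestMapReadToGenome:
    def test_exact_substring_maps_once(self, rng):
        genome = SequenceRecord("g", _seq(rng, 3000))
        read = SequenceRecord("r", genome.seq[500:900])
        hits = map_read_to_genome(read, genome)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (500, 900, "+")
        assert h.identity == 1.0 and h.coverage == 1.0
        assert h.matching_bases == 400

    def test_revcomp_substring_maps_minus_strand(self, rng):
        genome = SequenceRecord("g", _seq(rng, 3000))
        read = SequenceRecord("r", revcomp(genome.seq[500:900]))
        hits = map_read_to_genome(read, genome)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].strand) == (500, 900, "-")

    def test_highly_diverged_read_has_no_hit(self, rng):
        genome = SequenceRecord("g", _seq(rng, 3000))
        frag = SequenceRecord("f", genome.seq[500:900])
        diverged, identity = derive_related_genome(frag, 0.25, 5,
                                                   indel_fraction=0.0)
        assert identity < 0.80
        read = SequenceRecord("r", diverged.seq)
        assert map_read_to_genome(read, genome) == []

    def test_repeat_read_maps_to_every_copy(self, rng):
        unit = _seq(rng, 500)
        genome = SequenceRecord(
            "g", _seq(rng, 800) + unit + _seq(rng, 800) + unit + _seq(rng, 800))
        read = SequenceRecord("r", unit[50:450])
        hits = map_read_to_genome(read, genome)
        assert len(hits) == 2


class TestEnumerateCombinations:
    def test_two_by_two_placements_give_two_of_each_class(self):
        """Two placements per read at repeat copies X and Y give two
        overlapping and two non-overlapping combinations."""
        X, Y = 1000, 5000
        hits_a = [hit("A", X, X + 400), hit("A", Y, Y + 400)]
        hits_b = [hit("B", X + 50, X + 450), hit("B", Y + 50, Y + 450)]
        combos = enumerate_combinations(hits_a, hits_b, cand(a_hang=50))
        assert len(combos) == 4
        classes = [c[2] for c in combos]
        assert classes.count(OVERLAPPING) == 2
        assert classes.count(NON_OVERLAPPING) == 2

    def test_single_consistent_placement_is_overlapping(self):
        combos = enumerate_combinations([hit("A", 0, 400)],
                                        [hit("B", 50, 450)], cand(a_hang=50))
        assert [c[2] for c in combos] == [OVERLAPPING]
        assert combos[0][3] == 800  # matching bases of both hits

    def test_strand_inconsistency_is_non_overlapping(self):
        combos = enumerate_combinations([hit("A", 0, 400, "+")],
                                        [hit("B", 50, 450, "-")],
                                        cand(a_hang=50))
        assert [c[2] for c in combos] == [NON_OVERLAPPING]

    def test_offset_beyond_tolerance_is_non_overlapping(self):
        combos = enumerate_combinations([hit("A", 0, 400)],
                                        [hit("B", 150, 550)],
                                        cand(a_hang=50), tolerance=30)
        assert [c[2] for c in combos] == [NON_OVERLAPPING]

    def test_flipped_candidate_requires_opposite_strands(self):
        combos = enumerate_combinations([hit("A", 0, 400, "+")],
                                        [hit("B", 50, 450, "-")],
                                        cand(a_hang=50, orientation=FLIPPED))
        assert [c[2] for c in combos] == [OVERLAPPING]

    def test_combination_count_is_product(self, rng):
        hits_a = [hit("A", int(s), int(s) + 100)
                  for s in rng.integers(0, 10_000, size=5)]
        hits_b = [hit("B", int(s), int(s) + 100)
                  for s in rng.integers(0, 10_000, size=7)]
        assert len(enumerate_combinations(hits_a, hits_b, cand())) == 35


class TestComparativeScore:
    def test_tie_gives_zero(self):
        assert comparative_score(750, 750) == 0.0

    def test_positive_margin_closed_form(self):
        assert comparative_score(107, 100) == pytest.approx(3.0)

    def test_negative_margin_has_negative_sign(self):
        assert comparative_score(100, 103) == pytest.approx(-2.0)

    def test_missing_when_both_absent(self):
        assert comparative_score(None, None) is None

    def test_absent_class_treated_as_zero(self):
        assert comparative_score(7, None) == pytest.approx(3.0)
        assert comparative_score(None, 7) == pytest.approx(-3.0)

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(deadline=None)
    def test_antisymmetry(self, a, b):
        assert comparative_score(a, b) == pytest.approx(-comparative_score(b, a))

    @given(st.integers(0, 5_000), st.integers(0, 5_000), st.integers(1, 100))
    @settings(deadline=None)
    def test_monotone_in_margin(self, a, b, delta):
        assert comparative_score(a + delta, b) > comparative_score(a, b)


class TestComparativeEvidence:
    def test_unique_consistent_pair_scores_positive(self, rng):
        genome = SequenceRecord("g", _seq(rng, 3000))
        read_a = SequenceRecord("A", genome.seq[500:900])
        read_b = SequenceRecord("B", genome.seq[550:950])
        hits_a = {"g": map_read_to_genome(read_a, genome)}
        hits_b = {"g": map_read_to_genome(read_b, genome)}
        ev = comparative_evidence(cand(a_hang=50), hits_a, hits_b)
        assert ev.score is not None and ev.score > 0
        assert ev.max_s_nonovl is None

    def test_repeat_induced_false_pair_scores_negative(self, rng):
        # two exact repeat copies with diverged flanks: each read's best
        # placement is its own copy, and those placements do not co-locate
        unit = _seq(rng, 300)
        genome = SequenceRecord(
            "g", _seq(rng, 500) + unit + _seq(rng, 500) + unit + _seq(rng, 500))
        copy1, copy2 = 500, 1300
        # read A: flank + start of copy 1; read B: end of copy 2 + flank
        read_a = SequenceRecord("A", genome.seq[copy1 - 150:copy1 + 250])
        read_b = SequenceRecord("B", genome.seq[copy2 + 50:copy2 + 450])
        hits_a = {"g": map_read_to_genome(read_a, genome)}
        hits_b = {"g": map_read_to_genome(read_b, genome)}
        # false candidate: aligned via the repeat as if B followed A
        false_cand = OverlapCandidate("A", "B", SAME, 200, 200, 200, 200, 0, 0, 0)
        ev = comparative_evidence(false_cand, hits_a, hits_b)
        assert ev.score is not None and ev.score < 0

    def test_unmapped_read_yields_missing(self, rng):
        genome = SequenceRecord("g", _seq(rng, 2000))
        read_a = SequenceRecord("A", genome.seq[100:500])
        read_b = SequenceRecord("B", _seq(rng, 400))  # unrelated
        ev = comparative_evidence(
            cand(), {"g": map_read_to_genome(read_a, genome)},
            {"g": map_read_to_genome(read_b, genome)})
        assert ev.score is None


class TestGenomeIdentity:
    def test_identical_genomes(self, rng):
        g = SequenceRecord("g", _seq(rng, 20_000))
        assert estimate_genome_identity(g, g) == pytest.approx(1.0)

    def test_diverged_genome_estimate_tracks_divergence(self, rng):
        g = SequenceRecord("g", _seq(rng, 50_000))
        rel, identity = derive_related_genome(g, 0.08, 3)
        est = estimate_genome_identity(g, rel)
        assert est == pytest.approx(identity, abs=0.02)
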