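import numpy as np
import pytest

from senrna.engines.base import EnsembleSample
from senrna.neutrality import (
    alignment_neutrality,
    bp_distance_neutrality,
    centroid_structure,
    mutant_neighbors,
    pcc_neutrality,
    positional_neutrality,
    sampled_bprob,
    sen_distance,
    sen_neutrality,
)
from senrna.structures import SecondaryStructure, Sequence, StructuredAlignment, parse_dot_bracket

from .oracles import exact_sen_neutrality, mfe_bp_neutrality, random_rna


def sample_of(dbs: list[str], seq: str) -> EnsembleSample:
    return EnsembleSample.from_structures(
        [parse_dot_bracket(db) for db in dbs], Sequence(seq)
    )


class TestMutantNeighbors:
    def test_dinucleotide_example(self):
        ms = mutant_neighbors(Sequence("AC"))
        assert [m.residues for m in ms.mutants] == ["CC", "GC", "UC", "AA", "AG", "AU"]

    def test_single_base(self):
        ms = mutant_neighbors(Sequence("G"))
        assert {m.residues for m in ms.mutants} == {"A", "C", "U"}

    def test_combinatorics_and_hamming(self):
        rng = np.random.default_rng(2)
        seq = Sequence(random_rna(rng, 30))
        ms = mutant_neighbors(seq)
        assert len(ms) == 3 * 30
        assert len({m.residues for m in ms.mutants}) == 3 * 30
        for m in ms.mutants:
            assert sum(a != b for a, b in zip(seq.residues, m.residues)) == 1
        for i in range(30):
            assert len(ms.by_position(i)) == 3
            for m in ms.by_position(i):
                assert m.residues[i] != seq[i]


class TestSampledBprob:
    def test_direct_count(self):
        p = sampled_bprob(sample_of(["()..", "(..)"], "GCGC")).entries
        assert p[0, 1] == pytest.approx(0.5)
        assert p[0, 3] == pytest.approx(0.5)
        assert p.sum() == pytest.approx(2.0)  # symmetric double count

    def test_identical_samples_binary(self):
        p = sampled_bprob(sample_of(["(())"] * 7, "GGCC")).entries
        assert set(np.unique(p)) <= {0.0, 1.0}

    def test_row_sums(self):
        p = sampled_bprob(sample_of(["(())", "()..", "...."], "GCGC")).entries
        assert (p.sum(axis=1) <= 1 + 1e-12).all()


class TestCentroid:
    def test_majority_pairs(self):
        c = centroid_structure(sample_of(["(())", "(())", "().."], "GGCC"))
        assert c.pairs == frozenset({(0, 3), (1, 2)})

    def test_exact_half_excluded(self):
        c = centroid_structure(sample_of(["()..", "(..)"], "GCGC"))
        assert c.pairs == frozenset()

    def test_single_sample_is_itself(self):
        c = centroid_structure(sample_of(["(.).."], "GACGC"))
        assert c.pairs == frozenset({(0, 2)})


class TestSenDistance:
    def test_added_pair_not_penalized(self):
        t = SecondaryStructure(frozenset({(0, 9), (1, 8), (2, 7)}), 10)
        sample = EnsembleSample.from_structures(
            [SecondaryStructure(frozenset({(0, 9), (2, 7), (3, 6)}), 10)],
            Sequence("GGGGAAUCCC"),
        )
        assert sen_distance(t, sample) == pytest.approx(2 / 3)

    def test_superset_scores_one(self):
        t = SecondaryStructure(frozenset({(0, 9)}), 10)
        sample = EnsembleSample.from_structures(
            [SecondaryStructure(frozenset({(0, 9), (1, 8)}), 10)] * 5,
            Sequence("GGGGAAUCCC"),
        )
        assert sen_distance(t, sample) == 1.0

    def test_disjoint_scores_zero(self):
        t = SecondaryStructure(frozenset({(0, 9)}), 10)
        sample = EnsembleSample.from_structures(
            [SecondaryStructure(frozenset({(1, 8)}), 10)], Sequence("GGGGAAUCCC")
        )
        assert sen_distance(t, sample) == 0.0

    def test_empty_reference_undefined(self):
        t = SecondaryStructure(frozenset(), 4)
        with pytest.raises(ValueError):
            sen_distance(t, sample_of(["...."], "ACGU"))


class TestMetamorphic:
    """Augmenting every sampled structure with extra non-conflicting pairs
    must leave SEN unchanged but strictly decrease bp-distance neutrality —
    the defining difference between the two metrics."""

    def test_sen_ignores_added_pairs_bp_distance_does_not(self):
        t = SecondaryStructure(frozenset({(0, 11), (1, 10)}), 12)
        base = [
            SecondaryStructure(frozenset({(0, 11)}), 12),
            SecondaryStructure(frozenset({(0, 11), (1, 10)}), 12),
        ]
        extra = (3, 8)  # non-conflicting addition
        augmented = [
            SecondaryStructure(s.pairs | {extra}, 12) for s in base
        ]
        seq = Sequence("GGAGAAAAUCCC")
        s0 = EnsembleSample.from_structures(base, seq)
        s1 = EnsembleSample.from_structures(augmented, seq)
        assert sen_distance(t, s1) == sen_distance(t, s0)
        # bp-distance terms: d grows by 1 for every augmented structure
        for orig, aug in zip(base, augmented):
            d0 = len(t.pairs.symmetric_difference(orig.pairs))
            d1 = len(t.pairs.symmetric_difference(aug.pairs))
            assert d1 == d0 + 1
            assert (1 - d1 / 12) < (1 - d0 / 12)


class TestSenNeutrality:
    def test_exact_mode_matches_enumeration_oracle(self, toy, hairpin):
        seq, struct = hairpin
        expected = exact_sen_neutrality(seq.residues, struct.pairs)
        got = sen_neutrality(seq, struct, toy, n_samples=0)
        assert got.value == pytest.approx(expected, abs=1e-9)

    def test_sampled_mode_within_binomial_error(self, toy, hairpin):
        seq, struct = hairpin
        expected = exact_sen_neutrality(seq.residues, struct.pairs)
        n = 1000
        got = sen_neutrality(seq, struct, toy, n_samples=n, seed=1)
        # conservative bound on the sampling sd of the overall mean
        sigma = np.sqrt(0.25 / (n * 3 * len(seq)))
        assert abs(got.value - expected) < 3 * sigma + 1e-12

    def test_profile_mean_equals_global(self, toy, hairpin):
        seq, struct = hairpin
        r = sen_neutrality(seq, struct, toy, n_samples=200, seed=4)
        assert r.per_position.mean() == pytest.approx(r.value)
        profile = positional_neutrality(seq, struct, toy, n_samples=200, seed=4)
        assert np.array_equal(profile, r.per_position)

    def test_deterministic_under_seed(self, toy, hairpin):
        seq, struct = hairpin
        a = sen_neutrality(seq, struct, toy, n_samples=100, seed=9)
        b = sen_neutrality(seq, struct, toy, n_samples=100, seed=9)
        assert a.value == b.value
        assert np.array_equal(a.per_position, b.per_position)

    def test_loop_positions_more_neutral_than_stem(self, toy):
        """Stem mutations disrupt structure more than loop mutations
        (rank property on a riboswitch-like two-stem fixture)."""
        seq = Sequence("GGGGGAAAACCCCC")
        struct = toy.mfe_structure(seq)
        assert len(struct) >= 5
        profile = sen_neutrality(seq, struct, toy, n_samples=0).per_position
        partner = struct.partner_array()
        loop_scores = profile[partner == -1]
        stem_scores = profile[partner != -1]
        assert np.median(loop_scores) > np.median(stem_scores)


class TestBpDistanceNeutrality:
    def test_term_arithmetic(self):
        t = parse_dot_bracket("(())")
        mutant_mfe = parse_dot_bracket("()..")
        d = len(t.pairs.symmetric_difference(mutant_mfe.pairs))
        assert 1 - d / 4 == pytest.approx(0.25)

    def test_matches_enumeration_oracle(self, toy):
        rng = np.random.default_rng(5)
        for _ in range(5):
            seq = random_rna(rng, 10)
            struct = toy.mfe_structure(Sequence(seq))
            expected = mfe_bp_neutrality(seq, struct.pairs)
            got = bp_distance_neutrality(Sequence(seq), struct, toy)
            assert got.value == pytest.approx(expected)

    def test_identity_case(self, toy, hairpin):
        seq, struct = hairpin
        r = bp_distance_neutrality(seq, struct, toy)
        assert 0.0 <= r.value <= 1.0


class TestPccNeutrality:
    def test_identical_centroid_term_is_one(self, toy, hairpin):
        # every mutant whose centroid equals V(T) contributes 1.0; on the
        # strong GC hairpin most do, so the value is high
        seq, struct = hairpin
        r = pcc_neutrality(seq, struct, toy, n_samples=300, seed=2)
        assert 0.5 < r.value <= 1.0

    def test_degenerate_convention(self):
        from senrna.neutrality import _pcc_term

        flat = np.zeros(6, dtype=np.int8)
        assert _pcc_term(flat, flat.copy(), "plus") == 1.0
        other = flat.copy()
        other[0] = 1
        assert _pcc_term(flat, other, "plus") == 0.5

    def test_anticorrelated_balanced_vectors(self):
        from senrna.neutrality import _pcc_term

        v = np.array([1, 1, 0, 0], dtype=np.int8)
        assert _pcc_term(v, 1 - v, "plus") == pytest.approx(0.0)
        assert _pcc_term(v, v, "plus") == pytest.approx(1.0)

    def test_printed_convention_inverts(self):
        from senrna.neutrality import _pcc_term

        v = np.array([1, 0, 1, 0], dtype=np.int8)
        assert _pcc_term(v, v, "printed") == pytest.approx(0.0)


class TestAlignmentNeutrality:
    def test_two_row_fixture(self, toy):
        aln = StructuredAlignment(
            [("a", "GGGAAACCC"), ("b", "GGCAAAGCC")], "(((...)))", "given"
        )
        results, skips = alignment_neutrality(aln, toy, "SEN", n_samples=100, seed=0)
        assert len(results) == 2 and not skips
        assert all(0 <= r.value <= 1 for r in results)

    def test_ambiguous_row_skipped(self, toy):
        aln = StructuredAlignment(
            [("good", "GGGAAACCC"), ("bad", "GGNAAACCC")], "(((...)))", "given"
        )
        results, skips = alignment_neutrality(aln, toy, "SEN", n_samples=50, seed=0)
        assert [r.sequence_id for r in results] == ["good"]
        assert skips[0].sequence_id == "bad" and "ambiguous" in skips[0].reason

    def test_empty_structure_row_skipped(self, toy):
        aln = StructuredAlignment(
            # row 'nopair' pairs A with C at the consensus pair: non-canonical
            [("good", "GGGAAACCC"), ("nopair", "AAAAAACAA")], "..(...)..", "given"
        )
        results, skips = alignment_neutrality(aln, toy, "SEN", n_samples=50, seed=0)
        assert [r.sequence_id for r in results] == ["good"]
        assert skips[0].reason == "empty reference structure"

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            StructuredAlignment([], "....", "given")
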