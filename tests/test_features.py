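import math
from collections import Counter

import numpy as np
import pytest

from senrna.features import (
    FeatureVector,
    disruption_regression,
    esdc,
    feature_vector,
    label_disrupting,
    mean_pairwise_identity,
    mean_stem_entropy,
    mean_stem_mutual_information,
    structure_conservation_index,
    train_evaluate_svm,
    zscore_mfe,
)
from senrna.structures import StructuredAlignment, parse_dot_bracket


def aln_of(rows, consensus):
    return StructuredAlignment(
        [(f"s{i}", r) for i, r in enumerate(rows)], consensus, "given"
    )


class TestStemEntropy:
    def test_conserved_column_zero_bits(self):
        aln = aln_of(["GAAAAC"] * 4, "(....)")
        assert mean_stem_entropy(aln) == 0.0

    def test_two_base_column_one_bit(self):
        aln = aln_of(["GAAAAC", "GAAAAC", "UAAAAA", "UAAAAA"], "(....)")
        assert mean_stem_entropy(aln) == pytest.approx(1.0)

    def test_bounded_by_two_bits(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            rows = ["".join(rng.choice(list("ACGU"), 8)) for _ in range(6)]
            aln = aln_of(rows, "((....))")
            assert 0 <= mean_stem_entropy(aln) <= 2.0

    def test_no_pairs_errors(self):
        with pytest.raises(ValueError):
            mean_stem_entropy(aln_of(["ACGU"] * 3, "...."))


class TestStemMutualInformation:
    def test_perfect_covariation_two_bits(self):
        aln = aln_of(["GAAAAC", "CAAAAG", "AAAAAU", "UAAAAA"], "(....)")
        assert mean_stem_mutual_information(aln) == pytest.approx(2.0)

    def test_identical_rows_zero(self):
        aln = aln_of(["GAAAAC"] * 5, "(....)")
        assert mean_stem_mutual_information(aln) == 0.0

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            rows = ["".join(rng.choice(list("ACGU"), 8)) for _ in range(5)]
            aln = aln_of(rows, "((....))")
            assert mean_stem_mutual_information(aln) >= 0

    def test_matches_bruteforce_tables(self):
        """MI and entropy agree with a direct frequency-table computation
        on a random small alignment."""
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(list("ACGU"), 10)) for _ in range(8)]
        consensus = "((......))"
        aln = aln_of(rows, consensus)
        struct = parse_dot_bracket(consensus)
        # entropy, independently
        ents = []
        for col in sorted({i for p in struct.pairs for i in p}):
            counts = Counter(r[col] for r in rows)
            n = sum(counts.values())
            ents.append(-sum(c / n * math.log2(c / n) for c in counts.values()))
        assert mean_stem_entropy(aln) == pytest.approx(np.mean(ents))
        # MI, independently
        mis = []
        for i, j in sorted(struct.pairs):
            joint = Counter((r[i], r[j]) for r in rows)
            n = sum(joint.values())
            pi = Counter(r[i] for r in rows)
            pj = Counter(r[j] for r in rows)
            mis.append(sum(
                c / n * math.log2((c / n) / ((pi[a] / n) * (pj[b] / n)))
                for (a, b), c in joint.items()
            ))
        assert mean_stem_mutual_information(aln) == pytest.approx(np.mean(mis))


class TestPairwiseIdentity:
    def test_identical_rows(self):
        assert mean_pairwise_identity(aln_of(["ACGU"] * 3, "....")) == 1.0

    def test_single_mismatch(self):
        assert mean_pairwise_identity(aln_of(["AAAA", "AAAU"], "....")) == 0.75

    def test_row_order_symmetric(self):
        a = mean_pairwise_identity(aln_of(["ACGU", "ACGA", "UCGU"], "...."))
        b = mean_pairwise_identity(aln_of(["UCGU", "ACGA", "ACGU"], "...."))
        assert a == pytest.approx(b)

    def test_gap_handling(self):
        # both-gapped column excluded; gap-vs-base is a mismatch
        aln = aln_of(["A-GU", "A-GA"], "....")
        assert mean_pairwise_identity(aln) == pytest.approx(2 / 3)

    def test_single_row_errors(self):
        with pytest.raises(ValueError):
            mean_pairwise_identity(aln_of(["ACGU"], "...."))


class TestZscoreAndSci:
    def test_zscore_arithmetic(self, toy, monkeypatch):
        """Row MFE -10 against shuffle MFEs {-6, -8}: z = -3/1.4142."""
        aln = aln_of(["GGGAAACCC"], ".........")
        energies = iter([-10.0, -6.0, -8.0])
        monkeypatch.setattr(toy, "mfe_energy", lambda s: next(energies))
        z = zscore_mfe(aln, toy, n_shuffles=2, seed=0)
        assert z == pytest.approx(-3 / math.sqrt(2))

    def test_homopolymer_rows_zero(self, toy):
        aln = aln_of(["AAAAAAAA"] * 2, "........")
        assert zscore_mfe(aln, toy, n_shuffles=5, seed=0) == 0.0

    def test_sci_identical_rows_is_one(self, toy):
        aln = aln_of(["GGGAAACCC"] * 4, "(((...)))")
        assert structure_conservation_index(aln, toy) == pytest.approx(1.0)

    def test_sci_unfoldable_rows_zero(self, toy):
        aln = aln_of(["AAAAAAA"] * 3, ".......")
        assert structure_conservation_index(aln, toy) == 0.0


class TestFeatureVector:
    def test_all_fields_populated(self, toy, fixture_alignment):
        fv = feature_vector(fixture_alignment, toy, True, "SEN",
                            n_samples=50, seed=0, n_shuffles=10)
        arr = fv.as_array()
        assert arr.shape == (7,) and np.isfinite(arr).all()
        assert fv.n_sequences == fixture_alignment.n_rows

    def test_without_neutrality(self, toy, fixture_alignment):
        fv = feature_vector(fixture_alignment, toy, False, n_shuffles=10)
        assert fv.neutrality is None
        assert fv.as_array().shape == (6,)
        with pytest.raises(ValueError):
            fv.as_array(("neutrality",))

    def test_deterministic(self, toy, fixture_alignment):
        a = feature_vector(fixture_alignment, toy, True, "SEN", 50, seed=3, n_shuffles=10)
        b = feature_vector(fixture_alignment, toy, True, "SEN", 50, seed=3, n_shuffles=10)
        assert np.array_equal(a.as_array(), b.as_array())


def _fv(neutrality, label):
    return FeatureVector(0, 0, 0, 0, 0, 5, neutrality=neutrality, label=label)


class TestSvm:
    def test_perfect_separation_auc_one(self):
        rng = np.random.default_rng(0)
        pos = [_fv(0.8 + 0.1 * rng.random(), "structured") for _ in range(15)]
        neg = [_fv(0.1 + 0.1 * rng.random(), "other") for _ in range(15)]
        auc, roc = train_evaluate_svm(pos, neg, ("neutrality",), seed=0)
        assert auc == 1.0
        assert roc.shape[1] == 2

    def test_shuffled_labels_near_half(self):
        """With labels carrying no signal the cross-validated AUC hovers
        around 0.5 (stochastic null property, 20 repeats)."""
        rng = np.random.default_rng(1)
        aucs = []
        for rep in range(20):
            values = rng.random(30)
            pos = [_fv(v, "structured") for v in values[:15]]
            neg = [_fv(v, "other") for v in values[15:]]
            auc, _ = train_evaluate_svm(pos, neg, ("neutrality",), seed=rep)
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        values = rng.random(30)
        pos = [_fv(v, "structured") for v in values[:15]]
        neg = [_fv(v, "other") for v in values[15:]]
        auc1, _ = train_evaluate_svm(pos, neg, ("neutrality",), seed=0)
        pos2 = [_fv(np.exp(3 * v), "structured") for v in values[:15]]
        neg2 = [_fv(np.exp(3 * v), "other") for v in values[15:]]
        auc2, _ = train_evaluate_svm(pos2, neg2, ("neutrality",), seed=0)
        assert auc1 == pytest.approx(auc2, abs=0.08)

    def test_too_few_examples_rejected(self):
        pos = [_fv(0.9, "structured")] * 5
        neg = [_fv(0.1, "other")] * 15
        with pytest.raises(ValueError):
            train_evaluate_svm(pos, neg, ("neutrality",))


class TestEsdc:
    @pytest.mark.parametrize("pcc,length,expected", [
        (1.0, 100, 0.0),
        (0.9, 100, pytest.approx(1.0)),
        (0.0, 4, pytest.approx(2.0)),
    ])
    def test_values(self, pcc, length, expected):
        assert esdc(pcc, length) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            esdc(1.5, 10)
        with pytest.raises(ValueError):
            esdc(0.5, 0)

    def test_top_half_labeled(self):
        labels = label_disrupting([0.1, 0.9, 0.5, 0.7])
        assert labels == [False, True, False, True]
        assert sum(labels) == 2

    def test_tie_break_stable(self):
        labels = label_disrupting([0.5, 0.5, 0.5, 0.5])
        assert labels == [True, True, False, False]

    def test_disruption_regression_separable(self):
        neut = np.array([0.9, 0.85, 0.8, 0.2, 0.15, 0.1])
        disrupt = np.array([0, 0, 0, 1, 1, 1])
        auc, _ = disruption_regression(neut, disrupt)
        assert auc == 1.0
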