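import numpy as np
import pytest

from r3dfold.covariation import (CovariationConfig, classify_pairs,
                                 expected_null_count, load_external_pairs,
                                 null_scores, pair_scores, _mi_matrix, _onehot)
from r3dfold.errors import ContractError, FormatError
from r3dfold.synthetic import PlantSpec, PlantedHelix, generate

from conftest import make_alignment

PERFECT_WC = ["AU", "AU", "GC", "GC", "CG", "CG", "UA", "UA"]


class TestPairScores:
    def test_perfect_covariation_scores_two_bits_raw(self):
        aln = make_alignment(PERFECT_WC)
        mi = _mi_matrix(_onehot(aln))
        assert mi[0, 1] == pytest.approx(2.0)

    def test_constant_columns_score_zero(self):
        aln = make_alignment(["AU", "AU", "AU"])
        mi = _mi_matrix(_onehot(aln))
        assert mi[0, 1] == pytest.approx(0.0)

    def test_apc_of_single_scored_pair_is_its_own_score(self):
        aln = make_alignment(PERFECT_WC)
        assert pair_scores(aln)[(0, 1)] == pytest.approx(0.0)

    def test_single_sequence_rejected(self):
        with pytest.raises(ContractError, match="2 sequences"):
            pair_scores(make_alignment(["ACGU"]))

    def test_gap_heavy_columns_not_scored(self):
        aln = make_alignment(["A-CG", "A-CG", "AUCG", "A-CG"])
        assert all(1 not in p for p in pair_scores(aln))

    def test_monotonicity_adding_covarying_sequences(self):
        """Adding a fresh compensatory pair type never decreases raw MI."""
        base = ["AU", "AU", "GC", "GC"]
        prev = None
        for extra in (["CG", "CG"], ["UA", "UA"]):
            base = base + extra
            mi = _mi_matrix(_onehot(make_alignment(base)))[0, 1]
            if prev is not None:
                assert mi >= prev - 1e-9
            prev = mi


class TestNullScores:
    def test_pool_size_counts_shuffles_times_pairs(self):
        aln = make_alignment(["ACGU", "AGCU", "ACGA", "UCGU"])
        cfg = CovariationConfig(n_null_shuffles=2, seed=0)
        assert len(null_scores(aln, cfg)) == 2 * 6

    def test_deterministic_under_seed(self):
        aln = make_alignment(["ACGU", "AGCU", "ACGA", "UCGU"])
        cfg = CovariationConfig(n_null_shuffles=5, seed=11)
        np.testing.assert_array_equal(null_scores(aln, cfg),
                                      null_scores(aln, cfg))

    def test_identical_sequences_give_zero_nulls(self):
        aln = make_alignment(["ACGU"] * 5)
        cfg = CovariationConfig(n_null_shuffles=3, seed=0)
        np.testing.assert_allclose(null_scores(aln, cfg), 0.0, atol=1e-12)


class TestClassify:
    def test_planted_pair_is_positive(self):
        # perfectly covarying pair in an otherwise random alignment
        spec = PlantSpec(length=14, n_seqs=30, mutation_rate=1.0,
                         helix_mutation_rate=0.0,
                         helices=[PlantedHelix([(3, 10)], 1.0)], seed=7)
        aln, _ = generate(spec)
        res = classify_pairs(aln, CovariationConfig(seed=7))
        labels = {r.pair: r.label for r in res}
        assert labels[(3, 10)] == "positive"

    def test_constant_columns_have_zero_power_and_stay_neutral(self):
        aln = make_alignment(["AU"] * 6)
        res = classify_pairs(aln, CovariationConfig(seed=0, n_null_shuffles=5))
        (r,) = res
        assert r.power == pytest.approx(0.0)
        assert r.label == "neutral"

    def test_independent_high_entropy_columns_are_negative(self):
        spec = PlantSpec(length=12, n_seqs=12, mutation_rate=1.0, seed=3)
        aln, _ = generate(spec)
        res = classify_pairs(aln, CovariationConfig(seed=3))
        labels = [r.label for r in res]
        assert labels.count("negative") > len(labels) / 2
        assert "positive" not in labels

    def test_determinism(self):
        spec = PlantSpec(length=12, n_seqs=10, seed=5)
        aln, _ = generate(spec)
        cfg = CovariationConfig(seed=5, n_null_shuffles=20)
        assert classify_pairs(aln, cfg) == classify_pairs(aln, cfg)

    def test_type_one_error_control(self):
        """On covariation-free alignments the positive rate stays near the
        nominal E-value threshold (within a factor of two)."""
        cfg_t = 0.05
        n_pos = n_pairs = 0
        for seed in range(50):
            spec = PlantSpec(length=10, n_seqs=15, mutation_rate=1.0,
                             seed=1000 + seed)
            aln, _ = generate(spec)
            res = classify_pairs(
                aln, CovariationConfig(seed=seed, n_null_shuffles=50))
            n_pos += sum(r.label == "positive" for r in res)
            n_pairs += len(res)
        assert n_pos / n_pairs <= 2 * cfg_t


class TestExternalPairs:
    def test_coordinates_shift_to_zero_based(self, tmp_path):
        p = tmp_path / "pairs.txt"
        p.write_text("3 14 positive 0.001\n")
        (r,) = load_external_pairs(p, n_cols=20)
        assert r.pair == (2, 13) and r.label == "positive"
        assert r.evalue == pytest.approx(0.001)

    @pytest.mark.parametrize("line,msg", [
        ("5 5 positive", "i < j"),
        ("0 4 positive", "range"),
        ("1 25 positive", "range"),
        ("1 4 maybe", "label"),
        ("1 positive", "expected"),
    ])
    def test_malformed_lines_rejected_with_line_number(self, tmp_path, line, msg):
        p = tmp_path / "pairs.txt"
        p.write_text(line + "\n")
        with pytest.raises(FormatError, match="line 1"):
            load_external_pairs(p, n_cols=20)

    def test_empty_file_is_unconstrained(self, tmp_path):
        p = tmp_path / "pairs.txt"
        p.write_text("")
        assert load_external_pairs(p, n_cols=20) == []


def test_expected_null_count_scales_threshold_by_tests():
    assert expected_null_count(14146, 0.05) == pytest.approx(707.3)
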