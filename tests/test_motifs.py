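import math

import numpy as np
import pytest

from r3dfold.errors import ContractError, FormatError
from r3dfold.motifs import (MotifDescriptor, OFF_CONSENSUS_PROB,
                            build_segment_hmm, compile_motif, expand_all,
                            hmm_forward, parse_descriptor_file,
                            standalone_variant_grammar)
from r3dfold.scfg import seq_to_profile


class TestDescriptors:
    def test_gnra_record(self, tmp_path):
        p = tmp_path / "m.r3d"
        p.write_text("GNRA HL L1=G loop=N R1=RA\n")
        (d,) = parse_descriptor_file(p)
        assert d.mtype == "HL"
        assert d.segments == [("L1", "G"), ("loop", "N"), ("R1", "RA")]

    def test_kturn_style_record_with_empty_segments(self, tmp_path):
        p = tmp_path / "m.r3d"
        p.write_text("Kt IL outL=- loopL=- inL=GA inR=AG loopR=RNN outR=-\n")
        (d,) = parse_descriptor_file(p)
        assert d.segment("loopR") == "RNN"
        assert d.segment("outL") == ""

    def test_wrong_segment_count_rejected(self, tmp_path):
        p = tmp_path / "m.r3d"
        p.write_text("Bad J3 S1=A S2=C S3=G S4=U\n")
        with pytest.raises(FormatError, match="J3"):
            parse_descriptor_file(p)

    def test_unknown_type_rejected(self):
        with pytest.raises(FormatError, match="unknown type"):
            MotifDescriptor("X", "HLX", [("loop", "A")])

    def test_illegal_residue_rejected(self):
        with pytest.raises(FormatError, match="illegal residue"):
            MotifDescriptor("X", "BS", [("seg", "AXG")])


class TestSegmentHMM:
    def test_off_consensus_emission_rule(self):
        h = build_segment_hmm("RNN")
        # position 0 is R = {A, G}: each gets (1 - 2e-4)/2, C/U get 1e-4
        np.testing.assert_allclose(
            h.match_emit[0],
            [(1 - 2 * OFF_CONSENSUS_PROB) / 2, OFF_CONSENSUS_PROB,
             (1 - 2 * OFF_CONSENSUS_PROB) / 2, OFF_CONSENSUS_PROB])
        np.testing.assert_allclose(h.match_emit[1], [0.25] * 4)

    @pytest.mark.parametrize("k,expect", [
        (0, 0.1), (1, 1.1), (4, 4.4), (14, 15.4), (15, 16.5), (20, 21.5),
    ])
    def test_expected_length_rule(self, k, expect):
        h = build_segment_hmm("N" * k)
        assert h.expected_length == pytest.approx(expect, abs=1e-6)

    def test_monte_carlo_length_matches_analytic(self):
        h = build_segment_hmm("RNN")
        rng = np.random.default_rng(0)
        n = 20000
        lengths = np.array([len(h.sample(rng)) for _ in range(n)])
        se = lengths.std(ddof=1) / math.sqrt(n)
        assert abs(lengths.mean() - h.expected_length) < 3 * se

    def test_forward_single_match_hand_computation(self):
        h = build_segment_hmm("G", delta=0.0)
        aln = seq_to_profile("G")
        got = hmm_forward(h, aln, 0, 0)
        # no insert at either junction, one undeleted match emitting G
        expect = (2 * math.log(1 - h.alpha)
                  + math.log(h.match_emit[0][2]))
        assert got == pytest.approx(expect, abs=1e-9)

    def test_empty_consensus_on_empty_span_closed_form(self):
        h = build_segment_hmm("")
        got = hmm_forward(h, seq_to_profile("A"), 0, -1)
        assert got == pytest.approx(math.log(1 - h.alpha), abs=1e-12)

    def test_span_shorter_than_consensus_unreachable_without_deletions(self):
        h = build_segment_hmm("ACG", delta=0.0)
        assert hmm_forward(h, seq_to_profile("AC"), 0, 1) == -math.inf

    def test_deletions_make_short_spans_reachable(self):
        h = build_segment_hmm("ACG", delta=0.01)
        assert hmm_forward(h, seq_to_profile("AC"), 0, 1) > -math.inf

    def test_consensus_outscores_single_substitutions(self):
        h = build_segment_hmm("GAUC")
        cons_score = hmm_forward(h, seq_to_profile("GAUC"), 0, 3)
        for pos in range(4):
            for sub in "ACGU":
                if sub == "GAUC"[pos]:
                    continue
                mutated = "GAUC"[:pos] + sub + "GAUC"[pos + 1:]
                assert hmm_forward(h, seq_to_profile(mutated), 0, 3) < cons_score

    def test_invalid_span_rejected(self):
        h = build_segment_hmm("A")
        with pytest.raises(ContractError):
            hmm_forward(h, seq_to_profile("ACG"), 2, 5)


class TestCompile:
    @pytest.mark.parametrize("mtype,roles,n", [
        ("HL", "L1=G loop=N R1=RA", 1),
        ("BL", "L=- loop=A R=-", 2),
        ("IL", "outL=- loopL=- inL=GA inR=AG loopR=RNN outR=-", 2),
        ("J3", "S1=A S2=C S3=G", 3),
        ("J4", "S1=A S2=C S3=G S4=U", 4),
        ("BS", "seg=AGGA", 1),
    ])
    def test_variant_multiplicities(self, tmp_path, mtype, roles, n):
        p = tmp_path / "m.r3d"
        p.write_text(f"X {mtype} {roles}\n")
        (d,) = parse_descriptor_file(p)
        assert len(compile_motif(d).variants) == n

    def test_every_variant_grammar_validates(self, default_descriptors):
        for d in default_descriptors[:12]:
            m = compile_motif(d)
            for v in range(len(m.variants)):
                assert standalone_variant_grammar(m, v).validate().ok

    def test_expand_all_counts(self, tmp_path):
        p = tmp_path / "m.r3d"
        p.write_text("A IL outL=- loopL=- inL=GA inR=AG loopR=RNN outR=-\n"
                     "B HL L1=G loop=N R1=RA\n")
        models, total = expand_all(parse_descriptor_file(p))
        assert total == 3

    def test_expand_all_empty(self):
        assert expand_all([]) == ([], 0)

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "m.r3d"
        p.write_text("A BS seg=AG\nA BS seg=CU\n")
        with pytest.raises(FormatError, match="duplicate"):
            expand_all(parse_descriptor_file(p))


def test_shipped_library_compiles_to_96_variant_models(default_descriptors):
    models, total = expand_all(default_descriptors)
    assert len(default_descriptors) == 51
    assert total == 96
    assert sum(1 for d in default_descriptors if d.mtype == "HL") == 15
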