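import math

import numpy as np
import pytest

from r3dfold.errors import ContractError, NoStructureError
from r3dfold.scfg import (Constraints, Grammar, cyk, enumerate_parses, inside,
                          score_tree, seq_to_profile, tree_pairs)

from conftest import random_sequence, toy_nested_grammar


class TestValidate:
    def test_normalized_grammar_passes(self):
        g = Grammar("g", "S")
        g.add_dist("u", [0.25] * 4)
        g.add_nonterminal("S")
        g.add_rule("S", (("emit", "u"),), 0.5)
        g.add_rule("S", (), 0.5)
        assert g.validate().ok

    def test_normalization_deficit_flagged(self):
        g = Grammar("g", "S")
        g.add_dist("u", [0.25] * 4)
        g.add_nonterminal("S")
        g.add_rule("S", (("emit", "u"),), 0.5)
        g.add_rule("S", (), 0.4)
        rep = g.validate()
        assert not rep.ok
        assert rep.deficits["S"] == pytest.approx(0.1)

    def test_undefined_reference_flagged(self):
        g = Grammar("g", "S")
        g.add_nonterminal("S")
        g.add_rule("S", (("nt", "GHOST"),), 1.0)
        rep = g.validate()
        assert not rep.ok
        assert any("GHOST" in m for m in rep.missing_refs)

    def test_unreachable_and_unproductive_flagged(self):
        g = Grammar("g", "S")
        g.add_nonterminal("S")
        g.add_nonterminal("DEAD")
        g.add_rule("S", (), 1.0)
        g.add_rule("DEAD", (("nt", "DEAD"),), 1.0)
        rep = g.validate()
        assert "DEAD" in rep.unreachable and "DEAD" in rep.unproductive


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_cyk_and_inside_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        g = toy_nested_grammar(seed)
        seq = random_sequence(rng, int(rng.integers(0, 9)))
        parses = enumerate_parses(g, seq)
        lps = sorted(lp for _, lp in parses)
        aln = seq_to_profile(seq)
        got_max, _ = cyk(g, aln)
        assert got_max == pytest.approx(max(lps), abs=1e-9)
        assert inside(g, aln) == pytest.approx(
            np.logaddexp.reduce(lps), abs=1e-9)

    def test_inside_never_below_cyk(self):
        g = toy_nested_grammar(3)
        for seed in range(5):
            seq = random_sequence(np.random.default_rng(seed), 7)
            aln = seq_to_profile(seq)
            assert inside(g, aln) >= cyk(g, aln)[0] - 1e-12

    def test_score_tree_reproduces_cyk_score(self):
        g = toy_nested_grammar(1)
        aln = seq_to_profile("GGACUCC")
        lp, tree = cyk(g, aln)
        assert score_tree(g, aln, tree) == pytest.approx(lp, abs=1e-9)


class TestEdgeCases:
    def test_empty_sequence_scores_epsilon_rule(self):
        g = toy_nested_grammar(0)
        lp, _ = cyk(g, seq_to_profile(""))
        assert lp == pytest.approx(g.rules["S"][1].logp)

    def test_ambiguous_toy_inside_sums_derivations(self):
        # two derivations of the empty string with probs 0.2 and 0.3
        g2 = Grammar("amb2", "S")
        g2.add_nonterminal("S")
        g2.add_nonterminal("A")
        g2.add_rule("S", (), 0.2)
        g2.add_rule("S", (("nt", "A"),), 0.8)
        g2.add_rule("A", (), 0.375)
        g2.add_rule("A", (("emit", "u"),), 0.625)
        g2.add_dist("u", [0.25] * 4)
        assert inside(g2, seq_to_profile("")) == pytest.approx(math.log(0.5))

    def test_enumeration_guard(self):
        g = toy_nested_grammar(0)
        with pytest.raises(ContractError, match="limited"):
            enumerate_parses(g, "A" * 13)

    def test_single_rule_chain_has_one_parse(self):
        g = Grammar("lin", "S")
        g.add_dist("u", [0.7, 0.1, 0.1, 0.1])
        g.add_nonterminal("S")
        g.add_rule("S", (("emit", "u"), ("nt", "S")), 0.5)
        g.add_rule("S", (), 0.5)
        assert len(enumerate_parses(g, "AA")) == 1


class TestConstraints:
    def test_forced_pairs_realized_and_forbidden_absent(self):
        g = toy_nested_grammar(2)
        aln = seq_to_profile("GGGAAACCC")
        cons = Constraints(forced_pairs={(0, 8), (1, 7)},
                           forbidden_pairs={(2, 6)})
        _, tree = cyk(g, aln, cons)
        pairs = tree_pairs(tree)
        assert {(0, 8), (1, 7)} <= pairs
        assert (2, 6) not in pairs

    def test_whitelist_restricts_pairing(self):
        g = toy_nested_grammar(2)
        aln = seq_to_profile("GGGAAACCC")
        cons = Constraints(forced_pairs={(0, 8)}, allowed_pairs={(0, 8)})
        _, tree = cyk(g, aln, cons)
        assert tree_pairs(tree) == {(0, 8)}

    def test_unsatisfiable_constraints_raise(self):
        # the toy grammar cannot leave zero columns inside a forced pair
        # while also pairing (0, 1): adjacent pair with empty interior
        g = Grammar("strict", "S")
        g.add_dist("u", [0.25] * 4)
        g.add_pair_table("w", [1 / 16] * 16)
        g.add_nonterminal("S")
        g.add_nonterminal("G")
        g.add_rule("S", (("nt", "G"),), 1.0, pair="w")
        g.add_rule("G", (("emit", "u"),), 1.0)
        with pytest.raises(NoStructureError):
            cyk(g, seq_to_profile("AU"), Constraints(forced_pairs={(0, 1)}))

    def test_crossing_forced_pairs_rejected(self):
        with pytest.raises(ContractError, match="cross"):
            Constraints(forced_pairs={(0, 5), (2, 8)})

    def test_overlapping_forced_forbidden_rejected(self):
        with pytest.raises(ContractError, match="overlap"):
            Constraints(forced_pairs={(0, 5)}, forbidden_pairs={(0, 5)})


class TestSerialization:
    def test_text_round_trip_is_bit_identical(self):
        g = toy_nested_grammar(9)
        text = g.to_text()
        assert Grammar.from_text(text).to_text() == text

    def test_round_trip_preserves_parse_scores(self):
        g = toy_nested_grammar(4)
        g2 = Grammar.from_text(g.to_text())
        aln = seq_to_profile("GCAUGC")
        assert cyk(g2, aln)[0] == pytest.approx(cyk(g, aln)[0])
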