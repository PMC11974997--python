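import numpy as np
import pytest

from r3dfold.grammars import (MotifPriorConfig, TrainedParams,
                              allocate_motif_prior, build_g6x, build_rbgj3j4,
                              generic_loop_prob, integrate_r3d,
                              train_by_counting, LOOP_CLASSES)
from r3dfold.motifs import expand_all
from r3dfold.msa_io import ProfileAlignment, compute_profiles, parse_wuss
from r3dfold.scfg import (Constraints, Grammar, cyk, enumerate_parses,
                          seq_to_profile, tree_annotation, tree_pairs)


class TestBaseGrammar:
    def test_twelve_nonterminals(self, base_grammar):
        assert len(base_grammar.nonterminals) == 12

    def test_validates(self, base_grammar):
        assert base_grammar.validate().ok

    def test_generic_hairpin_probability_pinned(self, base_grammar):
        assert generic_loop_prob(base_grammar, "HL") == pytest.approx(0.3475)

    def test_hairpin_toy_fold_matches_enumeration(self, base_grammar):
        """A short stem-loop sequence folds into a single hairpin, and the
        CYK score equals the exhaustive-enumeration maximum."""
        aln = seq_to_profile("GGCAAAGCC")
        lp, tree = cyk(base_grammar, aln)
        parses = enumerate_parses(base_grammar, aln.seqs[0])
        assert lp == pytest.approx(max(p for _, p in parses), abs=1e-9)
        pairs = tree_pairs(tree)
        assert pairs, "stem-loop expected"
        # single helix: pairs form one stacked run
        (outer_i, outer_j) = min(pairs)
        assert all((outer_i + t, outer_j - t) in pairs
                   for t in range(len(pairs)))

    def test_text_round_trip_bit_identical(self, base_grammar):
        text = base_grammar.to_text()
        assert Grammar.from_text(text).to_text() == text


class TestPriorAllocation:
    def test_training_arithmetic(self):
        generic, mass, per_motif = allocate_motif_prior(0.3475, 0.4, 15)
        assert round(generic, 4) == 0.2085
        assert round(mass, 4) == 0.1390
        assert round(per_motif, 4) == 0.0093

    def test_zero_fraction_leaves_grammar_unchanged(self, base_grammar,
                                                    default_models):
        models, _ = default_models
        cfg = MotifPriorConfig(class_fractions={c: 0.0 for c in LOOP_CLASSES})
        g = integrate_r3d(base_grammar, models, cfg)
        for c in LOOP_CLASSES:
            assert generic_loop_prob(g, c) == pytest.approx(
                generic_loop_prob(base_grammar, c))
        assert not g.find_tagged("HL_motif")

    def test_full_library_gives_108_nonterminals(self, base_grammar,
                                                 default_models):
        models, total = default_models
        g = integrate_r3d(base_grammar, models)
        assert len(g.nonterminals) == 12 + total == 108
        assert g.validate().ok

    def test_probability_conserved_per_loop_class(self, base_grammar,
                                                  default_models):
        models, _ = default_models
        g = integrate_r3d(base_grammar, models)
        for c in LOOP_CLASSES:
            before = generic_loop_prob(base_grammar, c)
            after = generic_loop_prob(g, c) + sum(
                g.rule_prob(nt, k) for nt, k in g.find_tagged(f"{c}_motif"))
            assert after == pytest.approx(before, abs=1e-9)

    def test_missing_class_returns_mass_to_generic(self, base_grammar,
                                                   two_motif_descriptors):
        models, _ = expand_all(two_motif_descriptors)
        with pytest.warns(UserWarning, match="no motifs"):
            g = integrate_r3d(base_grammar, models)
        assert generic_loop_prob(g, "J3") == pytest.approx(
            generic_loop_prob(base_grammar, "J3"))


class TestG6X:
    def test_validates(self, layer_grammar):
        assert layer_grammar.validate().ok

    def test_forced_pair_realized(self, layer_grammar):
        aln = seq_to_profile("GAAAC")
        cons = Constraints(forced_pairs={(0, 4)}, allowed_pairs={(0, 4)})
        _, tree = cyk(layer_grammar, aln, cons)
        assert (0, 4) in tree_pairs(tree)

    def test_three_pair_helix_recovered_under_eligibility(self, layer_grammar):
        """With a helix's pairs whitelisted and forced, the layer parse
        returns exactly that helix."""
        aln = seq_to_profile("GGGAAACCC")
        helix = {(0, 8), (1, 7), (2, 6)}
        cons = Constraints(forced_pairs=set(helix), allowed_pairs=set(helix))
        _, tree = cyk(layer_grammar, aln, cons)
        assert tree_pairs(tree) == helix


class TestUnambiguity:
    def test_sampled_derivations_unique_base(self, base_grammar):
        rng = np.random.default_rng(42)
        tested = 0
        while tested < 10:
            seq, tree = base_grammar.sample(rng, max_len=9)
            if not seq:
                continue
            ann = tree_annotation(tree)
            matches = [1 for nd, _ in enumerate_parses(base_grammar, seq, 9)
                       if tree_annotation(nd) == ann]
            assert len(matches) == 1
            tested += 1

    def test_sampled_derivations_unique_with_motifs(self, base_grammar,
                                                    two_motif_descriptors):
        models, _ = expand_all(two_motif_descriptors)
        g = integrate_r3d(base_grammar, models)
        rng = np.random.default_rng(7)
        tested = 0
        while tested < 6:
            seq, tree = g.sample(rng, max_len=8)
            if not seq:
                continue
            ann = tree_annotation(tree)
            matches = [1 for nd, _ in enumerate_parses(g, seq, 8)
                       if tree_annotation(nd) == ann]
            assert len(matches) == 1
            tested += 1


class TestTraining:
    def _hairpin_alignment(self):
        aln = compute_profiles(
            ProfileAlignment(["x"], ["GGGACGUCCC"]), "none")
        return aln, parse_wuss("<<<....>>>")

    def test_loop_length_rules_concentrate(self):
        aln, cons = self._hairpin_alignment()
        params = train_by_counting([(aln, cons)] * 3)
        g = Grammar.from_text(params.rbg_text)
        # three loops of length 4: 9 extend + 3 end usages, Laplace +1
        assert g.rules["G"][0].prob == pytest.approx(10 / 14)
        assert g.rules["G"][1].prob == pytest.approx(4 / 14)

    def test_empty_corpus_gives_uniform_rules(self):
        params = train_by_counting([])
        g = Grammar.from_text(params.rbg_text)
        for nt in g.nonterminals:
            probs = [r.prob for r in g.rules[nt]]
            np.testing.assert_allclose(probs, 1.0 / len(probs))

    def test_single_structure_counts_equal_unique_derivation(self):
        aln, cons = self._hairpin_alignment()
        params = train_by_counting([(aln, cons)])
        g = Grammar.from_text(params.rbg_text)
        # derivation uses S->F0 S once and S->eps once: (1+1)/(2+3), etc.
        assert g.rules["S"][1].prob == pytest.approx(2 / 5)
        assert g.rules["S"][2].prob == pytest.approx(2 / 5)
        assert g.rules["S"][0].prob == pytest.approx(1 / 5)

    def test_undeliverable_structure_skipped_with_warning(self):
        aln = compute_profiles(ProfileAlignment(["x"], ["AU"]), "none")
        cons = parse_wuss("<>")  # adjacent pair: hairpin loop would be empty
        with pytest.warns(UserWarning, match="skipped"):
            params = train_by_counting([(aln, cons)])
        g = Grammar.from_text(params.rbg_text)
        probs = [r.prob for r in g.rules["G"]]
        np.testing.assert_allclose(probs, 0.5)
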