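import numpy as np
import pytest

from r3dfold.grammars import (build_g6x, build_rbgj3j4,
                              load_default_descriptors)
from r3dfold.motifs import expand_all
from r3dfold.msa_io import ProfileAlignment, compute_profiles
from r3dfold.scfg import Grammar
from r3dfold.synthetic import prototype_descriptors


@pytest.fixture(scope="session")
def default_descriptors():
    return load_default_descriptors()


@pytest.fixture(scope="session")
def two_motif_descriptors(default_descriptors):
    return prototype_descriptors(default_descriptors)


@pytest.fixture(scope="session")
def base_grammar():
    return build_rbgj3j4()


@pytest.fixture(scope="session")
def layer_grammar():
    return build_g6x()


@pytest.fixture(scope="session")
def default_models(default_descriptors):
    models, total = expand_all(default_descriptors)
    return models, total


def make_alignment(seqs, weighting="none"):
    names = [f"s{i}" for i in range(len(seqs))]
    return compute_profiles(ProfileAlignment(names, list(seqs)), weighting)


def toy_nested_grammar(seed=None):
    """A small randomized nested-pair grammar for oracle comparisons."""
    rng = np.random.default_rng(seed)

    def rand_probs(n):
        p = rng.dirichlet(np.ones(n) * 2.0)
        return p

    g = Grammar(f"toy{seed}", start="S")
    d = rng.dirichlet(np.ones(4) * 3.0)
    g.add_dist("u", d)
    g.add_pair_table("w", rng.dirichlet(np.ones(16) * 2.0))
    for nt in ("S", "L", "F"):
        g.add_nonterminal(nt)
    p = rand_probs(2)
    g.add_rule("S", (("nt", "L"), ("nt", "S")), p[0])
    g.add_rule("S", (), p[1])
    p = rand_probs(2)
    g.add_rule("L", (("nt", "F"),), p[0], pair="w")
    g.add_rule("L", (("emit", "u"),), p[1])
    p = rand_probs(3)
    g.add_rule("F", (("nt", "F"),), p[0], pair="w")
    g.add_rule("F", (("nt", "L"), ("nt", "L"), ("nt", "S")), p[1])
    g.add_rule("F", (("emit", "u"),), p[2])
    return g


def random_sequence(rng, length):
    return "".join(rng.choice(list("ACGU")) for _ in range(length))
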