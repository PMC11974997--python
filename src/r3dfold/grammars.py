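"""The base folding grammars and their integration with motif models.

Three grammars live here:

* the 12-nonterminal base grammar (helix stacking, hairpins, bulges,
  internal loops, explicit 3-way and 4-way junctions, generic >= 5-way
  multiloops via branch recursion);
* the small pseudoknot-layer grammar (a G6-family nested-pair grammar
  with a distinct unpaired-emission nonterminal), used for layers >= 1;
* the motif-extended grammar obtained by splicing compiled motif variant
  models into the base grammar's loop productions, with loop-class
  probability mass reallocated between the generic loop and the motifs.

Loop-class prior allocation: a loop class with generic probability ``p``
and curated class fraction ``f`` keeps ``p (1 - f)`` on the generic rule;
the remaining ``p f`` is split equally over the class's motifs (maximum
entropy across motifs), and each motif's share equally over its variants.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, NoStructureError
from .motifs import MotifModel, parse_descriptor_file
from .msa_io import ConsensusStructure, ProfileAlignment
from .scfg import Constraints, Grammar, cyk

N_BASE_NONTERMINALS = 12

#: loop classes in canonical order
LOOP_CLASSES = ("HL", "BL", "IL", "J3", "J4", "BS")


@dataclass
class MotifPriorConfig:
    """Curated fraction of each loop class's probability given to motifs."""

    class_fractions: dict = field(default_factory=lambda: {
        "HL": 0.4, "BL": 0.4, "IL": 0.5, "J3": 0.2, "J4": 0.2, "BS": 0.2,
    })

    def __post_init__(self):
        for c, f in self.class_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ContractError(f"fraction for {c} must be in [0,1]")


@dataclass
class TrainedParams:
    """Serialized rule probabilities and emission tables for both grammars."""

    rbg_text: str
    g6x_text: str

    @classmethod
    def default(cls) -> "TrainedParams":
        pkg = importlib.resources.files("r3dfold.data")
        return cls(
            rbg_text=(pkg / "rbgj3j4.params").read_text(),
            g6x_text=(pkg / "g6x.params").read_text(),
        )

    def save(self, rbg_path, g6x_path):
        with open(rbg_path, "w") as fh:
            fh.write(self.rbg_text)
        with open(g6x_path, "w") as fh:
            fh.write(self.g6x_text)


def default_trained_params() -> TrainedParams:
    return TrainedParams.default()


def default_descriptor_path():
    return importlib.resources.files("r3dfold.data") / "motifs.r3d"


def load_default_descriptors():
    with importlib.resources.as_file(default_descriptor_path()) as p:
        return parse_descriptor_file(p)


def build_rbgj3j4(params: TrainedParams | None = None) -> Grammar:
    """Build the base folding grammar from (default or trained) parameters."""
    params = params or TrainedParams.default()
    g = Grammar.from_text(params.rbg_text)
    if len(g.nonterminals) != N_BASE_NONTERMINALS:
        raise AssertionError(
            f"base grammar must have {N_BASE_NONTERMINALS} nonterminals, "
            f"got {len(g.nonterminals)}")
    rep = g.validate()
    if not rep.ok:
        raise ContractError(f"base grammar invalid: {rep}")
    return g


def build_g6x(params: TrainedParams | None = None) -> Grammar:
    """Build the pseudoknot-layer grammar."""
    params = params or TrainedParams.default()
    g = Grammar.from_text(params.g6x_text)
    rep = g.validate()
    if not rep.ok:
        raise ContractError(f"layer grammar invalid: {rep}")
    return g


def generic_loop_prob(g: Grammar, loop_class: str) -> float:
    """Summed probability of a loop class's generic productions."""
    rules = g.find_tagged(f"{loop_class}_generic")
    if not rules:
        raise ContractError(f"no generic rule tagged for class {loop_class}")
    return sum(g.rule_prob(nt, k) for nt, k in rules)


def allocate_motif_prior(generic_prob: float, fraction: float,
                         n_motifs: int) -> tuple[float, float, float]:
    """Split a generic-loop probability between the generic rule and motifs.

    Returns (probability left on the generic production, total class mass
    given to motifs, probability per individual motif).
    """
    class_mass = generic_prob * fraction
    generic_left = generic_prob - class_mass
    per_motif = class_mass / n_motifs if n_motifs else 0.0
    return generic_left, class_mass, per_motif


def integrate_r3d(base: Grammar, motifs: list[MotifModel],
                  cfg: MotifPriorConfig | None = None) -> Grammar:
    """Splice motif variant models into the base grammar.

    Per loop class, the generic production keeps ``p (1 - f)`` of its
    probability; each motif variant is added as an alternative production
    at its host nonterminal so that class probability is conserved
    exactly.  The resulting grammar has ``12 + total variants``
    nonterminals and validates.
    """
    cfg = cfg or MotifPriorConfig()
    g = base.copy()
    by_class: dict[str, list[MotifModel]] = {c: [] for c in LOOP_CLASSES}
    for m in motifs:
        by_class[m.descriptor.mtype].append(m)
    for c in LOOP_CLASSES:
        f = cfg.class_fractions.get(c, 0.0)
        models = by_class[c]
        if f <= 0.0:
            continue
        if not models:
            warnings.warn(f"loop class {c} has fraction {f} but no motifs; "
                          f"mass returned to the generic rule")
            continue
        generics = g.find_tagged(f"{c}_generic")
        p_c = sum(g.rule_prob(nt, k) for nt, k in generics)
        _, _, per_motif = allocate_motif_prior(p_c, f, len(models))
        for nt, k in generics:
            g.scale_rule(nt, k, 1.0 - f)
        for m in models:
            per_variant = per_motif / len(m.variants)
            for name, hmm in m.segment_hmms.items():
                g.add_segment(name, hmm)
            for var in m.variants:
                g.add_nonterminal(var.nt)
                g.add_rule(var.nt, var.rhs, 1.0)
                g.add_rule(var.host, var.production, per_variant,
                           tag=f"{c}_motif")
    rep = g.validate()
    if not rep.ok:
        raise ContractError(f"motif-integrated grammar invalid: {rep}")
    g.name = base.name + "-R3D"
    return g


# ---------------------------------------------------------------------------
# counting trainer


def train_by_counting(annotated: list[tuple[ProfileAlignment, ConsensusStructure]],
                      params: TrainedParams | None = None) -> TrainedParams:
    """Maximum-likelihood rule probabilities from annotated alignments.

    Each alignment's nested consensus structure (layer 0) is parsed under
    the base grammar with its pairs forced and everything else forbidden;
    the grammar being unambiguous, the derivation is unique, and rule /
    emission usage counts with Laplace pseudocount 1 give the new
    probabilities.  Alignments whose structure the grammar cannot derive
    are skipped with a warning.
    """
    params = params or TrainedParams.default()
    g = build_rbgj3j4(params)
    rule_counts = {nt: np.zeros(len(g.rules[nt])) for nt in g.nonterminals}
    dist_counts = {name: np.zeros(4) for name in g.dists}
    pair_counts = {name: np.zeros((4, 4)) for name in g.pair_tables}
    n_used = 0
    for aln, cons in annotated:
        pairs = set(cons.pairs_by_layer[0]) if cons.pairs_by_layer else set()
        constraints = Constraints(forced_pairs=pairs, allowed_pairs=set(pairs))
        try:
            _, tree = cyk(g, aln, constraints)
        except NoStructureError:
            warnings.warn("structure not derivable by the base grammar; "
                          "alignment skipped")
            continue
        n_used += 1
        freq = aln.renormalized_freq()
        for node in tree.walk():
            rule = g.rules[node.nt][node.rule_index]
            rule_counts[node.nt][node.rule_index] += 1
            if rule.pair is not None and node.pair is not None:
                i, j = node.pair
                pair_counts[rule.pair] += np.outer(freq[i], freq[j])
            emit_dists = [a[1] for a in rule.atoms if a[0] == "emit"]
            if emit_dists:
                # every base-grammar rule uses a single emission distribution
                dname = emit_dists[0]
                for c in node.emits:
                    dist_counts[dname] += freq[c]
    out = Grammar(g.name, g.start)
    for name, counts in dist_counts.items():
        c = counts + 1.0
        out.add_dist(name, c / c.sum())
    for name, counts in pair_counts.items():
        c = counts + 1.0
        out.add_pair_table(name, c / c.sum())
    for nt in g.nonterminals:
        out.add_nonterminal(nt)
        c = rule_counts[nt] + 1.0
        probs = c / c.sum()
        for k, r in enumerate(g.rules[nt]):
            out.add_rule(nt, r.atoms, float(probs[k]), pair=r.pair, tag=r.tag)
    return TrainedParams(rbg_text=out.to_text(), g6x_text=params.g6x_text)
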