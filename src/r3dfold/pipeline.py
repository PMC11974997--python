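"""End-to-end folding: covariation -> layers -> constrained parses -> result.

The flow mirrors the layered covariation-framed design: significantly
covarying column pairs are split into layers of mutually nested pairs;
layer 0 is folded with the motif-extended base grammar (its positives
forced, negatives and cross-layer positives forbidden), producing both
the nested secondary structure and the motif placements; every further
layer is folded with the small pseudoknot-layer grammar, where only that
layer's positives and their immediate stacking neighbors may pair.

A motif has *covariation support* when at least one of the helices
bounding its hosting loop contains a covarying (positive) pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import covariation as cov
from .grammars import (MotifPriorConfig, TrainedParams, build_g6x,
                       build_rbgj3j4, integrate_r3d, load_default_descriptors)
from .layering import decompose_layers
from .motifs import MotifDescriptor, expand_all
from .msa_io import ConsensusStructure, ProfileAlignment, compute_profiles
from .scfg import Constraints, cyk, score_tree, tree_pairs


@dataclass
class MotifPlacement:
    motif: str
    variant: int
    span: tuple                 # half-open columns of the whole placement
    segments: list              # (role, start, end) half-open column spans
    logprob: float
    support: bool = False
    bounding_helices: list = field(default_factory=list)  # lists of pairs


@dataclass
class PipelineConfig:
    covariation: cov.CovariationConfig = field(default_factory=cov.CovariationConfig)
    weighting: str = "henikoff"
    no_covariation: bool = False
    external_pairs: object = None      # path to a pair-list file, if any
    pair_results: list = None          # precomputed CovariationResult list
    prior: MotifPriorConfig = field(default_factory=MotifPriorConfig)
    params: TrainedParams = None

    def __post_init__(self):
        if self.params is None:
            self.params = TrainedParams.default()


@dataclass
class FoldResult:
    structure: ConsensusStructure
    motif_placements: list
    positives_by_layer: list
    covariation_results: list
    logprob: float
    metadata: dict = field(default_factory=dict)

    def motif_table(self):
        """Motif report as a DataFrame (1-based, closed column coordinates)."""
        import pandas as pd

        rows = []
        for pl in self.motif_placements:
            segtxt = ";".join(
                f"{role}:{a + 1}-{b}" if b > a else f"{role}:-"
                for role, a, b in pl.segments)
            rows.append({
                "motif": pl.motif,
                "variant": pl.variant,
                "first_col": pl.span[0] + 1,
                "last_col": pl.span[1],
                "segments": segtxt,
                "logprob": round(pl.logprob, 4),
                "covariation_support": pl.support,
            })
        return pd.DataFrame(rows, columns=[
            "motif", "variant", "first_col", "last_col", "segments",
            "logprob", "covariation_support"])

    def metadata_json(self) -> str:
        return json.dumps(self.metadata, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# helices and loops of a nested structure


def helices_of(pairs: set) -> list:
    """Maximal stacked runs of pairs; each helix is a list of pairs."""
    pairs = sorted(pairs)
    pairset = set(pairs)
    seen = set()
    helices = []
    for p in pairs:
        if p in seen:
            continue
        i, j = p
        if (i - 1, j + 1) in pairset:
            continue  # not the outermost pair of its helix
        helix = []
        while (i, j) in pairset:
            helix.append((i, j))
            seen.add((i, j))
            i, j = i + 1, j - 1
        helices.append(helix)
    return helices


def _loop_children(pairs: set):
    """Map each helix-closing pair (and the root) to its child helices."""
    helices = helices_of(pairs)
    outer = {h[0]: h for h in helices}       # outermost pair -> helix
    closing = {h[-1]: h for h in helices}    # innermost pair -> helix
    # sort helices by outer pair; nest via a stack
    children: dict = {None: []}
    for cp in closing:
        children[cp] = []
    stack = []
    for (i, j) in sorted(outer):
        while stack and i > stack[-1][1]:
            stack.pop()
        parent = stack[-1] if stack else None
        # parent is the *closing* pair of the enclosing helix
        children[parent].append(outer[(i, j)])
        h = outer[(i, j)]
        stack.append(h[-1])
    return children, closing


def bounding_helices_for_span(pairs: set, span: tuple) -> list:
    """Helices bounding the loop that hosts the given column span.

    The hosting loop is the one closed by the smallest pair enclosing the
    span; its bounding helices are that closing helix plus every child
    helix of the loop (the external loop has no closing helix).
    """
    children, closing = _loop_children(pairs)
    a, b = span
    host = None
    for (i, j) in sorted(closing, key=lambda p: p[1] - p[0]):
        if i < a and b <= j:
            host = (i, j)
            break
    out = []
    if host is not None:
        out.append(closing[host])
    # every child helix of the hosting loop bounds it (for an internal-loop
    # motif this includes the held inner helix; for a branch-segment motif,
    # all helices of the multiloop)
    out.extend(children.get(host, []))
    return out


def motif_support(result: FoldResult, positives: set) -> FoldResult:
    """Recompute covariation-support flags for all motif placements."""
    layer0 = result.structure.pairs_by_layer[0] if result.structure.pairs_by_layer else set()
    for pl in result.motif_placements:
        helices = bounding_helices_for_span(layer0, pl.span)
        pl.bounding_helices = helices
        pl.support = any(p in positives for h in helices for p in h)
    return result


# ---------------------------------------------------------------------------
# main pipeline


def _extract_placements(tree, variant_index: dict, grammar, aln) -> list:
    out = []
    for node in tree.walk():
        if node.nt in variant_index:
            motif, vidx = variant_index[node.nt]
            segs = []
            for (name, a, b) in node.segs:
                role = name.split("~", 1)[1]
                segs.append((role, a, b))
            out.append(MotifPlacement(
                motif=motif, variant=vidx, span=node.span,
                segments=segs, logprob=score_tree(grammar, aln, node)))
    return sorted(out, key=lambda p: (p.span, p.motif))


def _stacking_neighbors(pairs: set, L: int) -> set:
    out = set()
    for (i, j) in pairs:
        for (a, b) in ((i - 1, j + 1), (i + 1, j - 1)):
            if 0 <= a < b < L:
                out.add((a, b))
    return out


def fold_alignment(aln: ProfileAlignment,
                   descriptors: list[MotifDescriptor] | None = None,
                   config: PipelineConfig | None = None) -> FoldResult:
    """Joint prediction of nested helices, pseudoknot layers and 3D motifs.

    Runs covariation classification (unless disabled or supplied
    externally), decomposes positives into layers, folds layer 0 with the
    motif-extended grammar and the remaining layers with the pseudoknot
    grammar, and assembles the consensus structure with covariation-support
    flags per motif.
    """
    config = config or PipelineConfig()
    if descriptors is None:
        descriptors = load_default_descriptors()
    aln = compute_profiles(aln, weighting=config.weighting)
    L = aln.n_cols

    # 1) constraint set
    cov_results: list = []
    positives: set = set()
    negatives: set = set()
    if config.no_covariation:
        cov_results = []
    elif config.pair_results is not None:
        cov_results = list(config.pair_results)
    elif config.external_pairs is not None:
        cov_results = cov.load_external_pairs(config.external_pairs, L)
    elif aln.n_seqs >= 2 and L > 0:
        cov_results = cov.classify_pairs(aln, config.covariation)
    for r in cov_results:
        if r.label == "positive":
            positives.add(r.pair)
        elif r.label == "negative":
            negatives.add(r.pair)

    # 2) layer decomposition
    decomp = decompose_layers(positives)
    layers = decomp.layers if decomp.layers else [set()]

    # 3) layer 0: motif-extended base grammar
    models, _ = expand_all(descriptors)
    base = build_rbgj3j4(config.params)
    grammar = integrate_r3d(base, models, config.prior)
    variant_index = {
        var.nt: (m.name, vi)
        for m in models for vi, var in enumerate(m.variants)
    }
    if L == 0:
        structure = ConsensusStructure(pairs_by_layer=[set()], n_cols=0)
        return FoldResult(structure, [], [set()], cov_results, 0.0,
                          metadata=_metadata(config, aln))
    cross_layer = set().union(*layers[1:]) if len(layers) > 1 else set()
    cons0 = Constraints(
        forced_pairs=set(layers[0]),
        forbidden_pairs=(negatives | cross_layer) - set(layers[0]),
    )
    logprob, tree = cyk(grammar, aln, cons0)
    layer0_pairs = tree_pairs(tree)
    placements = _extract_placements(tree, variant_index, grammar, aln)

    # 4) layers >= 1: pseudoknot-layer grammar
    g6x = build_g6x(config.params)
    pairs_by_layer = [layer0_pairs]
    for layer in layers[1:]:
        allowed = set(layer) | _stacking_neighbors(layer, L)
        consL = Constraints(forced_pairs=set(layer), allowed_pairs=allowed)
        _, ltree = cyk(g6x, aln, consL)
        pairs_by_layer.append(tree_pairs(ltree))

    # 5) assemble
    structure = ConsensusStructure(pairs_by_layer=pairs_by_layer, n_cols=L)
    result = FoldResult(
        structure=structure,
        motif_placements=placements,
        positives_by_layer=[set(l) for l in layers],
        covariation_results=cov_results,
        logprob=logprob,
        metadata=_metadata(config, aln),
    )
    motif_support(result, positives)
    return result


def _metadata(config: PipelineConfig, aln: ProfileAlignment) -> dict:
    return {
        "n_seqs": aln.n_seqs,
        "n_cols": aln.n_cols,
        "weighting": config.weighting,
        "no_covariation": config.no_covariation,
        "evalue_threshold": config.covariation.evalue_threshold,
        "n_null_shuffles": config.covariation.n_null_shuffles,
        "seed": config.covariation.seed,
    }
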