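"""Seedable generators for alignments with planted helices and motifs.

Sequences are drawn from a common ancestor on a star phylogeny.  Planted
helix columns co-mutate: with probability ``covariation_rate`` a sequence
resamples a Watson-Crick-compatible pair at that position (a compensatory
double substitution), which is the simplest mechanism producing the
covariation signal a significance test can detect.  Planted motif columns
follow the motif's consensus with a reduced mutation rate.  The
column-shuffle control permutes each column's residues independently
across sequences, destroying covariation while preserving per-column base
composition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .motifs import MotifDescriptor
from .msa_io import IUPAC, ProfileAlignment, compute_profiles

RESIDUES = "ACGU"
WC_PAIRS = [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]

#: default per-column background substitution probability per sequence;
#: applies to every column, helix positions included (where it produces
#: the occasional mismatched pair real families show)
DEFAULT_MUTATION_RATE = 0.12
#: default reduced substitution rate inside planted motif columns
DEFAULT_MOTIF_MUTATION_RATE = 0.05


@dataclass
class PlantedHelix:
    pairs: list                    # (i, j) column pairs, 0-based
    covariation_rate: float = 1.0


@dataclass
class PlantedMotif:
    """A motif consensus written into fixed columns.

    ``starts`` gives the first column of each descriptor segment, in
    descriptor order; empty segments consume no columns.
    """

    descriptor: MotifDescriptor
    starts: list

    def spans(self) -> list:
        out = []
        for (role, cons), s in zip(self.descriptor.segments, self.starts):
            out.append((role, s, s + len(cons)))
        return out

    def extent(self) -> tuple:
        cols = [s for (_, s, e) in self.spans()] + \
               [e for (_, s, e) in self.spans()]
        return (min(cols), max(cols))


@dataclass
class PlantSpec:
    length: int
    n_seqs: int
    helices: list = field(default_factory=list)
    motifs: list = field(default_factory=list)
    mutation_rate: float = DEFAULT_MUTATION_RATE
    motif_mutation_rate: float = DEFAULT_MOTIF_MUTATION_RATE
    #: substitution rate on helix columns (single-side mismatches); when
    #: None, the background rate applies there too
    helix_mutation_rate: float = None
    seed: int = 0

    def __post_init__(self):
        claimed: dict[int, str] = {}

        def claim(cols, kind):
            for c in cols:
                if not 0 <= c < self.length:
                    raise ContractError(f"planted {kind} column {c} out of range")
                if c in claimed:
                    raise ContractError(
                        f"planted {kind} overlaps {claimed[c]} at column {c}")
                claimed[c] = kind

        for h in self.helices:
            claim([c for p in h.pairs for c in p], "helix")
        for m in self.motifs:
            claim([c for (_, s, e) in m.spans() for c in range(s, e)], "motif")


def _sample_from_code(code: str, rng: np.random.Generator) -> str:
    return rng.choice(list(IUPAC[code]))


def generate(spec: PlantSpec) -> tuple[ProfileAlignment, dict]:
    """Generate an alignment from a plant specification.

    Returns the alignment plus a truth dictionary with the planted pairs
    and the planted motifs' names, segment spans and overall extents.
    """
    rng = np.random.default_rng(spec.seed)
    L, S = spec.length, spec.n_seqs

    ancestor = [rng.choice(list(RESIDUES)) for _ in range(L)]
    helix_cols = set()
    for h in spec.helices:
        for (i, j) in h.pairs:
            a, b = WC_PAIRS[rng.integers(len(WC_PAIRS))]
            ancestor[i], ancestor[j] = a, b
            helix_cols.update((i, j))
    motif_cols: dict[int, str] = {}
    for m in spec.motifs:
        for (role, s, e), (r2, cons) in zip(m.spans(), m.descriptor.segments):
            for off, code in enumerate(cons):
                ancestor[s + off] = _sample_from_code(code, rng)
                motif_cols[s + off] = code

    seqs = []
    for _ in range(S):
        seq = list(ancestor)
        for h in spec.helices:
            for (i, j) in h.pairs:
                if rng.random() < h.covariation_rate:
                    a, b = WC_PAIRS[rng.integers(len(WC_PAIRS))]
                    seq[i], seq[j] = a, b
        helix_rate = (spec.mutation_rate if spec.helix_mutation_rate is None
                      else spec.helix_mutation_rate)
        for c in range(L):
            if c in motif_cols:
                rate = spec.motif_mutation_rate
            elif c in helix_cols:
                rate = helix_rate
            else:
                rate = spec.mutation_rate
            if rng.random() < rate:
                seq[c] = rng.choice(list(RESIDUES))
        seqs.append("".join(seq))

    aln = compute_profiles(
        ProfileAlignment(
            seq_names=[f"seq{k + 1}" for k in range(S)], seqs=seqs),
        weighting="henikoff",
    )
    truth = {
        "pairs": sorted({p for h in spec.helices for p in h.pairs}),
        "motifs": [
            {
                "name": m.descriptor.name,
                "segments": m.spans(),
                "extent": m.extent(),
            }
            for m in spec.motifs
        ],
    }
    return aln, truth


def column_shuffle(aln: ProfileAlignment, seed: int = 0) -> ProfileAlignment:
    """Permute each column's residues independently across sequences.

    Per-column residue multisets (hence base composition) are preserved
    exactly; the shuffle is deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    S, L = aln.n_seqs, aln.n_cols
    grid = [list(s) for s in aln.seqs]
    for c in range(L):
        perm = rng.permutation(S)
        col = [grid[r][c] for r in range(S)]
        for r in range(S):
            grid[r][c] = col[perm[r]]
    seqs = ["".join(row) for row in grid]
    return compute_profiles(
        ProfileAlignment(seq_names=list(aln.seq_names), seqs=seqs),
        weighting="henikoff",
    )


# ---------------------------------------------------------------------------
# benchmark fixture: planted GNRA hairpin + K-turn internal loop


def _helix(i0: int, j0: int, n: int) -> list:
    return [(i0 + t, j0 - t) for t in range(n)]


def prototype_descriptors(descriptors: list) -> list:
    """The two-motif (GNRA + K-turn) subset used by the prototype benchmark."""
    wanted = {"GNRA", "K-turn"}
    out = [d for d in descriptors if d.name in wanted]
    if len(out) != 2:
        raise ContractError("descriptor set lacks GNRA and/or K-turn")
    return out


def prototype_spec(seed: int, descriptors: list,
                   n_seqs: int = 50,
                   covariation_rate: float = 0.6) -> PlantSpec:
    """A 46-column alignment with one GNRA tetraloop and one K-turn.

    Layout: flank, a 4-pair helix closing the GNRA loop, a spacer, then a
    K-turn region (4-pair outer helix, 2-column left strand carrying the
    GA pairs, 4-pair inner helix with a generic tetraloop, 5-column right
    strand AG+RNN).
    """
    by_name = {d.name: d for d in descriptors}
    gnra = by_name["GNRA"]
    kturn = by_name["K-turn"]
    # GNRA: helix columns 2-5 paired with 13-10, loop columns 6..9
    h1 = PlantedHelix(_helix(2, 13, 4), covariation_rate)
    m_gnra = PlantedMotif(gnra, starts=[6, 7, 8])  # G | N | RA -> cols 6..9
    # K-turn region: outer helix 17-20 / 45-42, inner helix 23-26 / 36-33
    h2 = PlantedHelix(_helix(17, 45, 4), covariation_rate)
    h3 = PlantedHelix(_helix(23, 36, 4), covariation_rate)
    # left strand cols 21..22 = GA (inL); right strand cols 37..41 = AG RNN
    m_kturn = PlantedMotif(
        kturn,
        # roles: outL loopL inL inR loopR outR
        starts=[21, 21, 21, 37, 39, 42],
    )
    return PlantSpec(
        length=46, n_seqs=n_seqs,
        helices=[h1, h2, h3],
        motifs=[m_gnra, m_kturn],
        seed=seed,
    )


def single_sequence(aln: ProfileAlignment, index: int = 0) -> ProfileAlignment:
    """One sequence of an alignment as a single-row profile."""
    return compute_profiles(
        ProfileAlignment(seq_names=[aln.seq_names[index]],
                         seqs=[aln.seqs[index]]),
        weighting="none",
    )


def prototype_replicate(seed: int, descriptors: list,
                        n_null_shuffles: int = 100) -> dict:
    """One paired with/without-covariation run of the prototype benchmark.

    An alignment with a planted GNRA tetraloop and K-turn is generated and
    classified; the first sequence is then folded twice — once constrained
    by the classification, once without any constraints — and both
    predictions are scored against the planted truth by exact end matching.
    """
    from .covariation import CovariationConfig, classify_pairs
    from .pipeline import PipelineConfig, fold_alignment

    two = prototype_descriptors(descriptors)
    aln, truth = generate(prototype_spec(seed=seed, descriptors=two))
    results = classify_pairs(
        aln, CovariationConfig(seed=seed, n_null_shuffles=n_null_shuffles))
    seq0 = single_sequence(aln)
    with_cov = fold_alignment(seq0, two, PipelineConfig(pair_results=results))
    without = fold_alignment(seq0, two, PipelineConfig(no_covariation=True))
    return {
        "truth": truth,
        "with_covariation": evaluate_placements(with_cov, truth),
        "without_covariation": evaluate_placements(without, truth),
    }


def evaluate_placements(result, truth) -> dict:
    """Exact-end motif detection counts against a truth annotation.

    A planted motif counts as detected when some placement has the same
    motif name and the same overall column extent (exact end matching);
    every other placement is a false positive.
    """
    truth_keys = {(m["name"], tuple(m["extent"])) for m in truth["motifs"]}
    found = set()
    n_fp = 0
    for pl in result.motif_placements:
        key = (pl.motif, pl.span)
        if key in truth_keys:
            found.add(key)
        else:
            n_fp += 1
    return {
        "n_true": len(truth_keys),
        "n_detected": len(found),
        "n_false_positives": n_fp,
        "sensitivity": len(found) / len(truth_keys) if truth_keys else float("nan"),
    }
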