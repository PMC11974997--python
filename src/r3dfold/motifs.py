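"""RNA 3D motif descriptors, segment profile HMMs and variant sub-grammars.

A motif descriptor names a motif, assigns it one of six loop architectures
(hairpin HL, bulge BL, internal loop IL, 3-way junction J3, 4-way junction
J4, branch segment BS) and lists role-tagged consensus segments.  Each
descriptor compiles into one sub-grammar per topological variant (1 for
HL and BS, 2 for BL and IL, 3 for J3, 4 for J4); the variant's terminals
are short profile HMMs, one per segment, which accommodate substitutions,
insertions and deletions around the consensus.

Closing Watson-Crick pairs of the helices that bound a motif are emitted
by the base folding grammar, never by the motif models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, FormatError
from .msa_io import IUPAC, ProfileAlignment
from .scfg import NEG_INF, Grammar

#: per-position probability of any residue outside the consensus code's set
OFF_CONSENSUS_PROB = 1e-4
#: default per-position deletion probability
DEFAULT_DELETE_PROB = 0.01

MOTIF_TYPES = ("HL", "BL", "IL", "J3", "J4", "BS")

#: variant multiplicities per architecture
VARIANTS_PER_TYPE = {"HL": 1, "BL": 2, "IL": 2, "J3": 3, "J4": 4, "BS": 1}

#: maximum number of correlated left/right segment pairs in an HL motif
MAX_HL_PAIRS = 4

RESIDUES = "ACGU"


# ---------------------------------------------------------------------------
# segment profile HMMs


def _consensus_emissions(consensus: str) -> np.ndarray:
    """Per-position emission table: off-consensus residues get 1e-4 each,
    residues inside the consensus code's set share the remainder equally."""
    k = len(consensus)
    em = np.zeros((k, 4))
    for t, code in enumerate(consensus):
        inset = IUPAC[code]
        n_out = 4 - len(inset)
        share = (1.0 - n_out * OFF_CONSENSUS_PROB) / len(inset)
        for r_i, r in enumerate(RESIDUES):
            em[t, r_i] = share if r in inset else OFF_CONSENSUS_PROB
    return em


class ProfileHMM:
    """Profile HMM over a short consensus; emissions occur on transitions.

    Between consecutive match transitions (and at both ends) sits a
    geometric insert loop with per-step probability ``alpha``; each match
    may be skipped (deleted) with probability ``delta``.  ``alpha`` is
    solved analytically so the expected emitted length is exactly
    ``k + min(0.1 k, 1.5)`` (an empty consensus gets expected length 0.1),
    the deletion loss included.
    """

    def __init__(self, consensus: str, delta: float = DEFAULT_DELETE_PROB):
        consensus = consensus.upper().replace("T", "U")
        for ch in consensus:
            if ch not in IUPAC:
                raise FormatError(f"illegal consensus code '{ch}'")
        self.consensus = consensus
        self.k = len(consensus)
        self.delta = float(delta)
        self.match_emit = _consensus_emissions(consensus)
        self.insert_emit = np.full(4, 0.25)
        extra = 0.1 if self.k == 0 else min(0.1 * self.k, 1.5)
        self.extra = extra
        # (k+1) * alpha/(1-alpha) = extra + k*delta  (compensates deletions)
        target = extra + self.k * self.delta
        self.alpha = target / (self.k + 1 + target)

    @property
    def expected_length(self) -> float:
        """Analytic expected emitted length."""
        ins = (self.k + 1) * self.alpha / (1.0 - self.alpha)
        return self.k * (1.0 - self.delta) + ins

    @property
    def may_be_empty(self) -> bool:
        return self.k == 0 or self.delta > 0

    # -- scoring ------------------------------------------------------------

    def _emission_scores(self, aln: ProfileAlignment):
        """Expected log-probability of each column under match/insert tables."""
        freq = aln.renormalized_freq()
        ins = freq @ np.log(self.insert_emit)
        match = freq @ np.log(self.match_emit.T) if self.k else np.zeros((aln.n_cols, 0))
        return match, ins  # match[c, t], ins[c]

    def forward_span_scores(self, aln: ProfileAlignment) -> np.ndarray:
        """Matrix F with F[i, j] = log P(model emits exactly columns i..j-1).

        Computed by the forward algorithm, summing over insertion/deletion
        paths; unreachable span lengths score -inf (e.g. spans shorter than
        k when delta = 0).
        """
        L = aln.n_cols
        match, ins_sc = self._emission_scores(aln)
        la = math.log(self.alpha) if self.alpha > 0 else NEG_INF
        l1a = math.log(1.0 - self.alpha)
        ld = math.log(self.delta) if self.delta > 0 else NEG_INF
        l1d = math.log(1.0 - self.delta)
        F = np.full((L + 1, L + 1), NEG_INF)
        for i in range(L + 1):
            # abar[c] : at current junction, consumed columns i..c-1, not exited
            abar = np.full(L + 1, NEG_INF)
            abar[i] = 0.0
            for c in range(i + 1, L + 1):
                abar[c] = abar[c - 1] + la + ins_sc[c - 1]
            for t in range(self.k):
                a_prev = abar + l1a  # exited previous junction
                abar = np.full(L + 1, NEG_INF)
                for c in range(i, L + 1):
                    emit = a_prev[c - 1] + l1d + match[c - 1, t] if c > i else NEG_INF
                    skip = a_prev[c] + ld
                    b = np.logaddexp(emit, skip)
                    if c > i:
                        b = np.logaddexp(b, abar[c - 1] + la + ins_sc[c - 1])
                    abar[c] = b
            F[i, i:] = (abar + l1a)[i:]
        return F

    def score_span(self, aln: ProfileAlignment, i: int, j: int) -> float:
        """Log-probability of emitting exactly columns i..j (inclusive).

        The empty span is expressed as j = i - 1.
        """
        if not (0 <= i <= j + 1 <= aln.n_cols):
            raise ContractError(f"invalid span {i}..{j} for L={aln.n_cols}")
        return float(self.forward_span_scores(aln)[i, j + 1])

    # -- sampling -----------------------------------------------------------

    def sample(self, rng: np.random.Generator) -> str:
        out = []

        def inserts():
            while rng.random() < self.alpha:
                out.append(RESIDUES[rng.choice(4, p=self.insert_emit)])

        inserts()
        for t in range(self.k):
            if rng.random() >= self.delta:
                out.append(RESIDUES[rng.choice(4, p=self.match_emit[t])])
            inserts()
        return "".join(out)


def build_segment_hmm(consensus: str, delta: float = DEFAULT_DELETE_PROB) -> ProfileHMM:
    """Compile one consensus segment ('-' or '' denotes an empty segment)."""
    if consensus == "-":
        consensus = ""
    return ProfileHMM(consensus, delta=delta)


def hmm_forward(hmm: ProfileHMM, aln: ProfileAlignment, i: int, j: int) -> float:
    """Forward log-probability that ``hmm`` emits exactly columns i..j."""
    return hmm.score_span(aln, i, j)


# ---------------------------------------------------------------------------
# descriptors


_ROLES = {
    "BL": ["L", "loop", "R"],
    "IL": ["outL", "loopL", "inL", "inR", "loopR", "outR"],
    "J3": ["S1", "S2", "S3"],
    "J4": ["S1", "S2", "S3", "S4"],
    "BS": ["seg"],
}


@dataclass
class MotifDescriptor:
    """A named motif: architecture type plus role-tagged consensus segments."""

    name: str
    mtype: str
    segments: list  # ordered (role, consensus) pairs; '' = empty segment

    def __post_init__(self):
        if self.mtype not in MOTIF_TYPES:
            raise FormatError(f"motif '{self.name}': unknown type '{self.mtype}'")
        roles = [r for r, _ in self.segments]
        if self.mtype == "HL":
            k = sum(1 for r in roles if r.startswith("L"))
            expect = [f"L{t}" for t in range(1, k + 1)] + ["loop"] + \
                     [f"R{t}" for t in range(k, 0, -1)]
            if k < 1 or k > MAX_HL_PAIRS or roles != expect:
                raise FormatError(
                    f"motif '{self.name}': HL needs roles L1..Lk, loop, Rk..R1 "
                    f"(k <= {MAX_HL_PAIRS}), got {roles}")
        else:
            if roles != _ROLES[self.mtype]:
                raise FormatError(
                    f"motif '{self.name}': {self.mtype} needs roles "
                    f"{_ROLES[self.mtype]}, got {roles}")
        for role, cons in self.segments:
            for ch in cons:
                if ch not in IUPAC:
                    raise FormatError(
                        f"motif '{self.name}': illegal residue code '{ch}' "
                        f"in segment {role}")

    @property
    def n_variants(self) -> int:
        return VARIANTS_PER_TYPE[self.mtype]

    def segment(self, role: str) -> str:
        for r, c in self.segments:
            if r == role:
                return c
        raise ContractError(f"motif '{self.name}' has no segment '{role}'")


def parse_descriptor_file(path) -> list[MotifDescriptor]:
    """Parse the motif descriptor dialect.

    One record per line: ``NAME TYPE role=CONSENSUS ...`` where CONSENSUS
    is an IUPAC string and '-' marks an empty segment.  Lines starting
    with '#' are comments.
    """
    out = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"line {ln}: expected 'NAME TYPE role=CONS ...'")
            name, mtype = parts[0], parts[1]
            segments = []
            for tok in parts[2:]:
                role, eq, cons = tok.partition("=")
                if not eq:
                    raise FormatError(
                        f"line {ln} (motif '{name}'): bad segment token '{tok}'")
                cons = "" if cons == "-" else cons.upper().replace("T", "U")
                segments.append((role, cons))
            try:
                out.append(MotifDescriptor(name, mtype, segments))
            except FormatError as exc:
                raise FormatError(f"line {ln}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# variant compilation


@dataclass
class MotifVariant:
    """One topological variant of a motif, insertable into the base grammar.

    ``nt`` is the variant's start nonterminal, ``rhs`` its production
    (segment atoms plus ``F0`` helix re-entries), ``host`` the base-grammar
    nonterminal that receives ``production`` as an extra rule.
    """

    nt: str
    rhs: tuple
    host: str
    production: tuple


@dataclass
class MotifModel:
    descriptor: MotifDescriptor
    variants: list
    segment_hmms: dict  # qualified name -> ProfileHMM

    @property
    def name(self) -> str:
        return self.descriptor.name


def _seg_atom(name: str, role: str):
    return ("seg", f"{name}~{role}")


def compile_motif(d: MotifDescriptor, helix_nt: str = "F0") -> MotifModel:
    """Compile a descriptor into its topological variant sub-grammars.

    Multi-strand motifs get one variant per possible 5'/3' attachment to
    their bounding helices: the strand order is rotated around the loop so
    each bounding helix once plays the enclosing role.
    """
    segs = {role: f"{d.name}~{role}" for role, _ in d.segments}
    hmms = {f"{d.name}~{role}": build_segment_hmm(cons or "")
            for role, cons in d.segments}
    F0 = ("nt", helix_nt)
    variants = []

    def V(i):
        return f"{d.name}~v{i}"

    if d.mtype == "HL":
        rhs = tuple(("seg", segs[r]) for r, _ in d.segments)
        variants.append(MotifVariant(V(0), rhs, "P", (("nt", V(0)),)))
    elif d.mtype == "BL":
        rhs = tuple(("seg", segs[r]) for r in ("L", "loop", "R"))
        variants.append(MotifVariant(V(0), rhs, "P", (("nt", V(0)), F0)))
        variants.append(MotifVariant(V(1), rhs, "P", (F0, ("nt", V(1)))))
    elif d.mtype == "IL":
        left = [("seg", segs[r]) for r in ("outL", "loopL", "inL")]
        right = [("seg", segs[r]) for r in ("inR", "loopR", "outR")]
        rhs0 = tuple(left + [F0] + right)
        # rotated attachment: the inner helix becomes the enclosing one
        rhs1 = tuple(right + [F0] + left)
        variants.append(MotifVariant(V(0), rhs0, "P", (("nt", V(0)),)))
        variants.append(MotifVariant(V(1), rhs1, "P", (("nt", V(1)),)))
    elif d.mtype in ("J3", "J4"):
        roles = _ROLES[d.mtype]
        n = len(roles)
        host = d.mtype
        for v in range(n):
            order = [roles[(v + t) % n] for t in range(n)]
            rhs = []
            for t, r in enumerate(order):
                rhs.append(("seg", segs[r]))
                if t < n - 1:
                    rhs.append(F0)
            variants.append(MotifVariant(V(v), tuple(rhs), host, (("nt", V(v)),)))
    else:  # BS: a lone segment preceding a branch helix
        rhs = (("seg", segs["seg"]),)
        variants.append(MotifVariant(V(0), rhs, "BB", (("nt", V(0)), F0)))

    assert len(variants) == d.n_variants
    return MotifModel(descriptor=d, variants=variants, segment_hmms=hmms)


def expand_all(descriptors: list) -> tuple[list, int]:
    """Compile every descriptor; returns (models, total variant count)."""
    seen = set()
    models = []
    total = 0
    for d in descriptors:
        if d.name in seen:
            raise FormatError(f"duplicate motif name '{d.name}'")
        seen.add(d.name)
        m = compile_motif(d)
        models.append(m)
        total += len(m.variants)
    return models, total


def standalone_variant_grammar(model: MotifModel, vidx: int) -> Grammar:
    """A self-contained grammar for one variant (validation / inspection).

    The base grammar's helix nonterminal is stubbed with a minimal
    pair-emitting rule so the variant's own structure can be checked in
    isolation.
    """
    var = model.variants[vidx]
    g = Grammar(f"{model.name}.v{vidx}", start=var.nt)
    g.add_pair_table("wc", np.full(16, 1 / 16))
    g.add_dist("unp", np.full(4, 0.25))
    g.add_nonterminal(var.nt)
    g.add_rule(var.nt, var.rhs, 1.0)
    needs_f0 = any(a == ("nt", "F0") for a in var.rhs)
    if needs_f0:
        g.add_nonterminal("F0")
        g.add_nonterminal("F0loop")
        g.add_rule("F0", (("nt", "F0loop"),), 1.0, pair="wc")
        g.add_rule("F0loop", (("emit", "unp"), ("nt", "F0loop")), 0.5)
        g.add_rule("F0loop", (("emit", "unp"),), 0.5)
    for name, hmm in model.segment_hmms.items():
        g.add_segment(name, hmm)
    return g
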