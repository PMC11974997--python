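"""Probabilistic context-free grammar machinery over column profiles.

Grammars here generate *probabilistic sequences*: the terminal scoring unit
is an alignment column, scored by the expected log-probability of its
residue distribution under the rule's emission table.  Rules may emit
single columns, correlated column pairs (16-entry tables), reference other
nonterminals, or hand whole subspans to profile-HMM segment models.

Parsing is exact constrained CYK (maximum-probability derivation) and
inside (summed probability), both O(L^3 * rules) after an internal
binarization of multi-atom rules.  A brute-force derivation enumerator
serves as the test oracle on short sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, FormatError, NoStructureError, R3DFoldError
from .msa_io import ProfileAlignment, compute_profiles

NEG_INF = float("-inf")

# ---------------------------------------------------------------------------
# grammar representation


@dataclass(frozen=True)
class Rule:
    """One production.

    ``pair`` names a 16-entry emission table when the rule wraps its span
    in a correlated column pair; ``atoms`` is the ordered inner right-hand
    side, each atom one of ``("nt", name)``, ``("seg", name)`` or
    ``("emit", dist_name)``.  ``tag`` labels loop-class generic rules so
    motif integration can find them.
    """

    lhs: str
    pair: str | None
    atoms: tuple
    logp: float
    tag: str | None = None

    @property
    def prob(self) -> float:
        return math.exp(self.logp)


@dataclass
class ValidationReport:
    ok: bool
    deficits: dict
    missing_refs: list
    unreachable: list
    unproductive: list

    def __str__(self):
        if self.ok:
            return "grammar OK"
        parts = []
        if self.deficits:
            parts += [f"normalization deficit {d:+.3g} at {nt}"
                      for nt, d in self.deficits.items()]
        parts += [f"missing reference {r}" for r in self.missing_refs]
        parts += [f"unreachable nonterminal {nt}" for nt in self.unreachable]
        parts += [f"unproductive nonterminal {nt}" for nt in self.unproductive]
        return "; ".join(parts)


class Grammar:
    """An SCFG: ordered nonterminals, productions, emission tables, segments."""

    def __init__(self, name: str, start: str):
        self.name = name
        self.start = start
        self.nonterminals: list[str] = []
        self.rules: dict[str, list[Rule]] = {}
        self.dists: dict[str, np.ndarray] = {}
        self.pair_tables: dict[str, np.ndarray] = {}
        self.segments: dict[str, object] = {}
        self._compiled = None

    # -- construction -------------------------------------------------------

    def add_nonterminal(self, nt: str):
        if nt in self.rules:
            raise ContractError(f"duplicate nonterminal '{nt}'")
        self.nonterminals.append(nt)
        self.rules[nt] = []

    def add_dist(self, name: str, probs):
        p = np.asarray(probs, dtype=float)
        if p.shape != (4,):
            raise ContractError("residue distribution needs 4 entries")
        self.dists[name] = p

    def add_pair_table(self, name: str, probs):
        p = np.asarray(probs, dtype=float).reshape(4, 4)
        self.pair_tables[name] = p

    def add_segment(self, name: str, segment):
        self.segments[name] = segment

    def add_rule(self, lhs: str, atoms, prob: float, pair: str | None = None,
                 tag: str | None = None):
        if lhs not in self.rules:
            raise ContractError(f"unknown nonterminal '{lhs}'")
        logp = math.log(prob) if prob > 0 else NEG_INF
        self.rules[lhs].append(Rule(lhs, pair, tuple(atoms), logp, tag))
        self._compiled = None

    def scale_rule(self, lhs: str, index: int, factor: float):
        """Multiply one rule's probability by ``factor`` (motif integration)."""
        r = self.rules[lhs][index]
        logp = r.logp + (math.log(factor) if factor > 0 else NEG_INF)
        self.rules[lhs][index] = Rule(r.lhs, r.pair, r.atoms, logp, r.tag)
        self._compiled = None

    def rule_prob(self, lhs: str, index: int) -> float:
        return self.rules[lhs][index].prob

    def find_tagged(self, tag: str) -> list[tuple[str, int]]:
        out = []
        for nt in self.nonterminals:
            for k, r in enumerate(self.rules[nt]):
                if r.tag == tag:
                    out.append((nt, k))
        return out

    def copy(self) -> "Grammar":
        g = Grammar(self.name, self.start)
        for nt in self.nonterminals:
            g.add_nonterminal(nt)
            g.rules[nt] = list(self.rules[nt])
        g.dists = {k: v.copy() for k, v in self.dists.items()}
        g.pair_tables = {k: v.copy() for k, v in self.pair_tables.items()}
        g.segments = dict(self.segments)
        return g

    # -- validation ---------------------------------------------------------

    def validate(self, tol: float = 1e-9) -> ValidationReport:
        deficits = {}
        missing = []
        for nt in self.nonterminals:
            total = sum(r.prob for r in self.rules[nt])
            if abs(total - 1.0) > tol:
                deficits[nt] = 1.0 - total
            for r in self.rules[nt]:
                if r.pair is not None and r.pair not in self.pair_tables:
                    missing.append(f"pair table '{r.pair}' in {nt}")
                for a in r.atoms:
                    kind, ref = a[0], a[1]
                    if kind == "nt" and ref not in self.rules:
                        missing.append(f"nonterminal '{ref}' in {nt}")
                    elif kind == "seg" and ref not in self.segments:
                        missing.append(f"segment '{ref}' in {nt}")
                    elif kind == "emit" and ref not in self.dists:
                        missing.append(f"distribution '{ref}' in {nt}")
        # reachability
        reach = set()
        stack = [self.start]
        while stack:
            nt = stack.pop()
            if nt in reach or nt not in self.rules:
                continue
            reach.add(nt)
            for r in self.rules[nt]:
                for a in r.atoms:
                    if a[0] == "nt":
                        stack.append(a[1])
        unreachable = [nt for nt in self.nonterminals if nt not in reach]
        # productivity (can derive a finite string)
        productive = set()
        changed = True
        while changed:
            changed = False
            for nt in self.nonterminals:
                if nt in productive:
                    continue
                for r in self.rules[nt]:
                    if all(a[0] != "nt" or a[1] in productive for a in r.atoms):
                        productive.add(nt)
                        changed = True
                        break
        unproductive = [nt for nt in self.nonterminals if nt not in productive]
        ok = not (deficits or missing or unreachable or unproductive)
        return ValidationReport(ok, deficits, missing, unreachable, unproductive)

    # -- serialization ------------------------------------------------------

    def to_text(self) -> str:
        lines = [f"grammar {self.name}", f"start {self.start}"]
        for name, p in self.dists.items():
            lines.append("dist " + name + " " + " ".join(repr(float(x)) for x in p))
        for name, p in self.pair_tables.items():
            lines.append("pairtable " + name + " "
                         + " ".join(repr(float(x)) for x in p.ravel()))
        for name, seg in self.segments.items():
            cons = getattr(seg, "consensus", "")
            lines.append(f"# segment {name} consensus={cons or '-'}")
        for nt in self.nonterminals:
            lines.append(f"nt {nt}")
            for r in self.rules[nt]:
                head = f"rule {repr(float(r.prob))}"
                if r.pair is not None:
                    head += f" pair={r.pair}"
                if r.tag is not None:
                    head += f" tag={r.tag}"
                body = " ".join(f"{a[0]}:{a[1]}" for a in r.atoms)
                lines.append(f"  {head} | {body}".rstrip())
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, segments: dict | None = None) -> "Grammar":
        g = None
        start = None
        pending = []
        current_nt = None
        for ln, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "grammar":
                g = cls(parts[1], start="?")
            elif parts[0] == "start":
                g.start = parts[1]
            elif parts[0] == "dist":
                g.add_dist(parts[1], [float(x) for x in parts[2:6]])
            elif parts[0] == "pairtable":
                g.add_pair_table(parts[1], [float(x) for x in parts[2:18]])
            elif parts[0] == "nt":
                current_nt = parts[1]
                g.add_nonterminal(current_nt)
            elif parts[0] == "rule":
                if current_nt is None:
                    raise FormatError(f"line {ln}: rule outside nonterminal block")
                head, _, body = line.partition("|")
                hp = head.split()
                prob = float(hp[1])
                pair = None
                tag = None
                for extra in hp[2:]:
                    k, _, v = extra.partition("=")
                    if k == "pair":
                        pair = v
                    elif k == "tag":
                        tag = v
                    else:
                        raise FormatError(f"line {ln}: unknown rule option '{extra}'")
                atoms = []
                for tok in body.split():
                    kind, _, ref = tok.partition(":")
                    if kind not in ("nt", "seg", "emit"):
                        raise FormatError(f"line {ln}: unknown atom '{tok}'")
                    atoms.append((kind, ref))
                g.add_rule(current_nt, atoms, prob, pair=pair, tag=tag)
            else:
                raise FormatError(f"line {ln}: unknown directive '{parts[0]}'")
        if g is None:
            raise FormatError("missing 'grammar' header")
        if segments:
            for name, seg in segments.items():
                g.add_segment(name, seg)
        return g

    # -- compilation --------------------------------------------------------

    def compiled(self) -> "_CompiledGrammar":
        if self._compiled is None:
            self._compiled = _CompiledGrammar(self)
        return self._compiled

    # -- generative sampling ------------------------------------------------

    def sample(self, rng: np.random.Generator, max_len: int = 10_000,
               max_depth: int = 200):
        """Sample one derivation; returns (sequence string, ParseNode).

        Profile-HMM segments are sampled from their own generative model;
        the returned tree carries absolute column coordinates.
        """
        residues = "ACGU"

        def shift(node: "ParseNode", off: int):
            node.span = (node.span[0] + off, node.span[1] + off)
            if node.pair is not None:
                node.pair = (node.pair[0] + off, node.pair[1] + off)
            node.segs = [(n, a + off, b + off) for (n, a, b) in node.segs]
            node.emits = [c + off for c in node.emits]
            for ch in node.children:
                shift(ch, off)

        def gen_nt(nt: str, depth: int):
            if depth > max_depth:
                raise RecursionError("sampling exceeded depth guard")
            rules = self.rules[nt]
            probs = np.array([r.prob for r in rules])
            ridx = int(rng.choice(len(rules), p=probs / probs.sum()))
            r = rules[ridx]
            node = ParseNode(nt=nt, rule_index=ridx, span=(0, 0))
            seq = ""
            if r.pair is not None:
                tbl = self.pair_tables[r.pair].ravel()
                cell = int(rng.choice(16, p=tbl / tbl.sum()))
                cl, cr = residues[cell // 4], residues[cell % 4]
                inner, inner_events = gen_atoms(r.atoms, depth)
                seq = cl + inner + cr
                node.pair = (0, len(seq) - 1)
                _apply_events(node, inner_events, off=1)
            else:
                seq, events = gen_atoms(r.atoms, depth)
                _apply_events(node, events, off=0)
            node.span = (0, len(seq))
            if len(seq) > max_len:
                raise RecursionError("sampling exceeded length guard")
            return seq, node

        def _apply_events(node, events, off):
            pos = off
            for ev in events:
                if ev[0] == "res":
                    node.emits.append(pos)
                    pos += 1
                elif ev[0] == "seg":
                    node.segs.append((ev[1], pos, pos + len(ev[2])))
                    pos += len(ev[2])
                else:  # child
                    child = ev[1]
                    shift(child, pos)
                    node.children.append(child)
                    pos = child.span[1]

        def gen_atoms(atoms, depth):
            seq = ""
            events = []
            for a in atoms:
                if a[0] == "emit":
                    p = self.dists[a[1]]
                    ch = residues[int(rng.choice(4, p=p / p.sum()))]
                    seq += ch
                    events.append(("res", ch))
                elif a[0] == "seg":
                    s = self.segments[a[1]].sample(rng)
                    seq += s
                    events.append(("seg", a[1], s))
                else:
                    sub_seq, sub_node = gen_nt(a[1], depth + 1)
                    seq += sub_seq
                    events.append(("child", sub_node))
            return seq, events

        while True:
            try:
                seq, node = gen_nt(self.start, 0)
            except RecursionError:
                continue
            return seq, node


# ---------------------------------------------------------------------------
# parse trees


@dataclass
class ParseNode:
    """A derivation node for one original-grammar rule application.

    ``span`` is half-open column coordinates; ``pair`` is the closed
    (i, j) column pair emitted by the rule, if any; ``segs`` holds
    (segment name, start, end) half-open spans; ``emits`` the single
    columns emitted by this rule's chain.
    """

    nt: str
    rule_index: int
    span: tuple
    pair: tuple | None = None
    segs: list = field(default_factory=list)
    emits: list = field(default_factory=list)
    children: list = field(default_factory=list)

    def walk(self):
        yield self
        for ch in self.children:
            yield from ch.walk()


def tree_pairs(node: ParseNode) -> set:
    return {n.pair for n in node.walk() if n.pair is not None}


def tree_annotation(node: ParseNode, motif_nts: set | None = None):
    """Hashable (pairs, motif placements) annotation of a derivation.

    Motif placements are (nt, span, segment spans) for nodes whose
    nonterminal is in ``motif_nts`` (all NTs containing '~' by default,
    the motif-variant naming convention).
    """
    pairs = tuple(sorted(tree_pairs(node)))
    motifs = []
    for n in node.walk():
        is_motif = ("~" in n.nt) if motif_nts is None else (n.nt in motif_nts)
        if is_motif:
            motifs.append((n.nt, n.span, tuple(sorted(n.segs))))
    return pairs, tuple(sorted(motifs))


# ---------------------------------------------------------------------------
# constraints


@dataclass
class Constraints:
    """Covariation-derived folding constraints.

    ``forced_pairs`` must all appear in the derivation; ``forbidden_pairs``
    and ``forbidden_columns`` may not pair; when ``allowed_pairs`` is given
    it is a whitelist (anything outside it is forbidden).
    """

    forced_pairs: set = field(default_factory=set)
    forbidden_pairs: set = field(default_factory=set)
    forbidden_columns: set = field(default_factory=set)
    allowed_pairs: set | None = None

    def __post_init__(self):
        if self.forced_pairs & self.forbidden_pairs:
            raise ContractError("forced and forbidden pair sets overlap")
        pairs = sorted(self.forced_pairs)
        used = {}
        for (i, j) in pairs:
            if i >= j:
                raise ContractError(f"forced pair ({i},{j}) needs i < j")
            for c in (i, j):
                if c in used:
                    raise ContractError(f"column {c} forced into two pairs")
                used[c] = True
        for a in range(len(pairs)):
            for b in range(a + 1, len(pairs)):
                (i, j), (k, l) = pairs[a], pairs[b]
                if i < k < j < l:
                    raise ContractError(
                        f"forced pairs ({i},{j}) and ({k},{l}) cross")
        self._partner = {}
        for (i, j) in self.forced_pairs:
            self._partner[i] = j
            self._partner[j] = i

    def pair_ok(self, i: int, j: int) -> bool:
        if self.allowed_pairs is not None and (i, j) not in self.allowed_pairs:
            return False
        if (i, j) in self.forbidden_pairs:
            return False
        if i in self.forbidden_columns or j in self.forbidden_columns:
            return False
        for c, other in ((i, j), (j, i)):
            p = self._partner.get(c)
            if p is not None and p != other:
                return False
        return True

    def unpaired_ok(self, c: int) -> bool:
        return c not in self._partner


# ---------------------------------------------------------------------------
# compiled (binarized) form


class _CompiledGrammar:
    """Binarized rule set: every rule has at most two variable-width parts."""

    def __init__(self, g: Grammar):
        self.g = g
        self.symbols: list[str] = []
        self.rules: dict[str, list[tuple]] = {}
        self._anon = 0
        for nt in g.nonterminals:
            self._ensure(nt)
        for nt in g.nonterminals:
            for ridx, r in enumerate(g.rules[nt]):
                self._compile_rule(nt, ridx, r)
        self._analyze()

    def _ensure(self, sym: str):
        if sym not in self.rules:
            self.symbols.append(sym)
            self.rules[sym] = []

    def _new_anon(self, base: str) -> str:
        self._anon += 1
        sym = f"@{base}#{self._anon}"
        self._ensure(sym)
        return sym

    def _sym_for_atom(self, atom, base: str) -> str:
        kind, ref = atom
        if kind == "nt":
            return ref
        sym = self._new_anon(base)
        if kind == "seg":
            self.rules[sym].append(("hmm", ref, 0.0))
        else:
            self.rules[sym].append(("term", ref, 0.0))
        return sym

    def _sym_for_atoms(self, atoms, base: str) -> str:
        if len(atoms) == 1:
            return self._sym_for_atom(atoms[0], base)
        sym = self._new_anon(base)
        self._attach(sym, atoms, 0.0)
        return sym

    def _attach(self, sym: str, atoms, logp: float):
        base = sym.lstrip("@").split("#")[0]
        if len(atoms) == 0:
            self.rules[sym].append(("eps", logp))
        elif len(atoms) == 1:
            kind, ref = atoms[0]
            if kind == "nt":
                self.rules[sym].append(("unary", ref, logp))
            elif kind == "seg":
                self.rules[sym].append(("hmm", ref, logp))
            else:
                self.rules[sym].append(("term", ref, logp))
        elif atoms[0][0] == "emit":
            rest = self._sym_for_atoms(atoms[1:], base)
            self.rules[sym].append(("left", atoms[0][1], rest, logp))
        elif atoms[-1][0] == "emit":
            head = self._sym_for_atoms(atoms[:-1], base)
            self.rules[sym].append(("right", head, atoms[-1][1], logp))
        else:
            left = self._sym_for_atom(atoms[0], base)
            rest = self._sym_for_atoms(atoms[1:], base)
            self.rules[sym].append(("split", left, rest, logp))

    def _compile_rule(self, nt: str, ridx: int, r: Rule):
        if r.pair is not None:
            inner = self._sym_for_atoms(r.atoms, nt) if r.atoms else None
            if inner is None:
                inner = self._new_anon(nt)
                self.rules[inner].append(("eps", 0.0))
            self.rules[nt].append(("pair", r.pair, inner, r.logp, ridx))
        else:
            before = len(self.rules[nt])
            self._attach(nt, r.atoms, r.logp)
            # tag the newly attached top rule with the original rule index
            self.rules[nt][before] = self.rules[nt][before] + (ridx,)

    def _analyze(self):
        # emptyable fixpoint (hmm symbols conservatively emptyable)
        emptyable = set()
        changed = True
        while changed:
            changed = False
            for sym in self.symbols:
                if sym in emptyable:
                    continue
                for cr in self.rules[sym]:
                    kind = cr[0]
                    if kind == "eps" or kind == "hmm":
                        ok = True
                    elif kind == "unary":
                        ok = cr[1] in emptyable
                    elif kind == "split":
                        ok = cr[1] in emptyable and cr[2] in emptyable
                    else:
                        ok = False
                    if ok:
                        emptyable.add(sym)
                        changed = True
                        break
        self.emptyable = emptyable
        # same-span dependency graph -> topological order
        deps: dict[str, set] = {s: set() for s in self.symbols}
        for sym in self.symbols:
            for cr in self.rules[sym]:
                kind = cr[0]
                if kind == "unary":
                    deps[sym].add(cr[1])
                elif kind == "split":
                    if cr[2] in emptyable:
                        deps[sym].add(cr[1])
                    if cr[1] in emptyable:
                        deps[sym].add(cr[2])
        order = []
        state: dict[str, int] = {}

        def visit(s):
            if state.get(s) == 2:
                return
            if state.get(s) == 1:
                raise R3DFoldError("cyclic same-span dependency in grammar")
            state[s] = 1
            for d in deps[s]:
                visit(d)
            state[s] = 2
            order.append(s)

        for s in self.symbols:
            visit(s)
        self.topo_order = order


# ---------------------------------------------------------------------------
# emission scoring


class _Scorer:
    """Per-parse precomputed emission scores with constraints applied."""

    def __init__(self, g: Grammar, aln: ProfileAlignment, cons: Constraints):
        self.g = g
        L = aln.n_cols
        self.L = L
        freq = aln.renormalized_freq() if L else np.zeros((0, 4))
        used = freq > 1e-12
        unp_ok = np.array([cons.unpaired_ok(c) for c in range(L)], dtype=bool)
        self.E = {}
        for name, d in g.dists.items():
            logd = np.log(np.maximum(d, 1e-300))
            e = freq @ logd
            # a column putting mass on a zero-probability residue cannot be
            # emitted by this distribution at all
            impossible = used @ (d <= 0)
            e[impossible > 0] = NEG_INF
            e[~unp_ok] = NEG_INF
            self.E[name] = e
        self.P = {}
        pair_ok = np.zeros((L, L), dtype=bool)
        for i in range(L):
            for j in range(i + 1, L):
                pair_ok[i, j] = cons.pair_ok(i, j)
        for name, t in g.pair_tables.items():
            logt = np.log(np.maximum(t, 1e-300))
            p = np.einsum("ia,jb,ab->ij", freq, freq, logt)
            impossible = np.einsum("ia,jb,ab->ij", used.astype(float),
                                   used.astype(float), (t <= 0).astype(float))
            p[impossible > 0] = NEG_INF
            p[~pair_ok] = NEG_INF
            self.P[name] = p
        # segment span scores, masked so segments never cover forced columns
        bad = np.cumsum(np.concatenate([[0], (~unp_ok).astype(int)]))
        self.S = {}
        for name, seg in g.segments.items():
            m = seg.forward_span_scores(aln)
            mask = np.full((L + 1, L + 1), NEG_INF)
            for i in range(L + 1):
                for j in range(i, L + 1):
                    if bad[j] - bad[i] == 0:
                        mask[i, j] = 0.0
            self.S[name] = m + mask


def _logsumexp(vals) -> float:
    arr = np.asarray([v for v in vals if v > NEG_INF], dtype=float)
    if arr.size == 0:
        return NEG_INF
    m = arr.max()
    return float(m + np.log(np.exp(arr - m).sum()))


def _rule_candidates(cr, chart, sc, i, j, use_max):
    """Score one compiled rule at span (i, j); returns a float or NEG_INF."""
    d = j - i
    kind = cr[0]
    if kind == "eps":
        return cr[1] if d == 0 else NEG_INF
    if kind == "term":
        return sc.E[cr[1]][i] + cr[2] if d == 1 else NEG_INF
    if kind == "hmm":
        return sc.S[cr[1]][i, j] + cr[2]
    if kind == "unary":
        return chart[cr[1]][i, j] + cr[2]
    if kind == "left":
        if d < 1:
            return NEG_INF
        return sc.E[cr[1]][i] + chart[cr[2]][i + 1, j] + cr[3]
    if kind == "right":
        if d < 1:
            return NEG_INF
        return chart[cr[1]][i, j - 1] + sc.E[cr[2]][j - 1] + cr[3]
    if kind == "pair":
        if d < 2:
            return NEG_INF
        return sc.P[cr[1]][i, j - 1] + chart[cr[2]][i + 1, j - 1] + cr[3]
    # split
    tot = chart[cr[1]][i, i:j + 1] + chart[cr[2]][i:j + 1, j]
    if tot.size == 0:
        return NEG_INF
    if use_max:
        m = float(tot.max())
        return m + cr[3] if m > NEG_INF else NEG_INF
    s = _logsumexp(tot)
    return s + cr[3] if s > NEG_INF else NEG_INF


def _run_chart(g: Grammar, aln: ProfileAlignment, cons: Constraints, mode: str):
    """Fill the chart bottom-up; mode is 'max' (CYK) or 'sum' (inside)."""
    cg = g.compiled()
    sc = _Scorer(g, aln, cons)
    L = sc.L
    chart = {s: np.full((L + 1, L + 1), NEG_INF) for s in cg.symbols}
    use_max = mode == "max"
    old_err = np.seterr(invalid="ignore")
    try:
        for d in range(L + 1):
            for i in range(L - d + 1):
                j = i + d
                for sym in cg.topo_order:
                    cands = [
                        _rule_candidates(cr, chart, sc, i, j, use_max)
                        for cr in cg.rules[sym]
                    ]
                    cands = [c for c in cands if c > NEG_INF]
                    if cands:
                        chart[sym][i, j] = max(cands) if use_max else _logsumexp(cands)
    finally:
        np.seterr(**old_err)
    return chart, sc, cg


def _traceback(chart, sc, cg, g: Grammar) -> ParseNode:
    """Deterministic traceback of the max chart into an original-rule tree.

    Ties break to the first rule in declaration order, then the smallest
    split point.
    """
    TOL = 1e-7

    def node_for(nt: str, i: int, j: int) -> ParseNode:
        node = ParseNode(nt=nt, rule_index=-1, span=(i, j))
        fill(nt, i, j, node, top=True)
        return node

    def fill(sym: str, i: int, j: int, node: ParseNode, top: bool = False):
        target = chart[sym][i, j]
        for cr in cg.rules[sym]:
            v = _rule_candidates(cr, chart, sc, i, j, True)
            if not (v > NEG_INF and abs(v - target) <= TOL + 1e-9 * abs(target)):
                continue
            if top:
                node.rule_index = cr[-1] if isinstance(cr[-1], int) else -1
            kind = cr[0]
            if kind == "eps":
                return
            if kind == "term":
                node.emits.append(i)
                return
            if kind == "hmm":
                node.segs.append((cr[1], i, j))
                return
            if kind == "unary":
                descend(cr[1], i, j, node)
                return
            if kind == "left":
                node.emits.append(i)
                descend(cr[2], i + 1, j, node)
                return
            if kind == "right":
                descend(cr[1], i, j - 1, node)
                node.emits.append(j - 1)
                return
            if kind == "pair":
                node.pair = (i, j - 1)
                descend(cr[2], i + 1, j - 1, node)
                return
            # split: smallest split point first
            for q in range(i, j + 1):
                lv = chart[cr[1]][i, q]
                rv = chart[cr[2]][q, j]
                if lv > NEG_INF and rv > NEG_INF and \
                        abs(lv + rv + cr[3] - target) <= TOL + 1e-9 * abs(target):
                    descend(cr[1], i, q, node)
                    descend(cr[2], q, j, node)
                    return
            continue
        raise R3DFoldError(
            f"traceback failed at {sym}[{i},{j}] (score {chart[sym][i, j]})")

    def descend(sym: str, i: int, j: int, node: ParseNode):
        if sym in g.rules:  # official nonterminal -> new child node
            node.children.append(node_for(sym, i, j))
        else:
            fill(sym, i, j, node)

    return node_for(g.start, 0, sc.L)


def cyk(g: Grammar, aln: ProfileAlignment, cons: Constraints | None = None):
    """Maximum-log-probability constrained derivation of the alignment.

    Returns (logprob, ParseTree); raises :class:`NoStructureError` when no
    finite-probability derivation satisfies the constraints.
    """
    cons = cons or Constraints()
    chart, sc, cg = _run_chart(g, aln, cons, "max")
    L = sc.L
    score = float(chart[g.start][0, L])
    if not score > NEG_INF:
        raise NoStructureError("no valid structure under the given constraints")
    tree = _traceback(chart, sc, cg, g)
    return score, tree


def inside(g: Grammar, aln: ProfileAlignment, cons: Constraints | None = None) -> float:
    """Log of the summed probability of all valid constrained derivations."""
    cons = cons or Constraints()
    chart, sc, _ = _run_chart(g, aln, cons, "sum")
    score = float(chart[g.start][0, sc.L])
    if not score > NEG_INF:
        raise NoStructureError("no valid structure under the given constraints")
    return score


def score_tree(g: Grammar, aln: ProfileAlignment, node: ParseNode) -> float:
    """Log-probability of one derivation subtree (rules + emissions).

    Emission scores are computed on demand, so scoring a small subtree of
    a large parse is cheap.
    """
    freq = aln.renormalized_freq()

    def emit_score(dist: str, c: int) -> float:
        d = g.dists[dist]
        if np.any((freq[c] > 1e-12) & (d <= 0)):
            return NEG_INF
        return float(freq[c] @ np.log(np.maximum(d, 1e-300)))

    def rec(n: ParseNode) -> float:
        r = g.rules[n.nt][n.rule_index]
        total = r.logp
        if r.pair is not None and n.pair is not None:
            t = g.pair_tables[r.pair]
            i, j = n.pair
            total += float(np.einsum("a,b,ab->", freq[i], freq[j],
                                     np.log(np.maximum(t, 1e-300))))
        emit_dists = [a[1] for a in r.atoms if a[0] == "emit"]
        for c in n.emits:
            total += emit_score(emit_dists[0], c)
        for (sname, a, b) in n.segs:
            total += g.segments[sname].score_span(aln, a, b - 1)
        for ch in n.children:
            total += rec(ch)
        return total

    return rec(node)


# ---------------------------------------------------------------------------
# brute-force oracle


def seq_to_profile(seq: str) -> ProfileAlignment:
    return compute_profiles(
        ProfileAlignment(seq_names=["seq"], seqs=[seq.upper().replace("T", "U")]),
        weighting="none",
    )


def enumerate_parses(g: Grammar, seq, max_len: int = 12):
    """Exhaustively enumerate all derivations of a short sequence.

    Independent oracle for ``cyk`` (max over parses) and ``inside``
    (logsumexp over parses).  ``seq`` may be a string or a profile
    alignment; the guard rejects inputs longer than ``max_len`` columns.
    """
    aln = seq_to_profile(seq) if isinstance(seq, str) else seq
    L = aln.n_cols
    if L > max_len:
        raise ContractError(f"enumeration limited to {max_len} columns")
    sc = _Scorer(g, aln, Constraints())
    in_progress: set = set()
    memo: dict = {}

    def derivs(nt: str, i: int, j: int):
        key = (nt, i, j)
        if key in memo:
            return memo[key]
        if key in in_progress:
            raise R3DFoldError("grammar admits unbounded same-span recursion")
        in_progress.add(key)
        out = []
        for ridx, r in enumerate(g.rules[nt]):
            if r.logp == NEG_INF:
                continue
            if r.pair is not None:
                if j - i < 2:
                    continue
                e = sc.P[r.pair][i, j - 1]
                if not e > NEG_INF:
                    continue
                for events, lp in atom_seqs(r.atoms, i + 1, j - 1):
                    node = ParseNode(nt=nt, rule_index=ridx, span=(i, j),
                                     pair=(i, j - 1))
                    _apply(node, events)
                    out.append((node, r.logp + e + lp))
            else:
                for events, lp in atom_seqs(r.atoms, i, j):
                    node = ParseNode(nt=nt, rule_index=ridx, span=(i, j))
                    _apply(node, events)
                    out.append((node, r.logp + lp))
        in_progress.discard(key)
        memo[key] = out
        return out

    def _apply(node: ParseNode, events):
        for ev in events:
            if ev[0] == "emit":
                node.emits.append(ev[1])
            elif ev[0] == "seg":
                node.segs.append((ev[1], ev[2], ev[3]))
            else:
                node.children.append(ev[1])

    def atom_seqs(atoms, i, j):
        if not atoms:
            if i == j:
                yield [], 0.0
            return
        a, rest = atoms[0], atoms[1:]
        rest_min = sum(1 for x in rest if x[0] == "emit")
        if a[0] == "emit":
            if j > i:
                e = sc.E[a[1]][i]
                if e > NEG_INF:
                    for events, lp in atom_seqs(rest, i + 1, j):
                        yield [("emit", i)] + events, e + lp
        elif a[0] == "seg":
            for q in range(i, j - rest_min + 1):
                e = sc.S[a[1]][i, q]
                if e > NEG_INF:
                    for events, lp in atom_seqs(rest, q, j):
                        yield [("seg", a[1], i, q)] + events, e + lp
        else:
            for q in range(i, j - rest_min + 1):
                for child, clp in derivs(a[1], i, q):
                    for events, lp in atom_seqs(rest, q, j):
                        yield [("child", child)] + events, clp + lp

    return [(node, lp) for node, lp in derivs(g.start, 0, L)]
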