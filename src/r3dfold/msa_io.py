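"""Alignment I/O and the column-profile representation parsed by the grammars.

An alignment is represented column-wise: each column carries a probability
vector over {A, C, G, U} plus a gap fraction, so the folding grammars can
score "probabilistic sequences" (alignment columns) instead of individual
residues.  Stockholm 1.0 is the native format (the Rfam seed format);
unaligned FASTA records become one-sequence alignments.

Coordinates are 0-based, closed pair indices internally; human-readable
reports use 1-based columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO

from .errors import ContractError, FormatError

RESIDUES = "ACGU"
RES_INDEX = {r: i for i, r in enumerate(RESIDUES)}
GAP_CHARS = ".-_~"

#: IUPAC nucleotide ambiguity codes mapped to the residue sets they denote.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

#: Fractional count vectors for every accepted residue letter.
_IUPAC_VEC = {
    code: np.array([1.0 / len(s) if r in s else 0.0 for r in RESIDUES])
    for code, s in IUPAC.items()
}

# WUSS unpaired/loop annotation characters (treated as unpaired on read).
_WUSS_UNPAIRED = set(".,:_-~")
_OPEN = {"<": ">", "(": ")", "[": "]", "{": "}"}
_CLOSE = {v: k for k, v in _OPEN.items()}


def canonicalize_residue(ch: str) -> str:
    """Uppercase, map T to U and any gap dialect character to '-'."""
    ch = ch.upper()
    if ch == "T":
        return "U"
    if ch in GAP_CHARS:
        return "-"
    return ch


@dataclass
class ProfileAlignment:
    """Aligned RNA sequences plus per-column residue frequency profiles.

    ``col_freq[c]`` sums with ``col_gapfrac[c]`` to 1; ambiguity codes are
    distributed fractionally over their residue sets when counting.
    """

    seq_names: list[str]
    seqs: list[str]
    weights: np.ndarray = None
    col_freq: np.ndarray = None      # (L, 4)
    col_gapfrac: np.ndarray = None   # (L,)

    def __post_init__(self):
        self.seqs = ["".join(canonicalize_residue(ch) for ch in s)
                     for s in self.seqs]
        if self.seqs:
            L = len(self.seqs[0])
            for name, s in zip(self.seq_names, self.seqs):
                if len(s) != L:
                    raise FormatError(
                        f"ragged alignment: sequence '{name}' has length "
                        f"{len(s)}, expected {L}"
                    )
            for name, s in zip(self.seq_names, self.seqs):
                for pos, ch in enumerate(s):
                    if ch != "-" and ch not in IUPAC:
                        raise FormatError(
                            f"non-IUPAC residue '{ch}' in sequence "
                            f"'{name}' at column {pos + 1}"
                        )
        if self.weights is None:
            self.weights = np.ones(len(self.seqs))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if self.col_freq is None:
            prof = compute_profiles(self, weighting="precomputed")
            self.col_freq = prof.col_freq
            self.col_gapfrac = prof.col_gapfrac

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def renormalized_freq(self) -> np.ndarray:
        """Per-column frequencies with gap mass removed (rows sum to 1).

        All-gap columns fall back to a uniform distribution.
        """
        resid = 1.0 - self.col_gapfrac
        out = np.full_like(self.col_freq, 0.25)
        ok = resid > 1e-12
        out[ok] = self.col_freq[ok] / resid[ok, None]
        return out


@dataclass
class ConsensusStructure:
    """Layered consensus base pairs with a WUSS string rendering.

    Layer 0 holds the nested secondary structure (angle brackets); layers
    >= 1 hold pseudoknotted / tertiary pairs annotated with Aa, Bb, ...
    """

    pairs_by_layer: list[set]
    n_cols: int

    def __post_init__(self):
        seen_layers = []
        for li, layer in enumerate(self.pairs_by_layer):
            used = set()
            pairs = sorted(layer)
            for (i, j) in pairs:
                if not (0 <= i < j < self.n_cols):
                    raise ContractError(f"pair ({i},{j}) out of range in layer {li}")
                if i in used or j in used:
                    raise ContractError(f"column reused within layer {li}")
                used.update((i, j))
            for a in range(len(pairs)):
                for b in range(a + 1, len(pairs)):
                    (i, j), (k, l) = pairs[a], pairs[b]
                    if i < k < j < l:
                        raise ContractError(
                            f"crossing pairs ({i},{j}) and ({k},{l}) in layer {li}"
                        )
            seen_layers.append(set(layer))
        # empty layers beyond layer 0 carry no information; normalize away
        self.pairs_by_layer = [seen_layers[0] if seen_layers else set()] + \
            [l for l in seen_layers[1:] if l]

    @property
    def all_pairs(self) -> set:
        out = set()
        for layer in self.pairs_by_layer:
            out |= layer
        return out

    @property
    def wuss(self) -> str:
        """Single-string rendering: layer 0 as angle brackets, layers >= 1
        as pseudoknot letters.

        A column taking part in pairs of two layers (a base triplet) cannot
        be drawn twice in one string; the later layer's pair is skipped,
        earliest layers taking precedence.  Round-tripping is lossless
        whenever layers are column-disjoint.
        """
        chars = ["."] * self.n_cols
        taken = set()
        for li, layer in enumerate(self.pairs_by_layer):
            if li == 0:
                op, cl = "<", ">"
            else:
                op = chr(ord("A") + li - 1)
                cl = op.lower()
            for (i, j) in sorted(layer):
                if i in taken or j in taken:
                    continue
                chars[i], chars[j] = op, cl
                taken.update((i, j))
        return "".join(chars)


def parse_wuss(wuss: str) -> ConsensusStructure:
    """Parse a WUSS/dot-bracket string into layered pair sets.

    All bracket types ``<>()[]{}`` land in layer 0 (they must be mutually
    nested); each pseudoknot letter Aa, Bb, ... opens its own layer.  Any
    other character is read as unpaired.
    """
    n = len(wuss)
    bracket_stacks: dict[str, list[int]] = {k: [] for k in _OPEN}
    letter_stacks: dict[str, list[int]] = {}
    layer0: set = set()
    letter_pairs: dict[str, set] = {}
    for pos, ch in enumerate(wuss):
        if ch in _OPEN:
            bracket_stacks[ch].append(pos)
        elif ch in _CLOSE:
            stack = bracket_stacks[_CLOSE[ch]]
            if not stack:
                raise FormatError(f"unbalanced '{ch}' at column {pos + 1}")
            layer0.add((stack.pop(), pos))
        elif ch.isalpha() and ch.isupper():
            letter_stacks.setdefault(ch, []).append(pos)
        elif ch.isalpha() and ch.islower():
            stack = letter_stacks.get(ch.upper(), [])
            if not stack:
                raise FormatError(f"unbalanced pseudoknot '{ch}' at column {pos + 1}")
            letter_pairs.setdefault(ch.upper(), set()).add((stack.pop(), pos))
    for br, stack in bracket_stacks.items():
        if stack:
            raise FormatError(f"unclosed '{br}' at column {stack[-1] + 1}")
    for letter, stack in letter_stacks.items():
        if stack:
            raise FormatError(f"unclosed pseudoknot '{letter}' at column {stack[-1] + 1}")
    layers = [layer0] + [letter_pairs[k] for k in sorted(letter_pairs)]
    while len(layers) > 1 and not layers[-1]:
        layers.pop()
    if len(layers) == 1 and not layers[0]:
        layers = [set()]
    return ConsensusStructure(pairs_by_layer=layers, n_cols=n)


# ---------------------------------------------------------------------------
# profiles and weighting


def henikoff_weights(seqs: list[str]) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff 1994).

    Each column distributes one unit of weight equally over the residue
    types it contains (gaps count as a type), then over the sequences
    carrying each type.  Weights are normalized to sum to the number of
    sequences.
    """
    S = len(seqs)
    L = len(seqs[0]) if seqs else 0
    w = np.zeros(S)
    for c in range(L):
        col = [s[c] for s in seqs]
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        for si, ch in enumerate(col):
            w[si] += 1.0 / (r * counts[ch])
    if w.sum() == 0:
        return np.ones(S)
    return w * (S / w.sum())


def compute_profiles(aln: ProfileAlignment, weighting: str = "henikoff") -> ProfileAlignment:
    """Recompute column frequency vectors under the chosen weighting.

    ``weighting`` is one of ``none`` (every sequence counts 1),
    ``henikoff`` (position-based weights), or ``precomputed`` (use the
    weights already stored on the alignment).
    """
    if weighting == "none":
        w = np.ones(aln.n_seqs)
    elif weighting == "henikoff":
        w = henikoff_weights(aln.seqs)
    elif weighting == "precomputed":
        w = np.asarray(aln.weights, dtype=float) if aln.weights is not None \
            else np.ones(aln.n_seqs)
    else:
        raise ContractError(f"unknown weighting '{weighting}'")
    L = aln.n_cols
    freq = np.zeros((L, 4))
    gapfrac = np.zeros(L)
    total = w.sum() if aln.n_seqs else 1.0
    for si, s in enumerate(aln.seqs):
        ws = w[si]
        for c, ch in enumerate(s):
            if ch == "-":
                gapfrac[c] += ws
            else:
                freq[c] += ws * _IUPAC_VEC[ch]
    if total > 0:
        freq /= total
        gapfrac /= total
    out = ProfileAlignment(
        seq_names=list(aln.seq_names), seqs=list(aln.seqs),
        weights=w, col_freq=freq, col_gapfrac=gapfrac,
    )
    return out


# ---------------------------------------------------------------------------
# Stockholm / FASTA reading


def _canonicalize_seqs(names, raws):
    seqs = []
    for name, raw in zip(names, raws):
        seqs.append("".join(canonicalize_residue(ch) for ch in raw))
    return seqs


def _scan_stockholm_lengths(text: str):
    """Best-effort raggedness diagnosis for a malformed Stockholm file."""
    lengths: dict[str, int] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line == "//":
            continue
        parts = line.split()
        if len(parts) == 2:
            lengths[parts[0]] = lengths.get(parts[0], 0) + len(parts[1])
    if lengths:
        expected = max(set(lengths.values()), key=list(lengths.values()).count)
        for name, ln in lengths.items():
            if ln != expected:
                return name, ln, expected
    return None


def read_stockholm(path) -> tuple[ProfileAlignment, ConsensusStructure | None]:
    """Read a Stockholm 1.0 alignment (single- or multi-block).

    Returns the alignment plus the consensus structure parsed from the
    ``#=GC SS_cons`` line when one is present (otherwise ``None``).
    """
    with open(path) as fh:
        text = fh.read()
    try:
        msa = AlignIO.read(io.StringIO(text), "stockholm")
    except ValueError as exc:
        diag = _scan_stockholm_lengths(text)
        if diag is not None:
            name, ln, expected = diag
            raise FormatError(
                f"ragged alignment: sequence '{name}' has length {ln}, "
                f"expected {expected}"
            ) from exc
        raise FormatError(f"not a valid Stockholm file: {exc}") from exc
    names = [rec.id for rec in msa]
    seqs = _canonicalize_seqs(names, [str(rec.seq) for rec in msa])
    aln = compute_profiles(
        ProfileAlignment(seq_names=names, seqs=seqs), weighting="henikoff"
    )
    cons = None
    ss = msa.column_annotations.get("secondary_structure")
    if ss:
        cons = parse_wuss(ss)
    return aln, cons


def read_fasta(path) -> ProfileAlignment:
    """Read FASTA records; equal-length records form an alignment."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no sequences in '{path}'")
    names = [rec.id for rec in records]
    seqs = _canonicalize_seqs(names, [str(rec.seq) for rec in records])
    return compute_profiles(
        ProfileAlignment(seq_names=names, seqs=seqs), weighting="henikoff"
    )


# ---------------------------------------------------------------------------
# Stockholm writing


def write_stockholm(aln: ProfileAlignment, result=None, path=None) -> str:
    """Write the alignment (and, when given, a fold result) as Stockholm.

    The consensus structure goes into ``#=GC SS_cons`` (layer 0 as angle
    brackets, layers >= 1 as pseudoknot letters).  Each placed motif adds a
    ``#=GC R3D_<k>`` line marking its segment columns, with the motif name
    recorded in a ``#=GF R3D_<k>`` legend line.
    """
    lines = ["# STOCKHOLM 1.0", ""]
    gc_lines = []
    if result is not None:
        structure = result.structure
        if structure.n_cols != aln.n_cols:
            raise ContractError(
                f"column-count mismatch: result has {structure.n_cols} columns, "
                f"alignment has {aln.n_cols}"
            )
        for k, pl in enumerate(result.motif_placements, start=1):
            lines.append(f"#=GF R3D_{k} {pl.motif} variant={pl.variant} "
                         f"support={'yes' if pl.support else 'no'}")
        gc_lines.append(("SS_cons", structure.wuss))
        for k, pl in enumerate(result.motif_placements, start=1):
            marks = ["."] * aln.n_cols
            for (_, a, b) in pl.segments:
                for c in range(a, b):
                    marks[c] = "*"
            gc_lines.append((f"R3D_{k}", "".join(marks)))
    width = max([len(n) for n in aln.seq_names] + [len("#=GC SS_cons")] + [12])
    for name, seq in zip(aln.seq_names, aln.seqs):
        lines.append(f"{name:<{width}} {seq}")
    for tag, val in gc_lines:
        label = f"#=GC {tag}"
        lines.append(f"{label:<{width}} {val}")
    lines.append("//")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
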