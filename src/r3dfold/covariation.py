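"""Pairwise covariation analysis of alignment columns.

Every eligible column pair is scored with APC-corrected mutual information
and classified as *positive* (significantly covarying, judged against an
empirical column-shuffle null), *negative* (variable enough that the absence
of covariation argues against pairing), or *neutral*.  Positive pairs later
seed the fold's helices; negative pairs are forbidden from pairing.

E-values follow the per-alignment convention: the E-value of a score is the
expected number of column pairs in one shuffled alignment scoring at least
as high.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, FormatError
from .msa_io import _IUPAC_VEC, ProfileAlignment

#: Columns with a gap fraction at or above this carry no pairing signal and
#: are excluded from scoring (never positive or negative).
MAX_GAP_FRACTION = 0.5


@dataclass
class CovariationConfig:
    evalue_threshold: float = 0.05
    n_null_shuffles: int = 200
    power_threshold: float = 0.95
    power_lambda: float = 0.5
    #: a pair is only called negative when its score is no better than what
    #: the null produces at least this often per alignment (variability with
    #: no covariation tendency at all)
    negative_evalue_floor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.evalue_threshold <= 0:
            raise ContractError("evalue_threshold must be > 0")
        if self.n_null_shuffles < 1:
            raise ContractError("n_null_shuffles must be >= 1")


@dataclass
class CovariationResult:
    pair: tuple
    score: float
    evalue: float
    power: float
    label: str  # positive | negative | neutral


def _onehot(aln: ProfileAlignment) -> np.ndarray:
    """Weighted fractional one-hot tensor of shape (S, L, 4); gaps are zero rows."""
    S, L = aln.n_seqs, aln.n_cols
    X = np.zeros((S, L, 4))
    for si, s in enumerate(aln.seqs):
        w = aln.weights[si]
        for c, ch in enumerate(s):
            if ch != "-":
                X[si, c] = w * _IUPAC_VEC[ch]
    return X


def _eligible_columns(aln: ProfileAlignment) -> np.ndarray:
    return aln.col_gapfrac < MAX_GAP_FRACTION


def _mi_matrix(X: np.ndarray) -> np.ndarray:
    """Weighted mutual information (bits) between all column pairs.

    Sequence rows where either column is gapped contribute nothing to that
    pair's joint counts; marginals are taken from the pair's own joint
    table so each pair's distribution is properly normalized.
    """
    J = np.einsum("sia,sjb->ijab", X, X)
    T = J.sum(axis=(2, 3))
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(T[..., None, None] > 0, J / np.maximum(T, 1e-300)[..., None, None], 0.0)
        Pa = P.sum(axis=3)   # (i, j, a)
        Pb = P.sum(axis=2)   # (i, j, b)
        denom = Pa[..., :, None] * Pb[..., None, :]
        ratio = np.where((P > 0) & (denom > 0), P / np.maximum(denom, 1e-300), 1.0)
        mi = (P * np.log2(ratio)).sum(axis=(2, 3))
    return mi


def _apc_correct(mi: np.ndarray, eligible: np.ndarray,
                 variable: np.ndarray | None = None) -> np.ndarray:
    """Average-product correction over the informative pair set.

    The background means are estimated from pairs of *variable* eligible
    columns only; a constant column has mutual information exactly zero
    with everything, and letting it dilute the background estimate would
    inflate the correction applied to the informative pairs.
    """
    if variable is None:
        variable = np.ones(mi.shape[0], dtype=bool)
    active = eligible & variable
    mask = np.outer(active, active)
    np.fill_diagonal(mask, False)
    if mask.sum() == 0:
        return mi.copy()
    masked = np.where(mask, mi, 0.0)
    counts = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        col_mean = np.where(counts > 0, masked.sum(axis=1) / np.maximum(counts, 1), 0.0)
    overall = masked.sum() / mask.sum()
    if overall <= 0:
        return mi.copy()
    apc = np.outer(col_mean, col_mean) / overall
    return mi - np.where(mask, apc, 0.0)


def _variable_columns(aln: ProfileAlignment) -> np.ndarray:
    return column_substitutions(aln) > 1e-9


def _corrected_scores(X: np.ndarray, eligible: np.ndarray,
                      variable: np.ndarray | None = None) -> np.ndarray:
    return _apc_correct(_mi_matrix(X), eligible, variable)


def pair_scores(aln: ProfileAlignment) -> dict:
    """APC-corrected mutual information for all eligible column pairs.

    Eligible pairs are those where both columns have gap fraction below
    0.5.  Requires at least two sequences.
    """
    if aln.n_seqs < 2:
        raise ContractError("covariation requires >=2 sequences")
    eligible = _eligible_columns(aln)
    scores = _corrected_scores(_onehot(aln), eligible, _variable_columns(aln))
    out = {}
    L = aln.n_cols
    for i in range(L):
        if not eligible[i]:
            continue
        for j in range(i + 1, L):
            if eligible[j]:
                out[(i, j)] = float(scores[i, j])
    return out


def _shuffle_columns(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute each column's rows independently (composition preserved)."""
    S = X.shape[0]
    out = np.empty_like(X)
    for c in range(X.shape[1]):
        out[:, c] = X[rng.permutation(S), c]
    return out


def null_scores(aln: ProfileAlignment, cfg: CovariationConfig) -> np.ndarray:
    """Pooled corrected scores from column-wise permutations of the alignment.

    Each of the ``cfg.n_null_shuffles`` permutations is seeded
    deterministically from ``cfg.seed``; the pooled scores of all eligible
    pairs are returned sorted descending.
    """
    X = _onehot(aln)
    eligible = _eligible_columns(aln)
    variable = _variable_columns(aln)  # unchanged by column shuffling
    idx = np.triu(np.outer(eligible, eligible), k=1)
    pooled = []
    for t in range(cfg.n_null_shuffles):
        rng = np.random.default_rng([cfg.seed, t])
        Xs = _shuffle_columns(X, rng)
        pooled.append(_corrected_scores(Xs, eligible, variable)[idx])
    if not pooled:
        return np.array([])
    return np.sort(np.concatenate(pooled))[::-1]


def column_substitutions(aln: ProfileAlignment) -> np.ndarray:
    """Weighted minority-residue count per column (a substitution proxy)."""
    total = aln.weights.sum()
    counts = aln.col_freq * total              # weighted residue counts
    resid = counts.sum(axis=1)
    return resid - counts.max(axis=1, initial=0.0)


def classify_pairs(aln: ProfileAlignment, cfg: CovariationConfig | None = None) -> list[CovariationResult]:
    """Score, assign empirical E-values and label all eligible column pairs.

    E-value = (# pooled null scores >= score) / n_null_shuffles, i.e. the
    expected per-alignment count of null pairs at or above the score.
    Power is a calibrated proxy, 1 - exp(-lambda * min(subs_i, subs_j)),
    standing in for covariation power: a pair is labelled negative only
    when both columns vary enough that covariation would have been seen.
    """
    cfg = cfg or CovariationConfig()
    scores = pair_scores(aln)
    null = null_scores(aln, cfg)
    subs = column_substitutions(aln)
    results = []
    for (i, j), sc in sorted(scores.items()):
        n_ge = int(np.searchsorted(-null, -sc, side="right")) if null.size else 0
        evalue = n_ge / cfg.n_null_shuffles
        power = 1.0 - float(np.exp(-cfg.power_lambda * min(subs[i], subs[j])))
        if evalue <= cfg.evalue_threshold:
            label = "positive"
        elif power >= cfg.power_threshold and evalue >= cfg.negative_evalue_floor:
            label = "negative"
        else:
            label = "neutral"
        results.append(CovariationResult((i, j), float(sc), evalue, power, label))
    return results


def load_external_pairs(path, n_cols: int) -> list[CovariationResult]:
    """Load an externally supplied pair list (1-based: ``i j label [evalue]``).

    This substitutes for the built-in covariation stage when a dedicated
    covariation analysis has already been run on the alignment.
    """
    results = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise FormatError(f"line {ln}: expected 'i j label [evalue]'")
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise FormatError(f"line {ln}: non-integer column index") from exc
            if i >= j:
                raise FormatError(f"line {ln}: require i < j, got {i} >= {j}")
            if not (1 <= i <= n_cols and 1 <= j <= n_cols):
                raise FormatError(f"line {ln}: column out of range 1..{n_cols}")
            label = parts[2].lower()
            if label not in ("positive", "negative", "neutral"):
                raise FormatError(f"line {ln}: unknown label '{parts[2]}'")
            evalue = float(parts[3]) if len(parts) == 4 else float("nan")
            results.append(CovariationResult((i - 1, j - 1), float("nan"), evalue,
                                             float("nan"), label))
    return results


def expected_null_count(n_items: int, evalue_threshold: float) -> float:
    """Expected number of false covariation calls among ``n_items`` tests.

    At an E-value cutoff ``e``, each tested unit (pair, or helix with at
    least one covarying pair) is expected to pass by chance ``e`` times per
    alignment; over ``n_items`` units the null expectation is their product.
    """
    return n_items * evalue_threshold


def report_table(results: list[CovariationResult]):
    """Pair classification as a pandas DataFrame (1-based columns)."""
    import pandas as pd

    rows = [
        {
            "i": r.pair[0] + 1,
            "j": r.pair[1] + 1,
            "score": r.score,
            "evalue": r.evalue,
            "power": r.power,
            "label": r.label,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["i", "j", "score", "evalue", "power", "label"])
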