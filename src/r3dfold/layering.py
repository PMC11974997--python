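"""Decompose covarying pairs into ordered layers of mutually nested pairs.

Layer 0 is a maximum-cardinality nested subset of the positive pairs
(the main secondary structure); remaining pairs cascade into further
layers (pseudoknots, triplets and other tertiary contacts), each again a
maximum nested subset of what is left.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ContractError


@dataclass
class LayerDecomposition:
    layers: list[set]
    layer_of_pair: dict

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def _max_nested_subset(pairs: set) -> list:
    """Maximum-cardinality mutually nested subset via Nussinov-style DP.

    Each input pair has weight 1; a column may be used at most once within
    the subset.  Ties are broken so the chosen subset is lexicographically
    smallest by its sorted pair list: at each interval the leftmost column
    pairs whenever some maximum subset pairs it, with the smallest
    admissible partner.
    """
    if not pairs:
        return []
    cols = sorted({c for p in pairs for c in p})
    # compress to the participating columns only; nesting is preserved
    rank = {c: k for k, c in enumerate(cols)}
    n = len(cols)
    partners = [[] for _ in range(n)]
    for (i, j) in pairs:
        partners[rank[i]].append(rank[j])
    for lst in partners:
        lst.sort()

    import functools

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if i >= j:
            return 0
        # i unpaired
        score = best(i + 1, j)
        for k in partners[i]:
            if k > j:
                break
            cand = 1 + best(i + 1, k - 1) + best(k + 1, j)
            if cand > score:
                score = cand
        return score

    def trace(i: int, j: int, out: list):
        while i <= j:
            if i == j:
                return
            target = best(i, j)
            chosen = None
            for k in partners[i]:
                if k > j:
                    break
                if 1 + best(i + 1, k - 1) + best(k + 1, j) == target:
                    chosen = k
                    break
            if chosen is None:
                i += 1
                continue
            out.append((cols[i], cols[chosen]))
            trace(i + 1, chosen - 1, out)
            i = chosen + 1

    out: list = []
    trace(0, n - 1, out)
    best.cache_clear()
    return sorted(out)


def decompose_layers(positives: set) -> LayerDecomposition:
    """Greedy cascade of maximum nested subsets until all pairs are used.

    A column appearing in several input pairs (triplets / base multiplets)
    lands in several layers, one pair per layer.
    """
    for (i, j) in positives:
        if i >= j:
            raise ContractError(f"pair ({i},{j}) must satisfy i < j")
    remaining = set(positives)
    layers: list[set] = []
    layer_of: dict = {}
    while remaining:
        layer = set(_max_nested_subset(remaining))
        if not layer:  # pragma: no cover - a single pair is always nested
            raise AssertionError("empty layer from non-empty pair set")
        for p in layer:
            layer_of[p] = len(layers)
        layers.append(layer)
        remaining -= layer
    return LayerDecomposition(layers=layers, layer_of_pair=layer_of)


def brute_force_max_nested(pairs: set) -> int:
    """Exhaustive maximum nested subset size (test oracle; <= ~14 pairs)."""
    plist = sorted(pairs)
    if len(plist) > 16:
        raise ContractError("brute-force oracle limited to 16 pairs")

    def compatible(a, b):
        (i, j), (k, l) = sorted((a, b))
        if len({i, j, k, l}) < 4:
            return False
        return (k > j) or (k > i and l < j)

    best = 0
    n = len(plist)
    for mask in range(1 << n):
        subset = [plist[t] for t in range(n) if mask >> t & 1]
        ok = all(
            compatible(subset[a], subset[b])
            for a in range(len(subset))
            for b in range(a + 1, len(subset))
        )
        if ok:
            best = max(best, len(subset))
    return best
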