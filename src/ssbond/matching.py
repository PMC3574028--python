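"""Pattern-space combinatorics and maximum-weight matching extraction.

The number of valid connectivity patterns with exactly B bridges among n
cysteines is C(n, 2B) * (2B-1)!!  -- choose which cysteines are bonded, then
count the perfect pairings among them.  Summing over B (including B = 0, the
bridge-free case) gives the full pattern-space size.

Pattern extraction maximizes the pattern weight -- the sum of the bonding
probabilities of its bonds -- over perfect matchings of the cysteine graph.
For an odd number of cysteines, the matching is run on each of the n subsets
of n-1 cysteines and the best solution kept.  Ties between co-optimal
patterns are broken toward the lexicographically smallest bond set.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .core import Bond, BondingProbabilityMatrix, DisulfidePattern

ENUMERATION_GUARD = 12
EXHAUSTIVE_GUARD = 10
#: above this cysteine count, switch from the exact DP to blossom matching
_DP_MAX_N = 14


def double_factorial(m: int) -> int:
    """(m)!! for odd m >= -1; (-1)!! == 1 by convention."""
    result = 1
    while m > 1:
        result *= m
        m -= 2
    return result


def count_patterns(n: int, B: int) -> int:
    """Number of valid patterns with exactly ``B`` bridges among ``n`` cysteines."""
    if n < 0 or B < 0:
        raise ValueError("n and B must be non-negative")
    if 2 * B > n:
        return 0
    return comb(n, 2 * B) * double_factorial(2 * B - 1)


def count_all_patterns(n: int) -> int:
    """Total number of valid patterns among ``n`` cysteines (any bridge count)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return sum(count_patterns(n, B) for B in range(n // 2 + 1))


def _pairings(indices: Tuple[int, ...]) -> List[Tuple[Bond, ...]]:
    """All perfect pairings of ``indices``, lowest index matched first."""
    if not indices:
        return [()]
    first, rest = indices[0], indices[1:]
    out = []
    for i, partner in enumerate(rest):
        bond = (first, partner)
        remaining = rest[:i] + rest[i + 1:]
        for tail in _pairings(remaining):
            out.append((bond,) + tail)
    return out


def enumerate_patterns(n: int, B: int) -> List[DisulfidePattern]:
    """All valid patterns with exactly ``B`` bridges, in lexicographic order."""
    if n > ENUMERATION_GUARD:
        raise ValueError(f"enumeration is guarded to n <= {ENUMERATION_GUARD}")
    if 2 * B > n:
        return []
    from itertools import combinations

    patterns = []
    for subset in combinations(range(n), 2 * B):
        for pairing in _pairings(subset):
            patterns.append(tuple(sorted(pairing)))
    return [DisulfidePattern(bonds) for bonds in sorted(patterns)]


@dataclass
class PatternSearchResult:
    pattern: DisulfidePattern
    weight: float
    excluded_cysteine: Optional[int] = None


def pattern_weight(pattern: DisulfidePattern, probs: BondingProbabilityMatrix) -> float:
    """Sum of the probabilities attached to the pattern's bonds (in bond order)."""
    total = 0.0
    for a, b in pattern.sorted_bonds():
        total += probs.probs[a, b]
    return total


def _dp_perfect_matching(
    weights: np.ndarray, nodes: Tuple[int, ...]
) -> Tuple[Bond, ...]:
    """Exact max-weight perfect matching on an even node set, lex tie-break.

    Matches the lowest unmatched node first and prefers the smallest partner
    among co-optimal choices, which yields the lexicographically smallest
    optimal bond set.
    """
    index_of = {node: i for i, node in enumerate(nodes)}
    full_mask = (1 << len(nodes)) - 1

    @lru_cache(maxsize=None)
    def best(mask: int) -> Tuple[float, Tuple[Bond, ...]]:
        if mask == full_mask:
            return 0.0, ()
        first = next(i for i in range(len(nodes)) if not mask & (1 << i))
        best_weight = -np.inf
        best_bonds: Tuple[Bond, ...] = ()
        for j in range(first + 1, len(nodes)):
            if mask & (1 << j):
                continue
            w = weights[nodes[first], nodes[j]]
            sub_weight, sub_bonds = best(mask | (1 << first) | (1 << j))
            total = w + sub_weight
            if total > best_weight:  # strict: first (smallest j) wins ties
                best_weight = total
                best_bonds = ((nodes[first], nodes[j]),) + sub_bonds
        return best_weight, best_bonds

    _, bonds = best(0)
    best.cache_clear()
    return bonds


def _blossom_perfect_matching(
    weights: np.ndarray, nodes: Tuple[int, ...]
) -> Tuple[Bond, ...]:
    """Max-weight perfect matching via blossom; lex tie-break by refinement.

    networkx's ``max_weight_matching(maxcardinality=True)`` gives an optimal
    perfect matching but no tie-break guarantee, so the optimum weight is
    refined greedily: fix, for the lowest unmatched node, the smallest partner
    that still permits the optimal total.
    """
    def optimum(node_list: Sequence[int]) -> float:
        graph = nx.Graph()
        graph.add_nodes_from(node_list)
        for i, a in enumerate(node_list):
            for b in node_list[i + 1:]:
                graph.add_edge(a, b, weight=float(weights[a, b]))
        matching = nx.max_weight_matching(graph, maxcardinality=True)
        return sum(float(weights[min(a, b), max(a, b)]) for a, b in matching)

    tol = 1e-9
    remaining = list(nodes)
    bonds: List[Bond] = []
    target = optimum(remaining)
    while remaining:
        first = remaining[0]
        for partner in remaining[1:]:
            rest = [v for v in remaining if v not in (first, partner)]
            sub = optimum(rest) if rest else 0.0
            if weights[first, partner] + sub >= target - tol:
                bonds.append((first, partner))
                remaining = rest
                target = sub
                break
        else:  # numerically should not happen on a complete graph
            raise RuntimeError("failed to refine a perfect matching")
    return tuple(bonds)


def _best_perfect_matching(
    weights: np.ndarray, nodes: Tuple[int, ...]
) -> Tuple[Bond, ...]:
    if len(nodes) <= _DP_MAX_N:
        return _dp_perfect_matching(weights, nodes)
    return _blossom_perfect_matching(weights, nodes)


def max_weight_pattern(probs: BondingProbabilityMatrix) -> PatternSearchResult:
    """Extract the valid pattern with maximal weight.

    Even n: maximum-weight perfect matching over all cysteines.  Odd n: the
    matching is run on each of the n subsets of n-1 cysteines (excluded
    cysteine in ascending order, first optimum kept).  n < 2 yields the empty
    pattern.
    """
    n = probs.n
    if n < 2:
        return PatternSearchResult(DisulfidePattern(), 0.0)
    weights = probs.probs
    if n % 2 == 0:
        bonds = _best_perfect_matching(weights, tuple(range(n)))
        pattern = DisulfidePattern(bonds)
        return PatternSearchResult(pattern, pattern_weight(pattern, probs))
    best: Optional[PatternSearchResult] = None
    for excluded in range(n):
        nodes = tuple(i for i in range(n) if i != excluded)
        pattern = DisulfidePattern(_best_perfect_matching(weights, nodes))
        weight = pattern_weight(pattern, probs)
        better = best is None or weight > best.weight or (
            weight == best.weight
            and pattern.sorted_bonds() < best.pattern.sorted_bonds()
        )
        if better:
            best = PatternSearchResult(pattern, weight, excluded_cysteine=excluded)
    return best


def exhaustive_best_pattern(probs: BondingProbabilityMatrix) -> PatternSearchResult:
    """Exhaustive-search oracle over the same admissible space.

    Enumerates every full pattern (B = floor(n/2) bonds) in lexicographic
    order and keeps the first pattern of maximal weight, which implements the
    lexicographically-smallest tie-break by construction.
    """
    n = probs.n
    if n > EXHAUSTIVE_GUARD:
        raise ValueError(f"exhaustive search is guarded to n <= {EXHAUSTIVE_GUARD}")
    if n < 2:
        return PatternSearchResult(DisulfidePattern(), 0.0)
    best_pattern = None
    best_weight = -np.inf
    for pattern in enumerate_patterns(n, n // 2):
        weight = pattern_weight(pattern, probs)
        if weight > best_weight:
            best_weight = weight
            best_pattern = pattern
    excluded = None
    if n % 2 == 1:
        (excluded,) = set(range(n)) - best_pattern.bonded_indices
    return PatternSearchResult(best_pattern, best_weight, excluded_cysteine=excluded)
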