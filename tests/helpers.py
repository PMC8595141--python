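"""Independent brute-force oracles used across the test suite.

These deliberately re-derive quantities by direct enumeration or a full
walk, sharing no code with the implementation paths they check.
"""

from __future__ import annotations

from itertools import combinations

from gmpnet.expression import RankedList


def es_brute_force(ranked: RankedList, module: set[str], weight_exp: float) -> float:
    """Full O(N) running-sum walk; returns the signed maximal deviation."""
    hits = set(module) & set(ranked.genes)
    n = len(ranked)
    m = len(hits)
    total_w = sum(abs(s) ** weight_exp for g, s in zip(ranked.genes, ranked.scores) if g in hits)
    running = 0.0
    best = 0.0
    for g, s in zip(ranked.genes, ranked.scores):
        if g in hits:
            if total_w > 0:
                running += abs(s) ** weight_exp / total_w
            else:
                running += 1.0 / m
        else:
            running -= 1.0 / (n - m)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


def hypergeom_tail_enumeration(k: int, big_k: int, n: int, big_n: int) -> float:
    """P(X >= k) by exhaustive enumeration of all size-n draws from N items."""
    universe = list(range(big_n))
    marked = set(range(big_k))
    hits = 0
    total = 0
    for draw in combinations(universe, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def bh_by_hand(pvalues: list[float]) -> list[float]:
    """Textbook BH step-up: q_(i) = min over j>=i of m*p_(j)/j, capped at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, m * pvalues[i] / (rank_from_top + 1))
        q[i] = min(running_min, 1.0)
    return q
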