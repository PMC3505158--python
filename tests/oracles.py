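"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they validate: link counting by
explicit edge enumeration, assortativity by building the endpoint-degree
table, the log-odds z from its textbook definition, and the sequential
randomizer's exact output distribution by recursion over its choice tree.
"""

from __future__ import annotations

import math
from collections import defaultdict
from fractions import Fraction
from typing import Dict, FrozenSet, Iterable, Sequence, Set, Tuple


def count_links_bruteforce(
    edges: Iterable[Tuple[str, str]], A: Set[str], F: Set[str]
) -> int:
    n = 0
    for u, v in edges:
        if (u in A and v in F) or (u in F and v in A):
            n += 1
    return n


def assortativity_bruteforce(edges: Sequence[Tuple[str, str]]) -> float:
    """Pearson correlation from the explicit 2|E|-row endpoint-degree table."""
    deg: Dict[str, int] = defaultdict(int)
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    xs, ys = [], []
    for u, v in edges:
        xs += [deg[u], deg[v]]
        ys += [deg[v], deg[u]]
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / math.sqrt(sxx * syy)


def log_odds_z(a: float, b: float, c: float, d: float) -> float:
    """Textbook log odds-ratio z with 0.5 substitution for zero cells."""
    a = a or 0.5
    b = b or 0.5
    c = c or 0.5
    d = d or 0.5
    return math.log((a * d) / (b * c)) / math.sqrt(
        1 / a + 1 / b + 1 / c + 1 / d
    )


def sequential_exact_distribution(
    degrees: Sequence[int],
) -> Dict[FrozenSet[Tuple[int, int]], Fraction]:
    """Exact output distribution of the sequential weighted randomizer.

    Recursion over every choice path: uniform tie-break among maximal
    residual-degree nodes, then successive neighbor draws proportional to
    residual degrees without replacement.  Dead-end paths are dropped and
    the distribution renormalized, matching restart-from-scratch semantics.
    Feasible up to ~6 nodes.
    """
    dist: Dict[FrozenSet[Tuple[int, int]], Fraction] = defaultdict(Fraction)

    def neighbor_sets(res: Dict[int, int], cand: Sequence[int], d1: int):
        out: Dict[FrozenSet[int], Fraction] = defaultdict(Fraction)

        def rec(remaining: Set[int], chosen: Tuple[int, ...], prob: Fraction):
            if len(chosen) == d1:
                out[frozenset(chosen)] += prob
                return
            tot = sum(res[j] for j in remaining)
            for j in list(remaining):
                rec(remaining - {j}, chosen + (j,), prob * Fraction(res[j], tot))

        rec(set(cand), (), Fraction(1))
        return out

    def rec_state(res: Dict[int, int], edges: FrozenSet, prob: Fraction):
        mx = max(res.values(), default=0)
        if mx == 0:
            dist[edges] += prob
            return
        top = [i for i, d in res.items() if d == mx]
        for i in top:
            p_i = prob * Fraction(1, len(top))
            d1 = res[i]
            res2 = {j: d for j, d in res.items() if j != i}
            cand = [j for j, d in res2.items() if d > 0]
            if len(cand) < d1:
                continue  # dead end
            for S, pS in neighbor_sets(res2, cand, d1).items():
                res3 = dict(res2)
                for j in S:
                    res3[j] -= 1
                new_edges = edges | {tuple(sorted((i, j))) for j in S}
                rec_state(res3, frozenset(new_edges), p_i * pS)

    rec_state({i: d for i, d in enumerate(degrees)}, frozenset(), Fraction(1))
    total = sum(dist.values())
    return {g: p / total for g, p in dist.items()}
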