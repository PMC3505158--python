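"""Degree-preserving network randomization.

Three samplers over simple graphs with a fixed degree sequence:

``randomize_sequential``
    Fast sequential construction.  Nodes are processed from largest residual
    degree down; the current node's links are assigned to the remaining
    nodes with probability proportional to their residual degrees, drawn
    without replacement.  Each node is visited at most once, so a single
    randomization is linear in the number of links.

``randomize_edge_swap``
    Classic pairwise rewiring (A-B, C-D -> A-D, B-C), aborting proposals
    that would create a duplicate edge or self-loop.

``sample_uniform_rejection``
    The naive rejection sampler: every node independently picks its
    neighbors uniformly; the draw is accepted only when the resulting graph
    realizes the requested degree sequence.  Accepted graphs are exactly
    uniform over all simple graphs with that degree sequence, which makes
    this the reference oracle for the fast samplers on tiny instances.

``null_ensemble`` streams link-count curves n*_AF(k) over B randomized
networks, the Monte-Carlo null used by the enrichment statistics.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .network import Network, RankedGeneList, count_links, naf_curve

logger = logging.getLogger(__name__)

__all__ = [
    "DegreeSequence",
    "NullEnsemble",
    "RandomizationError",
    "randomize_sequential",
    "randomize_edge_swap",
    "sample_uniform_rejection",
    "null_ensemble",
    "is_graphical",
    "graphical_sequences",
    "enumerate_labeled_graphs",
    "replicate_rng",
]


class RandomizationError(RuntimeError):
    """Randomization could not produce a valid network."""


@dataclass(frozen=True)
class DegreeSequence:
    """Nodes with strictly positive degrees, ordered nonincreasing by degree."""

    pairs: Tuple[Tuple[str, int], ...]

    def __init__(self, pairs: Iterable[Tuple[str, int]]) -> None:
        pairs = tuple(sorted(pairs, key=lambda p: (-p[1], p[0])))
        degs = [d for _, d in pairs]
        if any(d <= 0 for d in degs):
            raise ValueError("degrees must be strictly positive")
        if sum(degs) % 2 != 0:
            raise ValueError("degree sum must be even")
        object.__setattr__(self, "pairs", pairs)

    @classmethod
    def from_degrees(cls, degrees: Sequence[int]) -> "DegreeSequence":
        return cls([(f"n{i}", d) for i, d in enumerate(degrees)])

    @classmethod
    def from_network(cls, net: Network) -> "DegreeSequence":
        return cls([(n, d) for n, d in net.degrees.items() if d > 0])

    @property
    def nodes(self) -> List[str]:
        return [n for n, _ in self.pairs]

    @property
    def degrees(self) -> List[int]:
        return [d for _, d in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)


def is_graphical(degrees: Sequence[int]) -> bool:
    """Erdős–Gallai test for a nonincreasing positive degree sequence."""
    d = sorted(degrees, reverse=True)
    n = len(d)
    if n == 0:
        return True
    if sum(d) % 2 != 0 or d[0] >= n:
        return False
    prefix = np.cumsum(d)
    for k in range(1, n + 1):
        rhs = k * (k - 1) + sum(min(di, k) for di in d[k:])
        if prefix[k - 1] > rhs:
            return False
    return True


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate generator derived from a master seed."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, replicate]))


# -- sequential weighted sampler --------------------------------------------

def _sequential_edges(
    deg: np.ndarray, rng: np.random.Generator
) -> List[Tuple[int, int]] | None:
    """One attempt at the sequential construction; None signals a dead end.

    Weighted sampling without replacement uses exponential keys
    (smallest ``Exp(1)/w`` first), which is distributionally identical to
    drawing the neighbors one at a time proportionally to residual degrees.
    """
    n = deg.shape[0]
    res = deg.astype(np.int64).copy()
    # equal residual degrees are ordered by a permutation drawn once per run
    prio = rng.permutation(n)
    key_base = np.int64(n)
    edges: List[Tuple[int, int]] = []
    while True:
        i = int(np.argmax(res * key_base + prio))
        d1 = int(res[i])
        if d1 == 0:
            return edges
        res[i] = 0
        cand = np.nonzero(res > 0)[0]
        if cand.shape[0] < d1:
            return None  # infeasible residual state: restart from scratch
        keys = rng.exponential(size=cand.shape[0]) / res[cand]
        if d1 < cand.shape[0]:
            pick = cand[np.argpartition(keys, d1 - 1)[:d1]]
        else:
            pick = cand
        res[pick] -= 1
        edges.extend((i, int(j)) for j in pick)


def randomize_sequential(
    net: Network, seed: int | np.random.Generator, max_restarts: int = 1000
) -> Network:
    """Degree-preserving randomization by sequential weighted assignment.

    Returns a simple graph in which every node keeps its original degree.
    A dead end (a node left with positive residual degree but no eligible
    partners) triggers a restart with a fresh random stream; after
    ``max_restarts`` failures a :class:`RandomizationError` is raised,
    signalling a pathological degree sequence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = [n for n, d in net.degrees.items() if d > 0]
    isolated = [n for n, d in net.degrees.items() if d == 0]
    if not nodes:
        return net.copy()
    deg = np.array([net.degree(n) for n in nodes], dtype=np.int64)
    for _ in range(max_restarts):
        edges = _sequential_edges(deg, rng)
        if edges is not None:
            return Network(
                ((nodes[i], nodes[j]) for i, j in edges), nodes=isolated
            )
    raise RandomizationError(
        f"sequential randomization failed after {max_restarts} restarts; "
        "degree sequence may be pathological"
    )


# -- edge-swap rewiring ------------------------------------------------------

def randomize_edge_swap(
    net: Network, n_swaps: int, seed: int | np.random.Generator
) -> Network:
    """Degree-preserving randomization by repeated pairwise edge rewiring.

    ``n_swaps`` counts proposals (attempts); a proposal picks two distinct
    edges A-B and C-D uniformly, rewires them to A-D and B-C, and is aborted
    when the two edges share a node or either new link already exists.
    Attempted and accepted counts are logged.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edge_list = sorted(net.edges())
    edge_set = set(edge_list)
    m = len(edge_list)
    if n_swaps > 0 and m < 2:
        raise ValueError("edge swapping requires at least 2 edges")
    accepted = 0
    for _ in range(n_swaps):
        i, j = rng.choice(m, size=2, replace=False)
        a, b = edge_list[i]
        c, d = edge_list[j]
        if rng.random() < 0.5:
            a, b = b, a
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue  # shared node: rewiring would create a self-loop
        e1 = (a, d) if a < d else (d, a)
        e2 = (b, c) if b < c else (c, b)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.remove(edge_list[i])
        edge_set.remove(edge_list[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edge_list[i] = e1
        edge_list[j] = e2
        accepted += 1
    logger.info("edge swap: %d attempted, %d accepted", n_swaps, accepted)
    isolated = [n for n, dg in net.degrees.items() if dg == 0]
    return Network(edge_set, nodes=isolated)


# -- naive rejection sampler (oracle) ----------------------------------------

def sample_uniform_rejection(
    dseq: DegreeSequence, seed: int | np.random.Generator, max_tries: int = 1_000_000
) -> Network:
    """Exactly-uniform sample over simple graphs with the given degree sequence.

    Every node independently picks its neighbors uniformly without
    replacement; the draw is accepted only when the union graph realizes the
    requested degrees (equivalently, all choices are mutual).  An accepted
    graph arises from exactly one choice profile and all profiles are
    equiprobable, so accepted graphs are uniform by construction.  Intended
    as a small-instance test oracle: acceptance probability decays
    explosively with size.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = dseq.nodes
    degs = np.asarray(dseq.degrees, dtype=np.int64)
    n = len(nodes)
    if n == 0:
        return Network()
    if degs.max() >= n:
        raise ValueError("degree sequence not graphical: max degree >= n")
    idx = np.arange(n)
    for _ in range(max_tries):
        chosen = []
        for i in range(n):
            others = np.delete(idx, i)
            picks = rng.choice(others, size=degs[i], replace=False)
            chosen.append(set(int(p) for p in picks))
        # accepted iff choices are mutual: i in S_j  <=>  j in S_i
        ok = all(
            all(i in chosen[j] for j in chosen[i]) for i in range(n)
        )
        if ok:
            edges = [(nodes[i], nodes[j]) for i in range(n) for j in chosen[i] if i < j]
            return Network(edges)
    raise RandomizationError(
        f"rejection sampler exhausted {max_tries} tries; instance too large"
    )


# -- exhaustive enumeration (oracle support) ---------------------------------

def graphical_sequences(n_max: int) -> List[Tuple[int, ...]]:
    """All graphical, strictly positive, nonincreasing degree sequences on
    2..n_max labeled nodes."""
    out: List[Tuple[int, ...]] = []
    for n in range(2, n_max + 1):
        for seq in itertools.combinations_with_replacement(range(n - 1, 0, -1), n):
            if sum(seq) % 2 == 0 and is_graphical(seq):
                out.append(seq)
    return out


def enumerate_labeled_graphs(degrees: Sequence[int]) -> List[frozenset]:
    """All labeled simple graphs (as frozensets of index pairs) realizing
    ``degrees`` on nodes 0..n-1.  Exhaustive over all edge subsets; n <= 8."""
    n = len(degrees)
    if n > 8:
        raise ValueError("enumeration limited to n <= 8")
    possible = list(itertools.combinations(range(n), 2))
    m = len(possible)
    target = np.asarray(degrees, dtype=np.int64)
    # incidence matrix: possible edges x nodes
    inc = np.zeros((m, n), dtype=np.int64)
    for e, (u, v) in enumerate(possible):
        inc[e, u] = 1
        inc[e, v] = 1
    masks = np.arange(2 ** m, dtype=np.uint64)
    bits = ((masks[:, None] >> np.arange(m, dtype=np.uint64)) & 1).astype(np.int64)
    degs = bits @ inc
    match = np.nonzero((degs == target).all(axis=1))[0]
    out = []
    for k in match:
        out.append(frozenset(possible[e] for e in range(m) if bits[k, e]))
    return out


# -- null ensembles -----------------------------------------------------------

@dataclass
class NullEnsemble:
    """Link-count curves n*_AF(k) from B degree-preserving randomizations."""

    curves: np.ndarray  # shape (B, k_max) or (B,) when k is fixed
    seed: int

    @property
    def B(self) -> int:
        return self.curves.shape[0]

    def mean_curve(self) -> np.ndarray:
        """Estimated expected link count μ̂_AF(k), averaged over replicates."""
        return self.curves.mean(axis=0)


def null_ensemble(
    net: Network,
    ags: RankedGeneList,
    F: Iterable[str],
    k_max: int,
    B: int,
    seed: int,
    fixed_k: bool = False,
) -> NullEnsemble:
    """Null link-count statistics over B sequentially randomized networks.

    With ``fixed_k=True`` only the scalar count at ``k_max`` is recorded per
    replicate (curves has shape (B,)); otherwise the full curve for
    k = 1..k_max.  Replicate b draws its generator deterministically from
    ``(seed, b)``, so results are reproducible and independent of B.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    F = set(F)
    if fixed_k:
        curves = np.empty(B, dtype=np.int64)
    else:
        curves = np.empty((B, k_max), dtype=np.int64)
    for b in range(B):
        rnd = randomize_sequential(net, replicate_rng(seed, b))
        if fixed_k:
            curves[b] = count_links(rnd, ags.prefix(k_max), F)
        else:
            curves[b] = naf_curve(rnd, ags, F, k_max)
    return NullEnsemble(curves=curves, seed=seed)
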