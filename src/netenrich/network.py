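"""Background gene network: data model, I/O, link counting and descriptive statistics.

The network is a simple undirected graph over gene symbols (binary symmetric
adjacency): no self-loops, no duplicate edges, no edge weights.  Gene
identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Sequence, Set, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "GeneSet",
    "RankedGeneList",
    "NetworkParseError",
    "AssortativityUndefinedError",
    "load_network",
    "load_gene_list",
    "write_edge_list",
    "count_links",
    "naf_curve",
    "assortativity",
]


class NetworkParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


class AssortativityUndefinedError(ValueError):
    """Degree assortativity is undefined (zero variance of endpoint degrees)."""


class Network:
    """Simple undirected graph over gene identifiers.

    Nodes are strings; edges are unordered pairs of distinct nodes.  The
    constructor deduplicates edges (including reversed duplicates) and rejects
    self-loops.  Isolated nodes are allowed (genes known to the network but
    without any interaction partner).
    """

    __slots__ = ("_adj",)

    def __init__(
        self,
        edges: Iterable[Tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        adj: Dict[str, Set[str]] = {}
        for n in nodes:
            adj.setdefault(n, set())
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop not allowed: {u!r}")
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        self._adj = adj

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> Set[str]:
        return set(self._adj)

    @property
    def node_list(self) -> List[str]:
        return list(self._adj)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def degree(self, node: str) -> int:
        return len(self._adj[node])

    @property
    def degrees(self) -> Dict[str, int]:
        return {n: len(nbrs) for n, nbrs in self._adj.items()}

    def neighbors(self, node: str) -> Set[str]:
        return set(self._adj[node])

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, ())

    def has_node(self, node: str) -> bool:
        return node in self._adj

    def edges(self) -> Iterator[Tuple[str, str]]:
        """Iterate each edge exactly once as a sorted (u, v) tuple."""
        for u, nbrs in self._adj.items():
            for v in nbrs:
                if u < v:
                    yield (u, v)

    def edge_set(self) -> Set[Tuple[str, str]]:
        return set(self.edges())

    def __contains__(self, node: str) -> bool:
        return node in self._adj

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self._adj == other._adj

    def __repr__(self) -> str:
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def copy(self) -> "Network":
        net = Network()
        net._adj = {n: set(nbrs) for n, nbrs in self._adj.items()}
        return net

    def check_invariants(self) -> None:
        """Assert the simple-graph invariants (handshake identity, symmetry)."""
        total = 0
        for u, nbrs in self._adj.items():
            if u in nbrs:
                raise AssertionError(f"self-loop at {u!r}")
            for v in nbrs:
                if u not in self._adj.get(v, ()):
                    raise AssertionError(f"asymmetric adjacency {u!r}-{v!r}")
            total += len(nbrs)
        if total != 2 * self.n_edges:
            raise AssertionError("handshake identity violated")


@dataclass(frozen=True)
class GeneSet:
    """Named, unordered set of gene identifiers (an FGS, or a plain AGS)."""

    name: str
    genes: FrozenSet[str]

    def __init__(self, name: str, genes: Iterable[str]) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", frozenset(genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)


@dataclass(frozen=True)
class RankedGeneList:
    """Ordered altered gene set; rank 1 is the most altered gene.

    The closed prefix of the first ``k`` genes defines the fixed-size altered
    set A(k).
    """

    name: str
    genes: Tuple[str, ...] = field(default=())

    def __init__(self, name: str, genes: Sequence[str]) -> None:
        genes = tuple(genes)
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate genes in ranked list {name!r}")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def prefix(self, k: int) -> Set[str]:
        """The altered set A(k): genes at ranks 1..k."""
        if not 1 <= k <= len(self.genes):
            raise ValueError(f"k={k} out of range 1..{len(self.genes)}")
        return set(self.genes[:k])

    def as_set(self) -> GeneSet:
        return GeneSet(self.name, self.genes)


# -- I/O --------------------------------------------------------------------

def load_network(path: str, delimiter: str | None = None, sif: bool = False) -> Network:
    """Read an undirected network from a two-column edge-list file.

    Lines starting with ``#`` are comments.  Duplicate lines and reversed
    duplicates collapse to a single edge; self-loop lines are dropped with a
    warning.  With ``sif=True`` the file is read as SIF (gene1 relation
    gene2): columns 1 and 3 are used.

    Parameters
    ----------
    path
        Edge-list file.
    delimiter
        Field separator; ``None`` splits on any whitespace (covers TSV).
    """
    edges: List[Tuple[str, str]] = []
    dropped_self_loops = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            need = 3 if sif else 2
            if len(fields) < need:
                raise NetworkParseError(
                    f"{path}:{lineno}: expected at least {need} fields, got {len(fields)}"
                )
            u, v = (fields[0], fields[2]) if sif else (fields[0], fields[1])
            n_lines += 1
            if u == v:
                dropped_self_loops += 1
                logger.warning("%s:%d: dropped self-loop %r", path, lineno, u)
                continue
            edges.append((u, v))
    if n_lines == 0:
        raise NetworkParseError(f"{path}: no edges found")
    net = Network(edges)
    logger.info(
        "loaded network from %s: %d nodes, %d edges (%d lines, %d self-loops dropped)",
        path, net.n_nodes, net.n_edges, n_lines, dropped_self_loops,
    )
    return net


def write_edge_list(net: Network, path: str) -> None:
    """Write the network as a tab-separated two-column edge list (sorted)."""
    with open(path, "w") as fh:
        for u, v in sorted(net.edges()):
            fh.write(f"{u}\t{v}\n")


def load_gene_list(path: str, name: str | None = None) -> RankedGeneList:
    """Read a ranked gene list: one gene per line, file order preserved."""
    genes: List[str] = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if not g or g.startswith("#"):
                continue
            if g in seen:
                logger.warning("%s: duplicate gene %r ignored", path, g)
                continue
            seen.add(g)
            genes.append(g)
    return RankedGeneList(name or path, genes)


# -- link counting ----------------------------------------------------------

def count_links(net: Network, A: Iterable[str], F: Iterable[str]) -> int:
    """Number of network links between gene sets A and F.

    An edge (u, v) qualifies when one endpoint is in A and the other in F.
    Each qualifying edge is counted exactly once, including edges with both
    endpoints in the overlap A ∩ F.  Genes absent from the network contribute
    no links.
    """
    adj = net._adj
    A = {g for g in A if g in adj}
    F = {g for g in F if g in adj}
    total = sum(len(adj[u] & F) for u in A)
    both = A & F
    if both:
        # edges fully inside A ∩ F were counted from both endpoints
        internal = sum(len(adj[u] & both) for u in both) // 2
        total -= internal
    return total


def naf_curve(
    net: Network, ags: RankedGeneList, F: Iterable[str], k_max: int
) -> np.ndarray:
    """Observed link-count curve n_AF(k) for k = 1..k_max.

    Element ``k-1`` equals ``count_links(net, A(k), F)``; the curve is
    nondecreasing in k.  Computed incrementally: adding the gene at rank k
    contributes its links to F that were not already counted via the overlap.
    """
    if not 1 <= k_max <= len(ags):
        raise ValueError(f"k_max={k_max} out of range 1..{len(ags)}")
    adj = net._adj
    F = {g for g in F if g in adj}
    curve = np.empty(k_max, dtype=np.int64)
    count = 0
    a_prev: Set[str] = set()
    for i, g in enumerate(ags.genes[:k_max]):
        nbrs = adj.get(g)
        if nbrs is not None:
            hits = nbrs & F
            add = len(hits)
            if g in F and a_prev:
                # edges g-v with v in F and v already in A were counted when
                # v entered (g in F made them qualify then)
                add -= len(hits & a_prev)
            count += add
            a_prev.add(g)
        curve[i] = count
    return curve


# -- descriptive statistics -------------------------------------------------

def assortativity(net: Network) -> float:
    """Degree assortativity: Pearson correlation of endpoint degrees over links.

    Each edge contributes its two endpoint degrees in both orientations.
    Raises :class:`AssortativityUndefinedError` when the endpoint-degree
    variance is zero (e.g. regular graphs), and ``ValueError`` on an edgeless
    network.
    """
    if net.n_edges == 0:
        raise ValueError("assortativity undefined for an edgeless network")
    deg = net.degrees
    x: List[int] = []
    y: List[int] = []
    for u, v in net.edges():
        du, dv = deg[u], deg[v]
        x.extend((du, dv))
        y.extend((dv, du))
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if np.var(xa) == 0.0:
        raise AssortativityUndefinedError(
            "all endpoint degrees equal; assortativity undefined"
        )
    return float(np.corrcoef(xa, ya)[0, 1])
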