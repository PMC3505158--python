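"""Synthetic networks and gene sets with known structure.

Biological interaction networks are scale-free: a few hubs, many sparsely
connected nodes.  The default generator uses preferential attachment, which
produces connected simple graphs with heavy-tailed degrees.  Null AGS/FGS
pairs are drawn uniformly and independently of topology (the calibration
setting in which enrichment p-values must be uniform); planted enrichment
adds a known number of extra AGS-FGS links to create a controlled effect
size for power studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .network import GeneSet, Network, RankedGeneList
from .randomize import DegreeSequence, sample_uniform_rejection

__all__ = [
    "SimulationConfig",
    "make_scale_free",
    "make_from_degree_sequence",
    "draw_null_pair",
    "plant_enrichment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study condition."""

    n_nodes: int = 500
    m_per_node: int = 3
    ags_size: int = 40
    fgs_size: int = 40
    n_extra_links: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ags_size > self.n_nodes or self.fgs_size > self.n_nodes:
            raise ValueError("gene-set sizes must not exceed n_nodes")
        if self.n_extra_links < 0:
            raise ValueError("n_extra_links must be >= 0")


def _gene_name(i: int) -> str:
    return f"g{i:04d}"


def make_scale_free(n_nodes: int, m_per_node: int, seed: int) -> Network:
    """Connected scale-free network by preferential attachment.

    Each new node attaches ``m_per_node`` edges to existing nodes with
    probability proportional to their degree, yielding a heavy-tailed degree
    distribution (max degree far above the median for n >= 100).
    """
    if not 1 <= m_per_node < n_nodes:
        raise ValueError("require 1 <= m_per_node < n_nodes")
    g = nx.barabasi_albert_graph(n_nodes, m_per_node, seed=int(seed))
    return Network((( _gene_name(u), _gene_name(v)) for u, v in g.edges()),
                   nodes=(_gene_name(i) for i in g.nodes()))


def make_from_degree_sequence(
    degrees: Sequence[int], seed: int, max_tries: int = 1_000_000
) -> Network:
    """Exact-degree-sequence network via the uniform rejection sampler
    (small instances only)."""
    return sample_uniform_rejection(DegreeSequence.from_degrees(degrees), seed,
                                    max_tries=max_tries)


def draw_null_pair(
    net: Network, ags_size: int, fgs_size: int, seed: int | np.random.Generator
) -> Tuple[RankedGeneList, GeneSet]:
    """AGS and FGS drawn uniformly from the nodes, independently of topology
    and of each other (overlap permitted); the AGS ranking is a uniform
    random order."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = np.array(sorted(net.nodes), dtype=object)
    if ags_size > len(nodes) or fgs_size > len(nodes):
        raise ValueError("set sizes exceed the node count")
    ags_genes = rng.choice(nodes, size=ags_size, replace=False)
    fgs_genes = rng.choice(nodes, size=fgs_size, replace=False)
    return (
        RankedGeneList("null_ags", ags_genes.tolist()),
        GeneSet("null_fgs", fgs_genes.tolist()),
    )


def plant_enrichment(
    net: Network,
    ags: RankedGeneList,
    fgs: GeneSet,
    n_extra_links: int,
    seed: int | np.random.Generator,
) -> Network:
    """Add exactly ``n_extra_links`` new AGS-FGS edges to the network.

    Each new edge joins a uniformly chosen non-adjacent (AGS member, FGS
    member) pair; no self-loops; edges outside AGS x FGS are untouched, and
    the degree sequence changes only at the chosen endpoints.
    """
    if n_extra_links == 0:
        return net.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    candidates = sorted(
        tuple(sorted((a, f)))
        for a in ags.genes
        for f in fgs.genes
        if a != f and not net.has_edge(a, f)
    )
    candidates = sorted(set(candidates))
    if n_extra_links > len(candidates):
        raise ValueError(
            f"cannot plant {n_extra_links} links: only {len(candidates)} "
            "absent AGS-FGS pairs"
        )
    picks = rng.choice(len(candidates), size=n_extra_links, replace=False)
    out = net.copy()
    adj = out._adj
    for p in picks:
        u, v = candidates[p]
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return out
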