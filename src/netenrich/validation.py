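"""Study-level validation procedures on synthetic data.

These are the package's standard self-checks, bundled so they can be run
both by the test suite and from a report script:

* exact degree preservation of both randomizers over repeated draws;
* the sequential sampler's output distribution versus the uniform
  distribution over all labeled realizations, exhaustively for every
  graphical degree sequence on up to 6 nodes (chi-square, with rejected
  sequences flagged — the sampler is only approximately uniform, and this
  scan measures the bias);
* calibration: with altered and functional sets drawn independently of the
  topology, two-sided enrichment p-values must be uniform;
* power: a known number of planted AGS-FGS links must be detected by the
  link-count z-score while leaving the overlap (GEA) z-score untouched.

Default parameters are the package's reference study conditions: a 500-node
preferential-attachment network (3 edges per node), 40-gene AGS/FGS, 100
randomization replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy.stats import chisquare, kstest

from .enrichment import run_nea
from .network import GeneSet, Network, RankedGeneList
from .overlap import contingency, gea_z
from .randomize import (
    _sequential_edges,
    enumerate_labeled_graphs,
    graphical_sequences,
    randomize_edge_swap,
    randomize_sequential,
)
from .synth import draw_null_pair, make_scale_free, plant_enrichment

__all__ = [
    "degree_preservation_trial",
    "UniformityResult",
    "sequential_uniformity_scan",
    "calibration_pvalues",
    "power_with_planted_links",
]


def degree_preservation_trial(
    n_nodes: int = 500,
    m_per_node: int = 3,
    n_draws: int = 100,
    seed: int = 0,
) -> Dict[str, int]:
    """Count invariant violations over repeated draws of both randomizers.

    Every draw of the sequential and of the edge-swap randomizer (one swap
    proposal per network link) is checked for exact degree preservation and
    the simple-graph invariants.  A correct implementation reports zero
    violations.
    """
    net = make_scale_free(n_nodes, m_per_node, seed)
    degrees = net.degrees
    violations = 0
    for b in range(n_draws):
        for rnd in (
            randomize_sequential(net, np.random.default_rng((seed, 1, b))),
            randomize_edge_swap(net, net.n_edges,
                                np.random.default_rng((seed, 2, b))),
        ):
            try:
                rnd.check_invariants()
            except AssertionError:
                violations += 1
                continue
            if rnd.degrees != degrees:
                violations += 1
    return {"n_draws": n_draws, "violations": violations}


@dataclass(frozen=True)
class UniformityResult:
    degrees: Tuple[int, ...]
    n_graphs: int
    n_draws: int
    chi2: float
    pvalue: float
    rejected: bool


def sequential_uniformity_scan(
    n_max: int = 6,
    n_draws: int = 20_000,
    alpha: float = 1e-3,
    seed: int = 0,
) -> List[UniformityResult]:
    """Compare the sequential sampler against uniformity on tiny instances.

    For every graphical positive degree sequence on 2..n_max labeled nodes,
    the empirical distribution of the sampler over all labeled simple-graph
    realizations (exhaustive enumeration) is tested with a chi-square
    goodness-of-fit against the uniform distribution; sequences where
    uniformity is rejected at ``alpha`` are flagged.  Every draw is also
    required to land in the enumerated support (i.e. to realize the exact
    degree sequence).
    """
    rng = np.random.default_rng(seed)
    results: List[UniformityResult] = []
    for seq in graphical_sequences(n_max):
        graphs = enumerate_labeled_graphs(seq)
        index = {g: i for i, g in enumerate(graphs)}
        deg = np.asarray(seq, dtype=np.int64)
        counts = np.zeros(len(graphs), dtype=np.int64)
        draws = n_draws if len(graphs) > 1 else min(n_draws, 100)
        for _ in range(draws):
            edges = None
            while edges is None:
                edges = _sequential_edges(deg, rng)
            key = frozenset(tuple(sorted(e)) for e in edges)
            counts[index[key]] += 1  # KeyError = degrees not realized
        if len(graphs) == 1:
            results.append(UniformityResult(seq, 1, draws, 0.0, 1.0, False))
            continue
        chi2, p = chisquare(counts)
        results.append(
            UniformityResult(seq, len(graphs), draws, float(chi2), float(p),
                             bool(p < alpha))
        )
    return results


def calibration_pvalues(
    n_pairs: int = 200,
    n_nodes: int = 500,
    m_per_node: int = 3,
    ags_size: int = 40,
    fgs_size: int = 40,
    B: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Two-sided enrichment p-values for topology-independent AGS/FGS pairs.

    Each pair is drawn uniformly from the nodes of one scale-free network
    and scored with the fixed-size link-count statistic; under this null the
    returned p-values should be (approximately) uniform on [0, 1].
    """
    net = make_scale_free(n_nodes, m_per_node, seed)
    pvals = np.empty(n_pairs)
    for i in range(n_pairs):
        pair_seed = int(np.random.SeedSequence([seed, 7, i]).generate_state(1)[0] >> 1)
        ags, fgs = draw_null_pair(net, ags_size, fgs_size,
                                  np.random.default_rng((seed, 8, i)))
        res = run_nea(net, [ags], [fgs], mode="fixed", k=ags_size, B=B,
                      seed=pair_seed)
        pvals[i] = res[0].p_two
    return pvals


def calibration_ks(pvals: np.ndarray) -> Tuple[float, float]:
    """Kolmogorov-Smirnov statistic and p-value against Uniform(0, 1)."""
    r = kstest(pvals, "uniform")
    return float(r.statistic), float(r.pvalue)


def power_with_planted_links(
    n_repeats: int = 100,
    n_extra_links: int = 30,
    n_nodes: int = 500,
    m_per_node: int = 3,
    ags_size: int = 40,
    fgs_size: int = 40,
    B: int = 100,
    z_crit: float = 1.96,
    seed: int = 0,
) -> Dict[str, float]:
    """Detection power for a planted link excess, and the overlap-score check.

    Per repeat an AGS and a disjoint FGS are drawn, ``n_extra_links`` new
    links are planted between them, and the fixed-size network z-score is
    computed on the planted network.  Power is the fraction of repeats with
    z above ``z_crit``.  Because planting changes no set membership, the
    overlap (GEA) z-score must be bitwise identical before and after
    planting; the maximum absolute change over repeats is returned.
    """
    net = make_scale_free(n_nodes, m_per_node, seed)
    nodes = sorted(net.nodes)
    universe = net.nodes
    detected = 0
    gea_change = 0.0
    for i in range(n_repeats):
        rng = np.random.default_rng((seed, 9, i))
        picks = rng.choice(len(nodes), size=ags_size + fgs_size, replace=False)
        ags = RankedGeneList("ags", [nodes[j] for j in picks[:ags_size]])
        fgs = GeneSet("fgs", [nodes[j] for j in picks[ags_size:]])
        planted = plant_enrichment(net, ags, fgs, n_extra_links,
                                   np.random.default_rng((seed, 10, i)))
        pair_seed = int(np.random.SeedSequence([seed, 11, i]).generate_state(1)[0] >> 1)
        res = run_nea(planted, [ags], [fgs], mode="fixed", k=ags_size, B=B,
                      seed=pair_seed)
        if res[0].z is not None and res[0].z > z_crit:
            detected += 1
        a, f = set(ags.genes), set(fgs.genes)
        z_before = gea_z(contingency(a, f, universe))
        z_after = gea_z(contingency(a, f, planted.nodes))
        gea_change = max(gea_change, abs(z_after - z_before))
    return {
        "power": detected / n_repeats,
        "n_repeats": n_repeats,
        "gea_max_abs_change": gea_change,
    }
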