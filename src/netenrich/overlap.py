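"""Overlap-based comparator statistics: GEA and GSEA.

GEA scores an AGS-FGS pair by the z-statistic of the log odds-ratio of the
2x2 membership table over the gene universe (zero cells replaced by 0.5).
GSEA walks the ranked gene list accumulating +1/N_hit at FGS members and
-1/N_miss elsewhere and reports the running-sum extremum; significance comes
from permuting gene ranks within the same list (within-sample permutation,
appropriate when each AGS belongs to a single sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Set, Tuple

import numpy as np

from .enrichment import pvalues
from .network import RankedGeneList

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "contingency",
    "gea_z",
    "gsea_es",
    "gsea_permutation_p",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 partition of the gene universe by AGS x FGS membership.

    a = |AGS ∩ FGS|, b = |AGS \\ FGS|, c = |FGS \\ AGS|, d = the rest.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency(
    ags: Iterable[str], fgs: Iterable[str], universe: Iterable[str]
) -> ContingencyTable:
    """Membership table of AGS x FGS over the gene universe.

    Genes outside the universe are discarded from both sets (counts logged).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    ags = set(ags)
    fgs = set(fgs)
    lost = len(ags - universe) + len(fgs - universe)
    if lost:
        logger.info("contingency: %d genes outside the universe discarded", lost)
    ags &= universe
    fgs &= universe
    a = len(ags & fgs)
    b = len(ags - fgs)
    c = len(fgs - ags)
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def gea_z(t: ContingencyTable) -> float:
    """z-statistic of the log odds-ratio: log(ad/bc) / sqrt(1/a+1/b+1/c+1/d).

    Any zero cell is replaced by 0.5 (in both the numerator and the variance
    term) so the statistic is always defined.
    """
    a, b, c, d = (x if x > 0 else 0.5 for x in (t.a, t.b, t.c, t.d))
    return float(
        np.log((a * d) / (b * c)) / np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    )


def gsea_es(
    ranked: RankedGeneList | Sequence[str],
    fgs: Iterable[str],
    signed: bool = True,
) -> float:
    """GSEA running-sum enrichment score over a ranked gene list.

    Hits (genes in ``fgs``) add 1/N_hit, misses subtract 1/N_miss, where
    N_hit = |ranked ∩ fgs| and N_miss = |ranked| - N_hit, so the running sum
    always ends at 0.  With ``signed`` (default) the extremum of largest
    absolute magnitude is returned with its sign; ``signed=False`` returns
    the plain running maximum.  Degenerate lists (no hit, or no miss) score
    0 with a warning.
    """
    genes = ranked.genes if isinstance(ranked, RankedGeneList) else tuple(ranked)
    if not genes:
        raise ValueError("ranked list is empty")
    fgs = set(fgs)
    is_hit = np.fromiter((g in fgs for g in genes), dtype=bool, count=len(genes))
    n_hit = int(is_hit.sum())
    n_miss = len(genes) - n_hit
    if n_hit == 0 or n_miss == 0:
        logger.warning(
            "GSEA: degenerate list (%d hits, %d misses); score defined as 0",
            n_hit, n_miss,
        )
        return 0.0
    # Evaluate from cumulative integer counts rather than accumulating
    # float increments: each term is an exact division in [0, 1], so the
    # running sum cannot drift outside [-1, 1] and ends at exactly 0.
    hits_cum = np.cumsum(is_hit)
    miss_cum = np.arange(1, len(genes) + 1) - hits_cum
    running = hits_cum / n_hit - miss_cum / n_miss
    if signed:
        idx = int(np.argmax(np.abs(running)))
        return float(running[idx])
    return float(running.max())


def gsea_permutation_p(
    ranked: RankedGeneList | Sequence[str],
    fgs: Iterable[str],
    B: int = 100,
    seed: int | np.random.Generator = 0,
    signed: bool = True,
) -> Tuple[float, float]:
    """Enrichment score with a within-sample permutation p-value.

    The null reshuffles the gene ranks of the same list B times and rescores;
    the two-sided p follows the same proportion rule as the network
    permutation p-values.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = list(ranked.genes if isinstance(ranked, RankedGeneList) else ranked)
    fgs = set(fgs)
    es = gsea_es(genes, fgs, signed=signed)
    null = np.empty(B, dtype=float)
    arr = np.array(genes, dtype=object)
    for b in range(B):
        perm = rng.permutation(len(arr))
        null[b] = gsea_es(arr[perm].tolist(), fgs, signed=signed)
    _, _, _, p_two = pvalues(es, null)
    return es, p_two
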