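"""Altered-gene-set construction from expression matrices, and GMT I/O.

An expression matrix holds per-gene, per-sample log intensity-ratios
log(T/N) (tumor vs matched normal, any log base; only centered values are
used downstream).  Per-sample deviation scores subtract the gene-wise mean
across samples, quantifying how uncommon a gene's differential expression is
in one sample relative to the cohort.  Altered gene sets are the top-k genes
by deviation (transcriptomics-style) or all genes above their cohort average
(proteomics-style).
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence

import pandas as pd

from .network import GeneSet, RankedGeneList

logger = logging.getLogger(__name__)

__all__ = [
    "load_expression_matrix",
    "deviation_scores",
    "top_k_ags",
    "above_average_ags",
    "load_gmt",
    "write_gmt",
]


def load_expression_matrix(path: str, sep: str = "\t") -> pd.DataFrame:
    """Read a genes x samples matrix: first column gene symbols, header row
    of sample identifiers."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene identifiers")
    return df


def deviation_scores(m: pd.DataFrame) -> pd.DataFrame:
    """Center each gene on its mean across samples: log(T/N)_pg - ave_g.

    Rows with all values missing are dropped with a warning; missing values
    are excluded from the row mean.  Output row means are 0.
    """
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples for centering")
    all_missing = m.isna().all(axis=1)
    if all_missing.any():
        logger.warning("dropping %d all-missing gene rows", int(all_missing.sum()))
        m = m.loc[~all_missing]
    return m.sub(m.mean(axis=1, skipna=True), axis=0)


def top_k_ags(
    scores: pd.DataFrame, sample: str, k: int, ranking: str = "abs"
) -> RankedGeneList:
    """Top-k altered genes for one sample, by deviation score.

    ranking="abs" (default) sorts by |score| descending, capturing both up-
    and down-regulation; "up" by signed score descending; "down" ascending.
    Genes with a missing score in the sample are excluded; ties are broken
    by gene identifier for determinism.
    """
    col = scores[sample].dropna()
    if k > len(col):
        raise ValueError(f"k={k} exceeds the {len(col)} scored genes in {sample!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if ranking == "abs":
        key = col.abs()
    elif ranking == "up":
        key = col
    elif ranking == "down":
        key = -col
    else:
        raise ValueError(f"unknown ranking mode {ranking!r}")
    order = (
        pd.DataFrame({"key": key})
        .rename_axis("gene")
        .reset_index()
        .sort_values(["key", "gene"], ascending=[False, True], kind="stable")
    )
    return RankedGeneList(str(sample), order["gene"].head(k).tolist())


def above_average_ags(m: pd.DataFrame, sample: str) -> GeneSet:
    """Genes whose expression in ``sample`` exceeds their cohort average
    (deviation score strictly positive) — the proteomics-style AGS."""
    dev = deviation_scores(m)[sample]
    return GeneSet(str(sample), dev.index[dev > 0].tolist())


def load_gmt(path: str) -> List[GeneSet]:
    """Read a GMT gene-set collection: name TAB description TAB gene1 TAB ...

    Duplicate genes within a line are deduplicated with a warning; duplicate
    set names raise an error; trailing empty fields are ignored.
    """
    sets: List[GeneSet] = []
    names = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name = fields[0]
            if name in names:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            names.add(name)
            genes = [g for g in fields[2:] if g]
            if len(set(genes)) != len(genes):
                logger.warning("%s:%d: duplicate genes in %r deduplicated",
                               path, lineno, name)
            sets.append(GeneSet(name, genes))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str,
              descriptions: Optional[Sequence[str]] = None) -> None:
    """Write gene sets in GMT format (genes sorted for stable output)."""
    with open(path, "w") as fh:
        for i, gs in enumerate(sets):
            desc = descriptions[i] if descriptions else "na"
            fh.write("\t".join([gs.name, desc, *sorted(gs.genes)]) + "\n")
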