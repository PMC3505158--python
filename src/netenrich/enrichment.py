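"""Network enrichment statistics.

The observed link count n_AF between an altered gene set A and a functional
gene set F is centered by its Monte-Carlo expectation under degree-preserving
randomization:

    d_AF(k) = n_AF(k) - mu_AF(k)                       (fixed k; FNEA)
    d_AF    = d_max if d_max >= -d_min else d_min      (largest signed
                                                        deviation over k; MNEA)

with z-scores z = (d_AF - mean(d*_AF)) / sd(d*_AF) over the null replicates,
permutation p-values by proportion, and FDR by the standard m*pi0*p/k
estimate with enforced monotonicity (equal to Benjamini-Hochberg at pi0=1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.stats import norm

from .network import GeneSet, Network, RankedGeneList, count_links, naf_curve
from .randomize import NullEnsemble, null_ensemble, randomize_sequential, replicate_rng

logger = logging.getLogger(__name__)

__all__ = [
    "NullSummary",
    "EnrichmentResult",
    "deviation_fixed",
    "deviation_max",
    "pvalues",
    "zscore",
    "fdr",
    "run_nea",
    "results_to_frame",
]


@dataclass(frozen=True)
class NullSummary:
    """Mean and standard deviation of the null deviations d*_AF."""

    mean: float
    sd: float
    null_deviations: np.ndarray

    @property
    def B(self) -> int:
        return len(self.null_deviations)


@dataclass
class EnrichmentResult:
    ags_name: str
    fgs_name: str
    mode: str  # "fixed" | "max"
    k: Optional[int]
    n_obs: float
    mu: float
    d: float
    z: Optional[float]  # None when the null deviations are degenerate
    p_right: float
    p_left: float
    p_one: float
    p_two: float
    z_p_two: Optional[float]  # normal-approximation two-sided p from z
    B: int
    n_ags_in_network: int = 0
    n_fgs_in_network: int = 0
    fdr: Optional[float] = None


def deviation_fixed(
    n_obs: float, null_values: Sequence[float]
) -> Tuple[float, NullSummary]:
    """Fixed-k deviation d_AF(k) = n_obs - mu, with the null deviations.

    mu is estimated as the mean of the B null link counts at the same k; the
    same mu centers both the observed count and every null replicate.
    """
    null_values = np.asarray(null_values, dtype=float)
    B = len(null_values)
    if B < 2:
        raise ValueError("need at least 2 null replicates (variance undefined)")
    mu = null_values.mean()
    d = float(n_obs) - mu
    d_null = null_values - mu
    return d, NullSummary(
        mean=float(d_null.mean()), sd=float(d_null.std(ddof=1)), null_deviations=d_null
    )


def _max_signed_deviation(dev: np.ndarray) -> float:
    """Largest signed deviation: d_max when d_max >= -d_min, else d_min."""
    d_max = float(dev.max())
    d_min = float(dev.min())
    return d_max if d_max >= -d_min else d_min


def deviation_max(
    obs_curve: Sequence[float], null_curves: np.ndarray
) -> Tuple[float, np.ndarray, NullSummary]:
    """Largest-signed-deviation statistic d_AF over the whole curve (MNEA).

    mu(k) is the replicate mean at each k; the same selection rule is applied
    to the observed centered curve and to every null replicate's curve.
    Returns (d_AF, per-replicate null d*_AF, NullSummary).
    """
    obs_curve = np.asarray(obs_curve, dtype=float)
    null_curves = np.asarray(null_curves, dtype=float)
    if null_curves.ndim != 2 or null_curves.shape[1] != obs_curve.shape[0]:
        raise ValueError("observed and null curves must share length k_max")
    B = null_curves.shape[0]
    if B < 2:
        raise ValueError("need at least 2 null replicates")
    mu = null_curves.mean(axis=0)
    d_obs = _max_signed_deviation(obs_curve - mu)
    centered = null_curves - mu
    d_max = centered.max(axis=1)
    d_min = centered.min(axis=1)
    d_null = np.where(d_max >= -d_min, d_max, d_min)
    summary = NullSummary(
        mean=float(d_null.mean()), sd=float(d_null.std(ddof=1)), null_deviations=d_null
    )
    return d_obs, d_null, summary


def pvalues(
    d_obs: float, d_null: Sequence[float], smoothing: bool = False
) -> Tuple[float, float, float, float]:
    """Permutation p-values from the null deviations.

    p_right is the proportion of null deviations >= d_obs (ties count),
    p_left the proportion <= d_obs; the one-sided p is the smaller of the
    two and the two-sided p is twice the one-sided, capped at 1.  With
    ``smoothing`` both the count and the denominator gain 1, keeping the
    smallest attainable p strictly positive.
    """
    d_null = np.asarray(d_null, dtype=float)
    B = len(d_null)
    if B < 1:
        raise ValueError("need at least 1 null replicate")
    add = 1 if smoothing else 0
    p_right = (int((d_null >= d_obs).sum()) + add) / (B + add)
    p_left = (int((d_null <= d_obs).sum()) + add) / (B + add)
    p_one = min(p_right, p_left)
    p_two = min(1.0, 2.0 * p_one)
    return p_right, p_left, p_one, p_two


def zscore(d_obs: float, summary: NullSummary) -> Optional[float]:
    """Standardized enrichment score z = (d_obs - mean d*) / sd d*.

    Returns None when the null standard deviation is zero (degenerate null);
    callers flag this rather than propagate an infinity.
    """
    if summary.sd == 0.0 or not math.isfinite(summary.sd):
        return None
    return (d_obs - summary.mean) / summary.sd


def normal_p_two(z: Optional[float]) -> Optional[float]:
    """Two-sided p-value from z under a standard-normal assumption."""
    if z is None:
        return None
    return float(2.0 * norm.sf(abs(z)))


def fdr(pvals: Sequence[float], pi0: float = 1.0) -> np.ndarray:
    """False discovery rate estimate FDR(p_k) = m * pi0 * p_k / k.

    p-values are ranked ascending; monotonicity is imposed by the cumulative
    minimum over all p-values >= p_k; estimates are capped at 1.  At pi0 = 1
    this equals the Benjamini-Hochberg adjusted p-value.  Results are
    returned in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = m * pi0 * ranked / np.arange(1, m + 1)
    mono = np.minimum.accumulate(raw[::-1])[::-1]
    mono = np.minimum(mono, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = mono
    return out


def estimate_pi0(pvals: Sequence[float], lam: float = 0.5) -> float:
    """Storey-type estimate of the null proportion: #{p > lam} / (m (1-lam))."""
    p = np.asarray(pvals, dtype=float)
    est = (p > lam).sum() / (p.size * (1.0 - lam))
    return float(min(1.0, max(est, 1.0 / p.size)))


AgsInput = Union[RankedGeneList, GeneSet]


def run_nea(
    net: Network,
    ags_list: Sequence[AgsInput],
    fgs_list: Sequence[GeneSet],
    mode: str = "fixed",
    k: int = 100,
    B: int = 100,
    seed: int = 0,
    pi0: Optional[float] = 1.0,
    smoothing: bool = False,
    k_grid: Optional[Sequence[int]] = None,
) -> List[EnrichmentResult]:
    """Network enrichment analysis over all AGS x FGS pairs.

    mode="fixed" (FNEA) scores the link count of the top-k altered genes; an
    unordered GeneSet is accepted, in which case k is its size.  mode="max"
    (MNEA) takes the largest signed deviation of the link-count curve over
    k = 1..|AGS| (or over ``k_grid``) and requires a ranked AGS.

    The B randomized networks are generated once per AGS and reused across
    all FGSs; the joint FDR is computed across every pair in the run from
    the two-sided permutation p-values.  With ``pi0=None`` the null
    proportion is estimated from the data (Storey, lambda=0.5).
    """
    if mode not in ("fixed", "max"):
        raise ValueError(f"unknown mode {mode!r}")
    if B < 2:
        raise ValueError("B must be >= 2")
    results: List[EnrichmentResult] = []
    net_nodes = net.nodes
    for a_idx, ags in enumerate(ags_list):
        if mode == "max" and not isinstance(ags, RankedGeneList):
            raise ValueError(
                f"mode='max' requires a ranked AGS; {ags.name!r} is unordered"
            )
        if isinstance(ags, RankedGeneList):
            ranked = ags
            k_eff = min(k, len(ranked)) if mode == "fixed" else len(ranked)
        else:
            ranked = RankedGeneList(ags.name, sorted(ags.genes))
            k_eff = len(ranked)
        if k_eff < 1:
            raise ValueError(f"AGS {ags.name!r} is empty")
        a_genes = ranked.prefix(k_eff)
        n_ags_mapped = len(a_genes & net_nodes)
        if n_ags_mapped < len(a_genes):
            logger.info(
                "AGS %s: %d of %d genes not in network",
                ags.name, len(a_genes) - n_ags_mapped, len(a_genes),
            )

        if mode == "fixed":
            grid = None
        else:
            grid = list(k_grid) if k_grid is not None else list(range(1, k_eff + 1))

        # randomize once per AGS, reuse across FGSs
        ags_seed = int(np.random.SeedSequence([seed, a_idx]).generate_state(1)[0] >> 1)
        null_counts = np.empty((B, len(fgs_list)), dtype=np.int64) if mode == "fixed" else None
        null_curves = (
            np.empty((B, len(fgs_list), len(grid)), dtype=np.int64) if mode == "max" else None
        )
        fgs_genes = [set(f.genes) for f in fgs_list]
        for b in range(B):
            rnd = randomize_sequential(net, replicate_rng(ags_seed, b))
            for f_idx, fset in enumerate(fgs_genes):
                if mode == "fixed":
                    null_counts[b, f_idx] = count_links(rnd, a_genes, fset)
                else:
                    curve = naf_curve(rnd, ranked, fset, k_eff)
                    null_curves[b, f_idx] = curve[np.asarray(grid) - 1]

        for f_idx, fgs in enumerate(fgs_list):
            fset = fgs_genes[f_idx]
            n_fgs_mapped = len(fset & net_nodes)
            if mode == "fixed":
                n_obs = count_links(net, a_genes, fset)
                d, summary = deviation_fixed(n_obs, null_counts[:, f_idx])
                d_null = summary.null_deviations
                mu = n_obs - d
                k_out: Optional[int] = k_eff
            else:
                obs_full = naf_curve(net, ranked, fset, k_eff)
                obs_curve = obs_full[np.asarray(grid) - 1]
                d, d_null, summary = deviation_max(obs_curve, null_curves[:, f_idx])
                n_obs = float(obs_full[-1])
                mu = float(null_curves[:, f_idx, -1].mean())
                k_out = None
            z = zscore(d, summary)
            p_r, p_l, p_1, p_2 = pvalues(d, d_null, smoothing=smoothing)
            results.append(
                EnrichmentResult(
                    ags_name=ags.name,
                    fgs_name=fgs.name,
                    mode=mode,
                    k=k_out,
                    n_obs=float(n_obs),
                    mu=float(mu),
                    d=float(d),
                    z=z,
                    p_right=p_r,
                    p_left=p_l,
                    p_one=p_1,
                    p_two=p_2,
                    z_p_two=normal_p_two(z),
                    B=B,
                    n_ags_in_network=n_ags_mapped,
                    n_fgs_in_network=n_fgs_mapped,
                )
            )

    p_two_all = [r.p_two for r in results]
    pi0_eff = estimate_pi0(p_two_all) if pi0 is None else pi0
    for r, q in zip(results, fdr(p_two_all, pi0=pi0_eff)):
        r.fdr = float(q)
    return results


def results_to_frame(results: Sequence[EnrichmentResult]):
    """Tabulate enrichment results (one row per AGS-FGS pair)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "ags": r.ags_name,
                "fgs": r.fgs_name,
                "mode": r.mode,
                "k": r.k,
                "n_links": r.n_obs,
                "expected": r.mu,
                "d": r.d,
                "z": r.z,
                "p_right": r.p_right,
                "p_left": r.p_left,
                "p_two": r.p_two,
                "z_p_two": r.z_p_two,
                "fdr": r.fdr,
                "n_ags_in_network": r.n_ags_in_network,
                "n_fgs_in_network": r.n_fgs_in_network,
            }
        )
    return pd.DataFrame(rows)
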