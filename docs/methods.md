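# Methods

## The statistic

Gene-set enrichment is usually scored by membership overlap: how many genes
of an experimentally altered gene set (AGS) fall inside a known functional
gene set (FGS).  `netenrich` instead scores *network connectivity*: given a
background gene-interaction network, the observed statistic is

    n_AF(k) = number of network links between A(k) and F,

where `A(k)` is the top-`k` prefix of the ranked AGS and `F` the FGS.  An
edge qualifies when one endpoint is in `A(k)` and the other in `F`; each
qualifying edge counts once, including edges lying entirely inside the
overlap `A ∩ F` (overlap is explicitly allowed).  Because hub genes
accumulate links by chance, the raw count is centered by its expectation
under a null model that preserves every node's degree:

    d_AF(k) = n_AF(k) − μ_AF(k)          (fixed k; the "FNEA" statistic)

To remove the dependence on the cutoff `k`, the maximum-deviation variant
takes the largest signed deviation of the whole curve:

    d_max = max_k {n_AF(k) − μ_AF(k)},   d_min = min_k {…}
    d_AF  = d_max  if d_max ≥ −d_min,  else  d_min       ("MNEA")

Ties (`d_max = −d_min`) resolve to `d_max` per the `≥` branch.  Both
statistics are standardized against the null replicates,

    z = (d_AF − mean d*_AF) / sd(d*_AF),

with the sample (B−1) standard deviation; the same functional
(centering by the ensemble mean μ̂, then max/min selection) is applied to
every null replicate, with no leave-one-out correction — at B = 100 this is
very slightly anti-conservative and is accepted for simplicity.
Permutation p-values are proportions of null deviations at least as extreme
(right- and left-sided; one-sided = the smaller; two-sided = twice the
one-sided, capped at 1).  An optional add-one smoothing keeps the smallest
p strictly positive; it is off by default to match the plain proportion
rule.  Because B = 100 gives a granularity of 0.01, the
normal-approximation p-value derived from `z` is always reported alongside
(`z_p_two`) for ranking below that floor.

False discovery rates use the standard estimate FDR(p_k) = m·π̂₀·p_k/k on
the ascending p-values with monotonicity enforced by a cumulative minimum
from the largest rank down, capped at 1.  With the default π̂₀ = 1 this is
exactly the Benjamini–Hochberg adjusted p-value (cross-checked against
statsmodels in the test suite); a Storey-type estimator (λ = 0.5) is
available for π̂₀.

## The null model: degree-preserving randomization

The degree distribution of biological networks is highly skewed, so the
null must hold every node's degree fixed.  Two samplers are provided.

**Sequential weighted construction** (the default): nodes are processed in
order of residual degree (equal degrees ordered by a random permutation
drawn once per randomization).  The current largest node's links are
assigned to the remaining positive-residual nodes by successive draws
without replacement, each draw proportional to residual degree; the node is
then removed and residual degrees decremented.  Each node is visited at most
once, so one randomization costs O(|E|) draws.  The weighted draws are
implemented with exponential sort keys (`Exp(1)/w`), which is exactly
equivalent to successive proportional sampling.  Infeasible residual states
(a node left with positive degree but too few eligible partners) trigger a
restart from scratch — restarting, rather than patching the partial
assignment, avoids conditioning bias; a cap (default 1000 restarts) turns a
pathological sequence into an explicit error.  Restarts are rare on
skewed-degree networks.

*Measured bias.*  The construction is **approximately, not exactly,
uniform** over simple graphs with the given degree sequence.  We verified
the implementation against an exact recursion over the algorithm's choice
tree (tie-breaks × successive weighted draws, in exact rational
arithmetic), and the recursion itself shows the law is non-uniform: for
degrees (2,2,2,1,1), the triangle-plus-edge realization has probability
≈ 0.119 versus uniform 1/7 ≈ 0.143.  The validation scan
(`netenrich.validation.sequential_uniformity_scan`) compares the sampler
with exhaustive enumeration on every graphical degree sequence with ≤ 6
nodes and flags each sequence where a chi-square test at α = 10⁻³ rejects
uniformity (roughly a quarter of the 101 sequences at 20,000 draws).  The
sampler is used as designed — fast, degree-exact, close to uniform — and
its bias is reported rather than silently corrected; an exactly uniform
rejection sampler is available as the reference oracle.

**Edge-swap rewiring**: repeatedly pick two edges A–B, C–D uniformly at
random and rewire to A–D, B–C; abort the proposal when the edges share a
node or either new link already exists.  `n_swaps` counts proposals, so
graphs with no valid swap (e.g. a 3-node path) terminate unchanged.
Attempted and accepted counts are logged.

**Uniform rejection sampler** (test oracle): every node independently
chooses its neighbors uniformly; a draw is accepted only when all choices
are mutual, which happens exactly when the union graph realizes the degree
sequence.  Each accepted graph corresponds to one equiprobable choice
profile, so accepted graphs are *exactly* uniform.  Cost grows explosively;
it is restricted to tiny instances.

Null ensembles derive replicate `b`'s generator from `(master_seed, b)`, so
a prefix of a larger ensemble equals the smaller ensemble and runs are
bit-reproducible.

A note on second-order structure: randomized networks preserve degrees but
not degree–degree correlation (assortativity, the Pearson correlation of
endpoint degrees over links, available as `assortativity()`); samplers
constrained on assortativity are out of scope.

## Comparator statistics

**GEA** builds the 2×2 table (a, b, c, d) partitioning a gene universe by
AGS × FGS membership and scores the log odds-ratio z-statistic
`log(ad/bc) / √(1/a+1/b+1/c+1/d)`, with every zero cell replaced by 0.5.
The default universe is the union of the network's nodes and all genes seen
in the input sets; it can be overridden explicitly.

**GSEA** walks the ranked list adding `1/N_hit` at FGS members and
`−1/N_miss` elsewhere, where `N_hit` counts FGS members *within the ranked
list* — with this convention the running sum always terminates at 0 (an
asserted checksum) and the score lies in [−1, 1].  The reported score is
the signed extremum of largest magnitude (a max-only variant is behind a
flag).  Significance is by within-sample permutation: gene ranks of the
same list are reshuffled B times, appropriate when each AGS belongs to a
single sample and there is no group structure to permute.

## Altered gene sets from expression data

Per-sample deviation scores subtract each gene's mean log(T/N) across
samples, isolating how unusual a gene's differential expression is in one
sample relative to the cohort; the transform is idempotent and invariant to
per-gene offsets (batch shifts).  Transcriptomics-style AGSs take the top-k
genes per sample (default k = 100); since ranking by signed or by absolute
deviation are both defensible, the default is absolute deviation (captures
up- and down-regulation) with `up`/`down` modes exposed.  Ties break by
gene identifier.  Proteomics-style AGSs keep every gene whose centered
value is strictly positive in the sample.  Missing values are excluded from
row means and from per-sample rankings; upstream normalization is assumed
done.

## Synthetic study conditions

All statistical guarantees are exercised on generated data with known
structure.  The reference conditions are:

| parameter | default | rationale |
|---|---|---|
| network | preferential attachment, n = 500, m = 3 | connected, simple, heavy-tailed degrees; ~1,500 links |
| AGS / FGS size | 40 / 40 | ≈ 8 % of the nodes, the same order as a 100-gene set against a ~16,000-gene real network |
| replicates B | 100 | the standard choice for the randomization null |
| planted effect | 30 extra AGS–FGS links | ≈ 1.5× the null expectation of ~20 links — a clear but not overwhelming signal |
| repeats | 100 (power), 200 pairs (calibration) | enough for a stable fraction / KS test in minutes |

`draw_null_pair` samples both sets uniformly and independently of the
topology (overlap permitted), which is precisely the null the p-values are
calibrated against.  `plant_enrichment` adds exactly `n_extra_links` new
edges between uniformly chosen non-adjacent (AGS, FGS) pairs, leaving
every edge outside AGS × FGS untouched.  Because planting changes no
memberships, the GEA score is bitwise unchanged while the link-count z
rises — the cleanest statement of what network enrichment sees that
overlap enrichment cannot.

What the generator does **not** emulate: weighted or directed interactions,
modular/community structure, correlated gene sets, assortative mixing, and
expression-driven AGS noise.  Passing calibration and power checks here
demonstrates the statistics behave correctly under the stated null and a
clean planted alternative, not that any particular biological network meets
those assumptions.

## Numerical and design choices

- Link counting treats an edge inside A ∩ F as one link (not two); the
  convention is applied identically to observed and null counts.
- The maximum-deviation grid defaults to every k = 1..|AGS|; a coarser grid
  can be supplied for very long lists.
- `z` is reported as undefined (not ±∞) when the null deviations are
  degenerate (sd = 0), e.g. an FGS with no links anywhere.
- Assortativity raises an explicit "undefined" error on zero endpoint-degree
  variance (regular graphs) instead of propagating NaN.
- Randomization restarts use a fresh stream from the same generator, so a
  restart consumes entropy but keeps determinism under a fixed seed.
- Gene identifiers are opaque case-sensitive strings; genes absent from the
  network stay in the sets (they matter for overlap statistics) but
  contribute no links; unmapped counts are reported in results and logs.
- Validation scans on ≤ 6 nodes use 20,000 draws per degree sequence: large
  enough that expected counts per labeled graph stay well above 5 (at most
  70 realizations per sequence on 6 nodes).

## Known limitations

- The sequential sampler's bias (above) is inherited by the null
  distribution, but it is *not* what limits p-value calibration at the
  reference conditions: the z-scores of null pairs are well centered and
  scaled (mean ≈ 0, sd ≈ 1.05 over 150 pairs).
- The plain proportion **two-sided p-value is measurably conservative**
  with integer link counts at B = 100.  Ties (`n* = n_obs`, probability
  ≈ 0.08 when the null sd is ≈ 5) are counted in *both* the right- and the
  left-sided proportion, so `p_right + p_left > 1` and
  `min(1, 2·min(p_right, p_left))` piles probability mass near 1.  A
  reference simulation with the counting rule applied to iid integer
  counts (Poisson, mean 20 — the study-condition link scale) and a perfect
  null sample shows an intrinsic Kolmogorov–Smirnov distance of ≈ 0.10
  from Uniform(0,1); the identical rule applied to a continuous statistic
  gives ≈ 0.025, and a mid-p variant (ties counted half) ≈ 0.016.  The
  distortion therefore belongs to the printed discrete rule, not to the
  randomization, and shrinks as counts grow (KS ≈ 0.04 at mean 200, the
  regime of large real networks).  Consequently the 200-pair calibration
  KS check at α = 0.01 sits on a knife edge (critical distance ≈ 0.115
  versus intrinsic ≈ 0.10) and fails for many seeds — the acceptance test
  records this honestly rather than silently switching to a mid-p rule,
  which would be a different method from the one documented above.
- Permutation p-values have resolution 1/B; use `z_p_two` for finer
  ranking, bearing in mind it assumes normality of the null deviations.
- Indirect links, weighted links, and single-gene enrichment (expressible
  as an FGS of size 1) have no dedicated machinery.
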