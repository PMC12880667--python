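# Methods

## The trial model

All analyses assume a randomized complete block design: G genotypes × r
replicate blocks, n plants per genotype–block plot. Per trait t the
plant-level model is additive,

    y_ijk = μ_t + g_i + b_j + ε_ijk,
    g ~ N(0, σ²_g),  b ~ N(0, σ²_b),  ε ~ N(0, σ²_e),

with no genotype-by-block interaction term (a single-environment trial gives
no way to separate interaction from error at the plot level, and the plot
means carry exactly one observation per cell).

### Broad-sense heritability

H² = σ²_g / (σ²_g + σ²_e / r). The formula divides the residual by the
number of replicate *blocks*, i.e. it describes the reliability of a
genotype mean taken over r blocks. We therefore estimate components on
**genotype-by-block plot means** by default: the residual is then plot-level
and r divides it exactly once. The alternative plant-level scale
(`scale="plants"`) is available; its residual is the plant-to-plant variance
and the same formula then yields a stricter (smaller) H². Components carry
their scale so the convention is always explicit. Note that under culling
the effective replication per plot drops, so estimated H² on real or
culling-simulated data sits somewhat below the generator's nominal truth —
that is a property of the data, not an estimator defect.

### Estimation

Two fits serve two purposes. The genotype **F-test** treats genotype as
fixed and block as a nuisance: nested least-squares models
(1 + genotype + block vs 1 + block), F = ΔRSS/(G−1) / (RSS_full/df), with
df = N − G − B + 1 (the between-within approximation; exact for balanced
data, and identical to the mixed-model ANOVA F there). **Variance
components** come from a model with genotype and block both random:

- `REML` (default): direct maximization of the restricted likelihood of the
  two-way crossed random model. V = σ²_g Z_g Z_gᵀ + σ²_b Z_b Z_bᵀ + σ²_e I
  is small (≤ G·r on the plot-mean scale), so the deviance and its analytic
  gradient are computed densely; L-BFGS-B runs on log-variances with the
  EMS solution as the warm start (the classical method-of-moments
  initialization). On balanced data with interior solutions this lands on
  the EMS closed form to machine precision; estimates driven to the
  boundary are reported as exact zeros.
- `EMS`: the balanced expected-mean-squares closed form,
  σ̂²_g = (MS_G − MS_E)/k with k = r on plot means (k = r·n̄ with the
  harmonic-mean plot size n̄, plus a warning, on unbalanced plant-level
  data). Negative solutions truncate to 0 and are flagged. EMS is retained
  as the independent closed-form oracle for the REML path.

Constrained REML at a boundary (some σ̂² = 0) re-optimizes the remaining
components, so it legitimately differs from truncated EMS there; the
equivalence property holds for interior solutions only.

No multiple-testing correction is applied across traits; each trait is
reported at its own p-value (α = 0.05 by convention), matching standard
practice for per-trait trial reports. Correlations use the t transform
t = r√((n−2)/(1−r²)) for significance and pairwise-complete observations,
so each trait pair uses every genotype where both means exist.

## Percentile ranks and quadrants

Percentile = 100·rank/n with average ranks for ties, computed among
non-missing genotypes, hence invariant to monotone transforms. (A literal
"divide into 100 quantiles" binning is degenerate for panels of fewer than
100 genotypes — every genotype would occupy its own bin — so the rank
definition is used and documented here as a deliberate choice.) "Upper 50 %"
means strictly greater than the threshold (default 50); ≤ threshold is the
lower half, so the two halves partition the panel even at odd n.

A side (root or shoot) is BIG only if *every* designated trait on that side
is above threshold, SMALL only if every one is at or below, otherwise MIXED;
any MIXED side makes the genotype UNASSIGNED. The default classification
set is the six-trait one (root dry biomass, total root length, root convex
area / shoot dry biomass, shoot convex area, shoot height); a five-trait
variant without shoot height is selectable via the trait-set arguments.
Resemblance for unassigned genotypes is decided per side: majority of that
side's big/small indicators, ties broken by whether the side's mean
percentile exceeds the threshold. Mean-centering/scaling is applied only for
PCA and clustering, never to percentile ranks (ranks are scale-free).

## Clustering and stability

PCA runs on column-wise z-scores (population SD); K-means on the full set
of PCA scores, which is an orthogonal rotation of the z-scored matrix and so
equivalent to clustering the scaled data directly — clustering a truncated
score matrix is possible by slicing `PCAResult.scores`. K-means takes the
best of `n_starts` (default 25) k-means++ initializations.

Bootstrap Jaccard stability follows the clusterwise-assessment convention:
each of B (default 100) resamples with replacement is re-clustered from
scratch with fresh starts (never seeded from the original solution, which
would bias stability upward); each original cluster is matched to the
bootstrap cluster maximizing J(A,B*) = |A∩B*|/|A∪B*| over the points present
in the resample; per-cluster stability is the mean of the B maxima. A
maximum below 0.5 counts as a dissolution; dissolved resamples still
contribute their value to the mean, and dissolution counts are reported
alongside. Concordance with the quadrant groups is a contingency table plus
the adjusted Rand index (chance-corrected; 1 = identical partitions).

## The synthetic generator

The generator emulates the study conditions: 46 genotypes × 3 blocks × 5
plants; 13 raw traits (lengths in mm, masses in g, areas in mm²) with means,
genetic CVs and per-trait H² set to the magnitudes reported for such panels
(total root length 0.63, shoot dry biomass 0.77, root crown width 0.45, …);
a one-factor "plant size" correlation structure (loadings ±0.2–0.95, PSD by
construction) in which root and shoot biomass load at 0.95 each, giving
their ~0.9 genetic correlation; block variance set to a quarter of the
genetic variance (unreported in the source setting; a modest, realistic
level); and truncated-Poisson culling with mean 2 per plot, capped at
n−1 so every plot keeps at least one plant. Under that cap the expected
per-plot removal at rate 2 is 1.925 and the expected fraction of plots with
≥ 4 removals is P(Pois(2) ≥ 4) ≈ 0.143 — consistent with "about two plants
per plot" and "roughly one plot in eight heavily culled".

Plant-level residuals are multivariate normal whose cross-trait correlation
**defaults to the genetic correlation matrix** (override with
`residual_correlation`, e.g. identity for independent noise). This is a
deliberate design choice: root and shoot size of the same plant covary
environmentally as well as genetically, and an observed phenotypic
root–shoot biomass correlation near 0.9 at H² ≈ 0.77 is arithmetically
impossible with independent residuals (the genotype-mean correlation would
attenuate to ρ·H² ≈ 0.7). Block effects are univariate and independent
across traits — no block-level correlation structure is modelled.

A single seed expands into independent substreams (genotype effects, block
effects, residuals, culling, missingness), so e.g. re-running culling at a
different rate leaves the simulated trait values untouched.

What the generator does **not** emulate: trait-dependent culling (males are
removed independently of their trait values — whether culled males differed
systematically is unknown), neighbour effects of culling-created gaps,
non-normal trait distributions, measurement error structure of image
analysis, or any genotype-by-environment interaction. Passing tests
therefore certify the estimators and the pipeline mechanics under the
additive Gaussian model, not robustness to those violations.

## Problem sizes and numerical choices

The test suite and the acceptance script run the Monte-Carlo studies at
sizes chosen to put sampling noise well inside the asserted tolerances on a
single CPU: 200 replicates per H² level for estimator recovery (±0.05
band), 1000 replicates for type-I error ([0.03, 0.07] at α = 0.05), 100 for
the correlation envelope, 50 balanced datasets for the REML/EMS
equivalence; the acceptance script uses 100/500/50 replicates for the same
quantities. REML uses ftol 1e-14 / gtol 1e-10 and reports components below
10⁻⁹·var(y) as exact zeros. Degenerate inputs are handled explicitly:
constant traits give F with a missing p-value, zero denominators give
missing derived traits, σ²_g = σ²_e = 0 gives missing H², traits with fewer
than three complete pairs give missing correlations.

## Known limitations

- The heritability convention (plot-mean residual) is one of several in
  use; printed H² values from other software may differ by the choice of
  scale and truncation rule, typically within a few hundredths.
- Bootstrap Jaccard values are stochastic; with B = 100 their Monte-Carlo
  SD is a few hundredths, so only coarse comparisons are meaningful.
- The quadrant split depends on the percentile definition at small n; the
  rank-based definition here is principled but not the only reading of
  quantile binning.
- EMS on heavily unbalanced plant-level data is approximate (harmonic-mean
  plot size); REML is preferred there and is the default.
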