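# Methods

## Data model

A plot is a rectangle (default 1.1 × 0.9 m, origin at the lower-left
corner) holding mapped individuals with opaque species labels; an
experiment is the set of plots at two censuses (`t1`, `t2`) plus a map
from shading-treatment name to daily illumination (mol photons m⁻² d⁻¹).
Exactly two censuses are enforced at read time: the change statistics are
defined on one interval, and a multi-census generalization would make the
pairing semantics ambiguous. Plots split into subplots on a configurable
grid (default 3 × 2 = 6 subplots) using half-open cells closed on the max
edges, so boundary individuals are assigned exactly once, to the
higher-index cell.

## Dissimilarity dynamics

Bray–Curtis dissimilarity is computed on raw counts (no standardization or
transformation) over the union of species. ΔB = B_t2 − B_t1 is formed for
every unordered plot pair (grouped same- vs different-treatment) and, at
the subplot level, for pairs of subplots within a plot. Pairs touching an
empty community at either census are excluded and counted, not imputed:
dissimilarity to an empty community is undefined.

Group means are tested against zero with one-sample Student's t tests;
the different-vs-same contrast uses the pooled-variance two-sample t test
(Welch available via a flag); divergence is regressed on the absolute
illumination difference by OLS, reporting slope, R², the slope's two-sided
p and a 95% pointwise confidence band of the fitted mean. The regression
defaults to one point per plot pair; aggregation to treatment-pair means
is available as an option.

**Non-independence.** Each plot enters many pairs, so pairwise ΔB values
are correlated and the plain t tests overstate precision. They are kept
as the field-standard procedure; `block_permutation_test` reshuffles
treatment labels within blocks and re-evaluates the contrast, giving a
design-respecting p value reported separately.

**A bias worth knowing about.** Between finite multinomial samples the
expected Bray–Curtis dissimilarity grows as sample size falls. Any
mortality therefore inflates E[ΔB] above zero even with no ecology —
the second census is a smaller sample. For this reason the type-I-error
calibration of the one-sample test uses an *exchangeable* null
(`simulate_exchangeable_censuses`: both censuses drawn independently at
equal intensity), under which ΔB is symmetric about zero by construction.
Under the generator's thinning null the one-sample test is anticonservative
by design of the statistic, not by a defect of the test; the same-treatment
mean ΔB in any real or simulated experiment should be read with this
sampling-effort effect in mind.

## Pair-correlation analysis

The estimator is the standard kernel form

  ĝ(r) = Σ_{i≠j} e_i(d_ij) κ_h(r − d_ij) / (2πr · λ̂² · |W|)

with Epanechnikov kernel κ_h, pair-intensity estimate λ̂² = n(n−1)/|W|²
(unbiased; switchable to n²/|W|² only by passing weights by hand), and
Ripley's isotropic edge correction e_i: the reciprocal fraction of the
circle of radius d_ij centred on point i lying inside the window. The
closed form intersects the circle with the four bounding half-planes:
the arc beyond an edge at distance d has angular half-width
arccos(min(d/r, 1)); arcs beyond two adjacent edges overlap by
max(0, w_a + w_b − π/2); arcs beyond opposite edges cannot intersect, so
inclusion–exclusion over four edges and four corners is exact for every
r. Unit tests pin this against brute-force arc integration (400k samples
per circle) at 1e-5.

Numerical choices:

- **Bandwidth** defaults to Stoyan's rule h = 0.15/√λ̂. For Δpcf both
  censuses use a single h from the pooled intensity (n₁+n₂)/(2|W|), so the
  difference is not confounded by a bandwidth change.
- **r grid**: 101 points from h to min(width, height)/4 (0.225 m for the
  default window). Below h the 1/r factor makes the estimator unstable;
  beyond a quarter window-side replication, not larger r, carries the
  information. Because the Epanechnikov kernel has zero first moment, the
  estimator is exactly unbiased under CSR away from these limits, which
  the CSR calibration test verifies (mean ĝ within [0.95, 1.05] over 100
  plots of n ≈ 300).
- **Edge-weight guard**: weights are capped at 4 (the corner maximum,
  never exceeded while r ≤ min window side) and pairs farther apart than
  half the window diagonal are excluded and counted — irrelevant under the
  default grid but kept as an explicit validity boundary.
- **Corrections**: isotropic is the default and the one used throughout
  the pipeline; the translation correction (|W| divided by the shifted
  window overlap) and the uncorrected estimator are available as
  cross-checks, and a unit test confirms isotropic and translation agree
  under CSR while the uncorrected estimator is biased low near the border.
- ĝ is species-blind (all individuals of the plot), matching the
  community-level neighbourhood-density usage; marked/cross-type variants
  are out of scope.

Per-plot Δpcf(r) curves on the shared grid are averaged within each
treatment's replicate plots. The default band is the 95% t interval
(mean ± t₀.₉₇₅,ₙ₋₁·SE); a mean ± 1 SD band is available via
`band_type="mean_pm_1sd"` since both conventions circulate for this kind
of figure. The sign rule is strict: "negative" only where the whole band
is below zero, "positive" only where it is entirely above. A consequence
of a 95% band is a ~5% per-radius false-call rate where nothing happens;
calls should be read as curves, not as isolated radii.

## Synthetic experiments

The generator emulates the blocked shading design: `n_blocks` blocks
(default 12), one plot per treatment per block (default treatments
no/low/moderate/strong). Only strong shade has a field illumination value
(10 mol·m⁻²·d⁻¹, typical of regional subtropical understory); 40/30/20
for the lighter treatments are an assumed evenly spaced gradient, chosen
only so pairwise illumination differences are well defined, and are fully
configurable.

Census 1: per-plot counts are Poisson(λ₀|W|) with λ₀ = 47322/48/0.99 ≈
996 m⁻² (so the default experiment starts near the reference size of
~47,000 individuals in 48 plots); species are i.i.d. from a shared seed
bank (lognormal rank-abundance, S = 39 species; uniform available);
positions are CSR by default. The clustered alternative assigns each of
the N points to a uniformly chosen cluster centre (centres Poisson in the
window) plus an isotropic Gaussian offset, resampled until inside the
window — conditioning on N keeps the shared-seed-bank count model intact,
at the price of slight edge-effect deviation from a textbook Thomas
process at cluster scales comparable to the window (negligible for the
default 0.03 m cluster sd).

Census 2 applies one composite Bernoulli survival step

  p_surv = p₀ · F^φ · exp(−c·n_r),  capped at 1,

with F = exp(−(L − μ_s)²/(2σ_s²)) the Gaussian light match (species
optima μ_s uniform over the illumination span, tolerances σ_s uniform on
5–15 mol·m⁻²·d⁻¹) and n_r the number of t1 neighbours within r_c
(default 0.05 m). Neighbour counts are frozen at t1 so individuals are
conditionally independent given the first census — a simultaneous-update
scheme would couple all survival events and defeat exact binomial
oracles. Two censuses cannot identify anything finer than one composite
step. Defaults φ = 0.4, c = 0.015, p₀ = 0.95 were calibrated so expected
overall survival ≈ 0.59, matching the reference experiment's decline
(47,322 → 28,037 individuals); recruitment (re-draws from the seed bank)
exists but is off by default, since no mechanism is specified for it.
With φ = c = 0 the step is exact binomial thinning; that limit anchors
the generator's own tests (survival fractions inside binomial bands,
Δpcf centred on zero).

What the generator does *not* emulate: spectral light composition, soil
covariates, plant size/age structure, immigration, and any within-plot
environmental heterogeneity. Passing recovery tests therefore shows the
*statistical machinery* detects filtering and crowding signals of
plausible magnitude under the stated design — not that field data of this
kind are free of the confounders the design itself cannot remove.

## Problem sizes in the shipped checks

The acceptance checks run the full 48-plot design for design constants and
the filtering/competition recoveries; estimator calibration uses 100 CSR
plots of n ≈ 300; the t-test null uses 1,000 replicate experiments of
12 blocks × 2 treatments at n ≈ 150 per plot; band coverage uses 40
replicate experiments of 12 plots at n ≈ 300. These sizes give Monte-Carlo
error comfortably inside the asserted bands while keeping the whole suite
in well under a minute of compute per check.

## Known limitations

- The t tests on pairwise ΔB inherit the non-independence issue above;
  the permutation p value is the safer inferential quantity.
- ĝ at r close to the bandwidth has inflated variance for sparse plots
  (n below ~50); plots with < 2 points at a census are excluded from
  Δpcf with a logged reason rather than imputed.
- The generator's facilitation branch (c < 0) caps p_surv at 1, so strong
  facilitation saturates instead of amplifying.
- Pielou evenness is undefined (reported NaN) for single-species
  communities.
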