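# understory

Tools for asking whether **light acts as an environmental filter** on forest
understory grass communities, and whether **biotic interactions** (competition
or facilitation between neighbouring plants) are at work alongside it — from
mapped, twice-censused plot experiments arranged in a randomized block design
of shading treatments.

The package is aimed at plant community ecologists running (or simulating)
shading experiments in which many small plots regenerate from one shared,
homogenized soil seed bank, every individual is identified and mapped at a
first and a second census, and plots differ only in the illumination they
receive.

## The two statistics

**Compositional divergence.** For communities *j* and *k* with species
abundance vectors, the Bray–Curtis dissimilarity is
B(j,k) = Σᵢ|xᵢ − yᵢ| / Σᵢ(xᵢ + yᵢ). The change across censuses,

> ΔB(j,k) = B_t2(j,k) − B_t1(j,k),

is positive when two communities became more dissimilar. If light filters
species, plots under *different* shading treatments should diverge
(ΔB > 0, tested with a one-sample Student's t test), plots under the *same*
treatment should not, the different-vs-same contrast should be positive
(two-sample t test), and the size of the divergence should grow with the
pairwise illumination difference (OLS regression of ΔB on |Δlight|, with a
95% pointwise confidence band). Because pairwise ΔB values share plots, a
blocked permutation test (treatment labels reshuffled within blocks) is
available as a robustness check.

**Neighbourhood-density change.** The pair correlation function g(r) is the
expected density of further individuals at distance r from a typical
individual, standardized by the mean density, so g ≡ 1 under complete
spatial randomness. It is estimated per plot with an Epanechnikov-kernel
estimator and Ripley's isotropic edge correction on the rectangular window.
Because g is a *relative* density it is insensitive to how many individuals
died overall; only *scale-dependent* mortality moves it. The change

> Δpcf(r) = pcf_t2(r) − pcf_t1(r),

averaged over a treatment's replicate plots with a 95% t confidence band
(or a mean ± 1 SD band), classifies each distance: band entirely below zero →
negative interactions (competition); entirely above → positive
(facilitation); otherwise no call.

A fully seed-deterministic synthetic-experiment generator (shared seed bank,
Gaussian light-niche mortality with strength φ, crowding mortality
`exp(−c·n_r)` within radius r_c) provides ground truth for every stage:
with φ > 0 the ΔB machinery must detect divergence scaling with light
difference, with c > 0 the Δpcf machinery must call competition at r ≤ r_c.

## Worked example

```bash
understory simulate --seed 4 --out demo.csv
understory analyze --census demo.csv --outdir out --seed 4
understory report --outdir out
```

which prints (abridged):

```
wrote demo.csv: 48 plots, 47441 individuals at t1, 28095 at t2 (seed 4)

Dissimilarity-change tests:
                        test                group    n  mean_delta_B         t     df             p
                  one_sample       same_treatment  264      0.021986 23.496312  263.0  1.502978e-66
                  one_sample  different_treatment  864      0.190635 66.106515  863.0  0.000000e+00
                  one_sample within_plot_subplots  720      0.051852 34.697995  719.0 9.598808e-156
two_sample_different_vs_same    different_vs_same 1128      0.168649 32.160134 1126.0 1.671872e-161

Regression of delta_B on illumination difference:
   slope  intercept  r_squared   p   n
0.010826   0.010198   0.907311 0.0 864

Interaction calls per treatment (count of radii):
classification  negative  none  positive
treatment
low                   18    83     0
moderate              17    82     2
no                    10    91     0
strong                 5    93     3
```

Reading it: the default synthetic experiment (12 blocks × 4 shading
treatments, 48 plots of 1.1 × 0.9 m, ~47k seedlings thinning to ~28k) has
light filtering switched on, so different-treatment plot pairs diverged much
more (mean ΔB ≈ 0.19) than same-treatment pairs (≈ 0.02), the contrast is
overwhelming (t ≈ 32 on 1126 df), and divergence rises by ≈ 0.011 per
mol·m⁻²·d⁻¹ of illumination difference (R² ≈ 0.91). Mild default crowding
produces a handful of "negative" small-r interaction calls in every
treatment. `out/` also holds per-pair records, per-plot diversity changes
(Shannon, Gini–Simpson, Pielou), the Δpcf band tables and a JSON manifest
that reproduces the run bit-for-bit.

The same `analyze` command accepts any census CSV with columns
`plot_id,block_id,treatment,census,species_id,x,y` (censuses labelled
`t1`/`t2`; window size and treatment→illumination map in a
`<name>.meta.json` sidecar or passed programmatically).

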