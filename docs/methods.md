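# Methods

## Scope and data model

The package operates downstream of denoising: its inputs are a feature
table of exact-sequence-variant counts (samples × taxa, non-negative
integers), a rooted phylogeny whose leaves cover the table's taxa, and
sample metadata with `year`, `location`, `condition ∈ {uninvaded, invaded,
rhizosphere}` and `plot`. `(year, location)` pairs define the blocking
structure for all restricted permutation schemes. Readers accept plain and
BIOM-style TSV (taxa-as-rows input is transposed on read; the canonical
internal orientation is samples-as-rows), newick with branch lengths
(missing lengths become 0 with a warning), and a three-column-plus
metadata TSV. Counts are integers throughout; rarefied tables are integer
by construction.

## Rarefaction and diversity

Rarefaction subsamples each sample to a common depth `N` without
replacement — an exact multivariate-hypergeometric draw — once per
analysis, with the seed recorded in output headers (multi-draw averaging is
available as an option but not the default). Samples below depth are
dropped before rarefying, and the omitted IDs are reported. The default
depth is 4,000 reads.

Alpha diversity: observed richness; Shannon entropy in bits (base 2
default, configurable and recorded); Pielou evenness `H′/log S`, undefined
below two observed taxa; Faith phylogenetic diversity including the
root-connecting path (the dominant toolchain convention), with an
`include_root=False` variant for comparison. Beta diversity: weighted
UniFrac, unnormalized by default with the normalized variant exposed, and
Bray-Curtis. Phylogenetic metrics delegate to scikit-bio and are verified
against hand-computed fixtures in the test suite.

## Nested blocked PERMANOVA

Terms are nested cumulatively (Year, then Location within Year, then
Condition within Location and Year), so the k-th hat matrix is the group
projection of the distinct combinations of the first k factors, and the
sequential (Type-I) sums of squares are differences of traces `tr(H_k G)`
of the Gower-centered matrix `G`. Degrees of freedom follow the group
counts; for the two-year, six-locations-per-year, 2/3-condition survey they
are 1, 10, and 18 regardless of a handful of dropped samples. Pseudo-F per
term uses the residual mean square. p-values recompute every term's F under
permutations restricted to within-(year, location) blocks, the same
permutation stream for all terms, with `p = (1 + #{F* ≥ F}) / (1 + n_perm)`
(n_perm default 999). Terms at or above the block level are structurally
invariant under within-block exchange; their reported p-values derive only
from the permuted residual and should be read accordingly — the test is
designed for the within-block condition effect. Marginal (Type-III) sums of
squares are out of scope.

## Dispersion (PERMDISP) and ordination

Samples are embedded by principal coordinates of `G`; negative eigenvalues
are kept as an imaginary subspace, and squared distances to group centers
subtract the imaginary component (floored at zero) rather than truncating
axes. Centers are spatial medians by default (Weiszfeld iteration,
computed separately in the real and imaginary subspaces), with centroids
optional. The F statistic on distances has `(k−1, n−k)` degrees of
freedom; its p-value permutes group labels over the computed distances —
freely by default, within blocks if requested, since the blocking choice
for dispersion is genuinely open; the free default is calibrated (null
p-values are KS-uniform in the test suite).

NMDS is rank-based stress-1 minimization (scikit-learn's SMACOF with
isotonic regression), best of 20 random restarts, `k = 3` by default;
non-convergence sets a flag rather than raising. Reported stress is
cross-checked in tests against an independent stress-1 recomputation from
the returned coordinates.

## Univariate statistics

Kruskal-Wallis (tie-corrected, χ² p on k−1 df, H = 0 and p = 1 when all
values are identical), Spearman rank correlation (NaN when either vector is
constant), and condition contrasts for alpha diversity from a REML linear
mixed model with a random intercept per location, each year modeled
independently. Pairwise condition contrasts are Tukey-adjusted via the
studentized-range distribution on an approximate residual df
(`n − k − (#locations − 1)`); with a single location the random effect is
dropped (warning) and the model reduces to OLS, where the two-condition
case reproduces the two-sample t-test. This residual-df approximation is
coarser than Satterthwaite but calibrated in the test suite (≥90% of null
replicates show no significant contrast).

## Neutral model

Occupancy is the fraction of samples with count > 0 after rarefaction; the
detection limit is `d = 1/N` with `N` the uniform rarefaction depth. Mean
relative abundance has two conventions: `occupied_only` (mean over samples
where the taxon occurs — the configuration default, matching the
occupancy-abundance literature's phrasing) and `all_samples` (mean over
every sample — the convention of the widely used reference code). The two
estimate different quantities: conditioning on presence bounds every
taxon's abundance at `≥ 1/N`, which destroys the abundance signal of rare
taxa, so **parameter recovery and the pipeline's fitted migration rates use
`all_samples`**; `occupied_only` is retained for descriptive
occupancy-abundance tables.

The migration rate is fit by bounded scalar least squares on
`m ∈ [10⁻⁶, 1]` with multi-start brackets at {0.001, 0.01, 0.1, 0.5}
(tolerance 10⁻¹⁰; hitting a bound is flagged). R² is computed against the
mean-occupancy null and may be negative. The prediction band is the Wilson
score 95% interval at the study's sample count by default; a ±2·SD binomial
band reproduces the plotted-band convention, and both are reported where
they disagree.

**Known approximation limit.** The beta-tail prediction treats detection as
a threshold on the latent frequency (`π > 1/N`), while read sampling
detects a taxon with probability `1 − (1−π)^N`. At large `N·m` this
smooths the occupancy curve and biases the fitted `m̂` upward — about +20%
at `m = 0.05` and +30% at `m = 0.1` with `N = 4000`, negligible for
`m ≤ 0.01`. This is a property of the standard fitting formula, not of the
implementation; the median relative recovery error across the soil-relevant
grid `m ∈ {0.005, 0.01, 0.05, 0.1}` stays near 12%. Two-parameter or
likelihood-based variants that model read sampling explicitly are out of
scope.

## Core selection

Ranking is fully deterministic: occupancy descending, ties by mean relative
abundance descending, remaining ties by taxon ID. Contributions to
Bray-Curtis use the fixed full-pair denominator so they are additive and
the cumulative curve `E_k` ends at exactly 1; the mean over sample pairs is
unweighted over all unordered pairs. `Δ_k = (E_k − E_{k−1})/E_{k−1}` is the
relative increase; the core is the prefix admitted while `Δ_k ≥ 0.05`,
stopping at the first failure (later large increments are not
reconsidered). The first-ranked taxon always anchors the core: its own
share `E_1` is typically ~1% in a diverse community, so requiring
`E_1 ≥ threshold` would empty every core; a warning notes when the anchor
itself falls below the threshold. An alternative reading of the 5% rule —
absolute percentage points rather than relative increase — is not mixed in.
Over-occupant core members are the set intersection of the core prefix with
the neutral partition's "above" taxa; class-level aggregation sums mean
relative abundances by the third semicolon-delimited lineage field, mapping
missing or truncated lineages to "Unclassified".

## Synthetic-community generator

The generator emulates the survey the analysis assumes: year one, six
locations × {uninvaded, invaded} × 10 plots; year two, six further
locations adding rhizosphere plots (300 samples total, optional omissions
emulating failed libraries), 4,000 reads per sample.

* **Metacommunity:** lognormal rank-abundance profile (σ = 2 by default, a
  typical soil survey dominance structure), normalized and sorted.
* **Local assembly:** per sample, latent frequencies from the Sloan beta
  law at the condition's migration rate, then a single multinomial read
  draw so every row sums exactly to `N`. Default migration rates
  (0.043 / 0.050 / 0.042 for uninvaded / invaded / rhizosphere) sit in the
  fitted bacterial-soil range.
* **Location signal:** per-location Dirichlet perturbation of the
  metacommunity (concentration 500 × p), keeping taxa shared across
  locations while letting their proportions vary — chosen once so that
  location explains several-fold more variance than condition, matching the
  survey's variance ordering.
* **Condition effect:** invaded and rhizosphere cells share one
  multiplicative lognormal shift (scale 0.3); invaded cells are additionally
  homogenized by scaling the effective `N·m` so the between-sample
  frequency SD shrinks by the contraction factor (0.7 default), which
  leaves per-taxon mean composition unbiased.
* **Selected taxa:** 25 mid-occupancy taxa (predicted occupancy 0.2–0.6)
  have their reads redistributed evenly over `min(1, 2 × ô)·n` samples —
  occupancy rises, total abundance is conserved, isolating the
  over-occupancy signal from differential abundance. An inflation factor of
  exactly 1 is a no-op.
* **Seeds:** one master seed; every stage derives a child generator via
  `SeedSequence(master, spawn_key=(stage, extra))`, so any stage is
  independently reproducible.

What the generator does **not** emulate: PCR/primer bias, chimeras and
denoising artifacts, taxon-taxon interactions, temporal autocorrelation
between years, overdispersion beyond the neutral beta, and the low-R²
regime of fungal fits (a non-neutral fraction can be emulated via injected
taxa, but no mechanism is claimed). Passing tests therefore demonstrate
correctness of the statistics under neutral-plus-effects sampling, not that
real soil data satisfy those assumptions.

## Problem sizes and numerical choices

Tests and the acceptance script run the recovery experiments at the survey
scale (5,000 taxa × 120 samples × depth 4,000; 20 seeds per migration rate
in the test suite, 8 in the acceptance script) and the calibration nulls at
a reduced scale (200 taxa × 60 samples, 199 permutations, 200 replicates)
— the null distribution of a permutation p-value is pivotal, so the
reduced scale tests the same uniformity property at a fraction of the
cost. Permutation p-values use the +1 convention and a 10⁻¹² tie tolerance
on F comparisons; beta parameters are floored at 10⁻¹² before sampling;
Dirichlet concentrations at 10⁻⁸; Weiszfeld iterations stop at 10⁻¹⁰
movement or when the median coincides with a data point. Degenerate inputs
(all-identical tables, zero-read samples, saturated designs, single
locations) raise informative errors or reduce to documented fallbacks
rather than producing silent numbers.
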