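# Methods

This note documents the statistical machinery, the synthetic data model,
the numerical choices, and the limitations of `elevdiv`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Sampling designs and the transect bootstrap

The pipeline targets a two-design elevational survey: a *replicate
strategy* (r plots at each of k bands; defaults r = 5, k = 6) and a
*transect strategy* (one plot at each of K bands; default K = 16), sharing
plots at the replicated bands. Because the replicated bands offer a choice
of plot, the single-plot design is not one dataset but a product space
(r^k = 15,625 under the defaults). `draw_combinations` samples `n_boot`
(default 1000) combinations uniformly and independently, **with**
replacement across combinations — collisions are rare at 1000 ≪ 15,625 and
with-replacement keeps every draw exchangeable.

Aggregation (`bootstrap.aggregate`): numeric coefficients are averaged with
an SD; every named p-value field is Benjamini–Hochberg corrected **across
the n_boot values of that field** and then averaged; categorical outcomes
(selected predictor sets) are tallied. The BH family choice — one field at
a time, across combinations — is recorded in the summary object, since
other families (e.g. across q-orders within a combination) are defensible
but answer a different question. The single replicate-strategy fit has no
such family and its p is reported uncorrected.

## Hill numbers and rarefaction/extrapolation

`hill_number` implements ^qD = (Σ p_i^q)^{1/(1−q)} with the q→1 limit
exp(−Σ p ln p) evaluated explicitly; continuity at q = 1 is tested to
1e-4 at |Δq| = 1e-6.

`rarefy_abundance` provides the size-based estimators for q ∈ {0, 1, 2} at
target size m from a count vector x with n = Σx:

- **q = 0, m ≤ n**: exact hypergeometric interpolation
  S(m) = Σ_i [1 − C(n−x_i, m)/C(n, m)], evaluated with log-gamma.
- **q = 0, m > n**: S(n+m*) = S_obs + f̂₀(1 − (1 − f₁/(n f̂₀ + f₁))^{m*})
  anchored on the singleton/doubleton counts, with the bias-corrected
  f̂₀ = ((n−1)/n) f₁²/(2f₂), falling back to ((n−1)/n) f₁(f₁−1)/2 when
  f₂ = 0.
- **q = 1, m ≤ n**: the exact expectation of the subsample entropy,
  E[−Σ (X_i/m) ln(X_i/m)] with X_i hypergeometric, summed over the support
  and grouped by distinct count values; the estimate is exp of it.
- **q = 1, m > n**: exp of a size-weighted blend
  (n/m)·H_obs + (m*/m)·Ĥ_∞ of the observed entropy and the
  Chao–Wang–Jost asymptotic entropy estimator, which is continuous at
  m = n and approaches the asymptotic estimate as m grows.
- **q = 2, any m**: 1/(1/m + (1 − 1/m) Σ x_i(x_i−1)/(n(n−1))) — a single
  unbiased formula that covers interpolation, the observed point and
  extrapolation and reduces to the observed inverse Simpson at m = n.

Extrapolation is reliable to about twice the reference size and is capped
at 2n (2T for incidence) by default. The incidence estimator
(`rarefy_incidence`, q = 0) mirrors the abundance case with sampling units
T and incidence frequencies Y_j, using the Chao2-type Q̂₀.

The common alpha target defaults to **2× the minimum sequencing depth**
(the depth floor 3834 used by the simulator gives m = 7668), which
maximises retained information: every sample is either interpolated or at
most doubled.

Oracles in the test suite: exhaustive enumeration for tiny cases (counts
(2,1) at m = 2 → 5/3; 3-sample incidence at t = 2), Monte-Carlo
subsampling (10,000 draws, 3 SE) for all three orders, and R's
`vegan::rarefy` for q = 0 interpolation.

## Alpha regressions and ANCOVA

Per q and strategy, per-sample Hill estimates are regressed on elevation by
OLS (two-sided t-test for the slope). Strategy comparison stacks the two
datasets with an indicator and fits
`estimate ~ elevation + strategy + elevation:strategy`; the interaction p
is the reported ANCOVA p. The six replicated-band plots contribute to both
strategies — pseudo-replication inherited from the design, kept
deliberately because the bootstrap reuses replicate-band samples by
construction. Under equal slopes the interaction p is uniform (KS-tested
over 500 simulations).

## Beta diversity

Dissimilarity is Bray–Curtis, d(x,y) = Σ|x−y|/Σ(x+y), on
Hellinger-transformed data (square root of relative abundances), so
distances depend only on composition, never on depth. PCoA applies Gower
double-centring and an eigendecomposition; axes with positive eigenvalues
carry coordinates, negative eigenvalues are reported and logged but not
corrected (no Lingoes/Cailliez), matching common practice for Bray–Curtis.

PERMANOVA follows the McArdle–Anderson trace formulation: with G the
Gower-centred matrix of −d²/2 and H_k the hat matrices of the cumulative
design (intercept; + elevation, standardized continuous; + habitat
indicator; + interaction), sequential SS_k = tr(H_k G) − tr(H_{k−1} G),
pseudo-F per term against the residual, R²_k = SS_k/SS_total. p-values come
from free permutation of sample identities (default 999; p = (hits+1)/
(n_perm+1)), applied by conjugating G, with all permutations evaluated in
one einsum batch. `exact=True` enumerates all n! permutations (guarded at
n ≤ 8) and reports the exact tail fraction. Permutations that merely swap
replicates within a band reproduce the observed F exactly; ties are
counted as hits with an absolute tolerance of 1e-8 on F. Agreement with
`vegan::adonis2(by="terms")` is exact (SS/R²/F to 1e-6) in the suite.

Elevation decay regresses all within-habitat pairwise dissimilarities on
elevation separation and bins pairs by their nominal band interval (0 m =
within-band pairs; forest multiples of 100 m, alpine of 160 m under the
default design). One-way ANOVA across classes is followed by Tukey HSD
contrasts of each class against the within-band class. Pairs share samples,
so these tests inherit non-independence from the design; they describe the
pattern rather than provide strictly valid inference, and are used the same
way in the bootstrap comparisons. Habitats are analysed separately because
their nominal intervals differ.

## Environmental RDA

- **VIF** per column: 1/(1−R²_j) from OLS of column j on the rest (with
  intercept); exact collinearity is flagged as ∞, not an error.
- **OM_pc1**: the organic-matter block (SOM, TOC, TON, WC) mixes units, so
  PCA runs on standardized columns (correlation-matrix PCA); PC1 is
  sign-fixed to correlate positively with SOM and its variance share is
  reported (≈ 0.98 for the default simulator, where the block shares one
  latent).
- **RDA**: response = Hellinger-transformed relative abundances, centred
  column-wise (transformation-based RDA, consistent with the
  beta-diversity metric); predictors standardized so contributions are
  scale-free; R² = ‖projection‖²/‖Y_c‖², adjusted by Ezekiel:
  adjR² = 1 − (1−R²)(n−1)/(n−m−1). Wide responses are first compressed to
  their SVD row-space scores — exact for every R²-based quantity and a
  large constant-factor saving in the bootstrap loop.
- **Stepwise selection**: forward steps add the candidate with the largest
  adjusted-R² gain (ties by name), admitted only if (a) its partial
  pseudo-F passes a Freedman–Lane permutation test (residuals of the
  reduced model permuted; default α = 0.05, 999 permutations, 199 inside
  the bootstrap loop) and (b) the new model's adjusted R² does not exceed
  the adjusted R² of the model containing every candidate (the ceiling
  rule). Backward elimination then drops terms whose removal is not
  significant, least significant first. The ceiling's penalty uses the
  *effective rank* of the design, so duplicated or collinear candidates do
  not distort it. With one dominant predictor among pure noise the
  one-variable model can legitimately exceed the all-candidate adjusted R²
  and the forward phase stops — a documented property of this criterion,
  exercised in the tests. An empty selection is a valid outcome. Under
  pure-noise candidates the family-level false-selection rate stays near
  the nominal α.
- **Hierarchical partitioning**: over all 2^m predictor subsets (guarded
  at m ≤ 8), individual_j = Σ_S w(|S|)[adjR²(S∪j) − adjR²(S)] with
  hierarchy weights w(s) = s!(m−s−1)!/m!, and unique_j = adjR²(full) −
  adjR²(full∖j). The individual contributions sum to the full-model
  adjusted R² to machine precision (telescoping identity). Negative shared
  variance (suppression) makes unique exceed individual. On the adjusted-R²
  scale the small-sample penalty shifts the order-averaged terms, so
  "orthogonal ⇒ individual = unique" holds exactly only on the raw-R²
  scale; `adjusted=False` exposes that mode, and the default matches the
  adjusted-scale convention of the hierarchical-partitioning literature.

## Synthetic data model

`simulate_community` draws from a coenocline: species i has an elevation
optimum (3000-species pool, optima spread uniformly over the gradient ± 2
niche widths) and a Gaussian response exp(−(e−opt_i)²/2σ²) with σ = 300 m.
At each band the pool is thinned to the top-S(e) species by response
weight, where S(e) = 450 − 0.12·e follows the configured richness line —
this makes expected richness exactly the target and turnover deterministic,
at the cost of a sharper community edge than a pure Gaussian model.
Per-species lognormal "commonness" (sd 0.3) unevens abundances mildly.
Replicates within a band perturb log-abundances with sd 1/√c (concentration
c = 6, so sd ≈ 0.41) — lognormal overdispersion rather than spatially
explicit micro-habitats. Counts are multinomial at lognormal depths
(meanlog 9.2, sdlog 0.45 — median ≈ 10,000 reads) floored at 3834.

The environment table derives the OM block from a single latent that
declines logistically above the treeline; each of SOM/TOC/TON/WC is an
affine transform of the latent plus independent noise whose variance is
calibrated so the *population* pairwise correlation is
target + 0.3(1−target) (default target 0.96), keeping finite-sample
correlations above target − 0.02 at n ≥ 30. pH follows its own declining
exponential latent; P is lognormal with a mild elevational trend; C/N and
N/P are computed from their components, so ratio-consistency is testable.
`GroundTruth` records the richness line, the niche breadth, the initial
Bray–Curtis turnover rate per metre of the noise-free band expectations,
and the environment coefficients.

What the generator does **not** emulate: taxonomic composition (no
lineages are attached, so the micro-eukaryote filter is exercised on
hand-made tables), spatial autocorrelation within plots, sequence-level
error/chimeras, hump-shaped richness profiles, habitat-specific species
pools beyond the gradient itself, and heavy rare-species tails — per-sample
detection is nearly complete at the default depths, which makes the
richness-recovery tests sharper than field data would be. Passing tests
demonstrate correctness of the estimators and the design comparison under
this model, not robustness to every property of real soil eDNA.

## Problem sizes and runtime in the shipped checks

The test suite (~1.5 min) uses: 10,000-draw Monte-Carlo rarefaction
oracles; 500 structureless PERMANOVA null datasets (n = 40, 999
permutations) for type-I calibration; exact 720-permutation enumeration at
n = 6; 20 simulator seeds × 1000 transect combinations for slope recovery
and ANCOVA; 20 seeds × 100 combinations for the gamma/decay design-effect
checks; 200 pure-noise selection runs. `scripts/acceptance.py` runs the
full pipeline once at study scale (40 samples, 1000 combinations, 999
permutations, 199 inside the selection loop) in well under a minute.

## Reproducibility

All randomness flows from a single master seed through
`numpy.random.SeedSequence` children, one per stage and per bootstrap
combination, so stages can be re-run independently and two runs of
`run_full` with the same configuration produce byte-identical bundles (the
manifest records config, seeds, and a config hash; the output directory
itself is excluded from the manifest for exactly this reason).
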