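# Methods

This note documents the models and estimators implemented in `ripdiv`,
the defaults and their units, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Data model

Five inputs define a study: a site × species abundance matrix (integer
point-count totals), a species × trait table with declared per-column
types (continuous / ordinal / categorical), a rooted phylogeny with
branch lengths over the species pool, a site table (elevation in masl,
river identity, river direction, nine environmental columns), and a
species → conservation-weight map with weights in {1, 4, 8}. Species
name spaces are reconciled by exact string match after whitespace
trimming; the intersection across all tables is taken and discards are
logged — fuzzy matching is deliberately not attempted because a silent
misjoin is worse than a dropped species. Species detected at fewer than
3 sites are removed before analysis (configurable), a standard guard
against unstable metrics for rarely detected species. Quadrat-level
microhabitat measurements may be supplied as a long table and are
reduced to site means; the pipeline proper always works at site level.

## Diversity metrics

**Shannon index.** `H' = −Σ pᵢ log pᵢ` over within-site abundance
shares, log base 2 by default (bits). The base is configurable; base 2
is the package default because it keeps `H'` comparable with richness
through `H' ≤ log₂ S` at the typical richness of these surveys. Empty
sites get `H' = 0` with a warning, never NaN.

**Trait space and FRic.** Mixed-type traits enter a Gower
dissimilarity: continuous traits contribute `|xᵢ − xⱼ| / range`,
ordinal traits the same on ranks, categorical traits a 0/1 mismatch,
averaged over traits non-missing in both members of a pair. A
zero-range trait contributes 0 (warned). The matrix is embedded by
principal coordinates; if the smallest eigenvalue is below
`−1e−8 · λ_max` (Gower matrices are generally non-Euclidean) a Lingoes
additive correction (`d'² = d² + 2c`, `c = −λ_min`) is applied first
and recorded. FRic at a site is the convex-hull volume of its species
on the first `m` axes, divided by the pool hull volume, so values lie
in [0, 1]; the raw volume is also reported. FRic is computed on
presence only — hull volume is abundance-invariant by definition, so
"abundance-weighted FRic" is not a meaningful object; this caveat is
deliberate and documented here rather than hidden.

*Axis count.* By default `m = min(m_retained, S_min − 1)` so every site
can in principle form a hull, which fails loudly when any site has a
single species. The pipeline instead fixes `m = 2` (configurable):
sites with fewer than `m + 1` species, or with degenerate (collinear)
coordinates, get undefined FRic and are logged and dropped from the
FRic smooths — with ~47-species pools and sites down to S = 1, refusing
to compute FRic anywhere because of one species-poor site would be the
wrong trade.

**Faith's PD.** The branch-length sum of the minimal subtree spanning
the site's species. The root is included by default (a one-species site
already accrues its root-to-tip path), matching the common convention
of comparative-ecology software; `include_root=False` excludes the
edges above the species' MRCA. Internally every edge carries the set of
tips below it, so PD for any species set — and for thousands of null
randomizations at once — is a masked sum over the edge-length vector.

## Null model and SES

Raw FRic and PD correlate strongly with richness, so both are
standardized against a null that holds each site's richness fixed: the
site's S species are redrawn uniformly without replacement from the
regional pool (all species in the matrix) and the observed positive
abundances are reassigned to them in random order. Per-site richness
and the per-site abundance multiset are conserved *exactly*, by
construction, in every draw. Species occurrence frequencies are *not*
constrained — the scheme is the plain "richness" null, chosen because
it is the simplest null consistent with richness constancy; this is a
declared choice, not an inference. Default 1000 replicates;
`ses = (observed − null mean) / null SD`, undefined (with warning)
where the raw metric is undefined or the null SD is zero. A decoupling
report gives the Pearson correlation of each raw and standardized
metric with S, with the conventional `|r| < 0.10` flag evaluated and
reported, never enforced.

## Phylogenetic signal

Blomberg's K compares the ratio of the ordinary trait variance (about
the phylogenetically weighted ancestral mean `â = (1ᵀV⁻¹x)/(1ᵀV⁻¹1)`)
to the V⁻¹-weighted variance, against the expectation of that ratio
under Brownian motion, `[tr(V) − n/(1ᵀV⁻¹1)]/(n − 1)`, where `V` holds
shared root-to-MRCA path lengths. K = 1 under BM; the star tree with
equal branches gives K = 1 identically, which the tests use as an
analytic anchor. Significance comes from permuting trait values across
tips: `p = (1 + #{MSE_perm ≤ MSE_obs}) / (n_perm + 1)` with 1000
permutations by default. V⁻¹ is applied through a Cholesky solve; a
ridge of `1e−10 · tr(V)/n` is added only if the factorization fails.
Ordinal traits are rank-scored before the test; categorical traits are
one-hot encoded and projected on the first principal component of the
indicator matrix (deterministic sign). That scalar reduction is a
convention — K for categorical traits should be read as a rough screen,
and the package logs the encoding whenever it is used.

## Conservation value index

`CVI = Σ log₁₀(aᵢ + 1) · eᵢ` over species present at a site, with
abundance `aᵢ` and weight `eᵢ` = 1 (unprotected), 4 (class II) or 8
(class I). Log base 10 is the default — a site holding a single
unprotected individual then scores log₁₀ 2 ≈ 0.301 — and the base is
configurable. The index is additive over species and monotone in both
abundance and protection class; a per-species breakdown table
accompanies the site values.

## Elevation smooths

Each diversity facet is regressed on elevation with a cubic B-spline
basis (k = 5 functions by default; ~10 sites per river cannot support
more) and an exact curvature penalty `∫ B''ᵢ B''ⱼ dx`, whose null space
is exactly the straight lines — so an exactly linear signal is
reproduced to machine precision regardless of the smoothing parameter.
Elevation is internally rescaled to [0, 1] to keep the penalty well
conditioned. River identity and river direction enter as *shrunken*
random intercepts inside the same penalized least-squares problem; the
spline wiggles and both intercept sets are Gaussian random effects
whose variance ratios are chosen by REML (Nelder–Mead on the profiled
criterion), with a GCV fallback if REML is degenerate and an explicit
shrink-to-null-space shortcut when the response lies exactly in the
penalty null space (zero residuals leave REML undefined). One coherent
estimator, rather than a two-stage smooth-then-mixed-model fit, was
chosen because the two stages otherwise disagree about what counts as
residual variance. The smooth's effective degrees of freedom lie in
[1, k − 1] (1 = linear). Fitted curves with pointwise 95% intervals are
exported on a 1-masl grid; the peak locator takes the argmax on that
grid (ties to the lowest elevation) and classifies a boundary argmax as
"monotone". The CVI–elevation relationship is fitted separately as a
Gaussian polynomial GLM (degree 2 by default) with its own interval.

## Driver inference

The nine environmental columns are screened by stepwise VIF removal:
while any VIF ≥ 4, drop the single worst predictor and re-fit (each
removal logged with its VIF). Every subset of the retained predictors
(2^p models, guarded at p ≤ 15) is then fitted as a Gaussian linear
mixed model with a random intercept for river identity. River direction
is *not* a second random effect here: with six rivers it is confounded
with river identity, and estimating two nested variance components from
six groups is not defensible. Predictors are z-scored so estimates are
comparable across subsets.

The mixed model is estimated by maximum likelihood profiled over the
residual variance, leaving a bounded one-dimensional search over
`θ = σ²_river / σ²_resid`; with a single grouping factor the marginal
covariance can be whitened exactly per group
(`(I + θJ)^{−1/2} = I − c/m · J`), so each likelihood evaluation is an
ordinary least squares solve. This keeps the full 2^9 model sweep under
a second, and the fitter agrees with `statsmodels.MixedLM` on the same
data (checked in the test suite). `AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`
with k counting fixed effects plus the two variance components. Models
with ΔAICc ≤ 2 form the top set; averaging is *full* (zero
substitution: a model that lacks a predictor contributes an estimate of
0), which shrinks weakly supported effects — conditional averaging is
available by flag. Unconditional SEs combine within-model variance and
between-model spread; p-values use the normal approximation; relative
importance is the summed renormalized weight of the top-set models
containing the predictor.

## Synthetic data generator

The generator emulates the *structure* of a six-river submontane
survey, not any particular species list:

- **Sites:** 6 rivers × 10 sites, elevations evenly spaced over
  481–912 masl. Habitat-heterogeneity columns (land-cover patches
  `Lnum`, vegetation height variability `H_SD`, `Sinuosity`, `Forest`)
  follow Gaussian bumps centred on the configured richness peak
  (700 masl); fluvial size columns (`Width`, `Bar`) decline upstream;
  sinuosity is constructed ≥ 1. Noise scales with `noise_sd`
  (default 1).
- **Phylogeny:** Yule (pure-birth) tree, rate 1.0 per lineage; after
  the n-th lineage appears the tree is extended by one further
  exponential waiting time so every terminal branch is strictly
  positive. Pure birth is the simplest process with the right shape;
  the rate only sets the depth scale, which K is invariant to.
- **Traits:** six traits from independent Brownian motions on the tree
  (rate 1.0 per unit branch length); ordinal and categorical traits
  discretize latent BM traits at empirical tertiles, so all six carry
  phylogenetic signal.
- **Communities:** each species draws a niche optimum from
  N(700, 90²) masl and occupies a site with probability
  `0.30 · exp(−(elev − opt)²/(2·120²))`; abundances of present species
  are zero-truncated Poisson (rate 1.6). These values were chosen once
  to give realistic survey numbers — site richness averaging ~7–8 with
  range ≈ 1–20 of a 47-species pool and ~900 individuals in total — and
  a realized richness hump at the configured peak.
- **Conservation status:** weights drawn with probabilities
  (0.85, 0.10, 0.05) over {1, 4, 8}.
- **Driver responses:** `simulate_driver_response` builds a Gaussian
  response with known standardized effects (default 0.8 on Forest,
  H_SD, Lnum and Sinuosity), river intercepts (sd 0.3) and unit
  residual noise. The 0.8 effect size is the generator's definition of
  a "true driver": strong enough that the averaging pipeline should
  recover it reliably (measured ≥ 90% detection at n = 60) while null
  predictors stay at their nominal false-positive rate. Weaker effects
  are of course legitimate inputs; they simply sit in the regime where
  model-averaging shrinkage trades power for fewer false claims.

All randomness flows from one integer seed through per-component child
streams, so adding draws to one component does not perturb the others,
and the same seed reproduces every output file byte for byte.

**What the generator does not emulate:** real trait distributions or
trait–niche correlations, detection error (presence means detected),
spatial autocorrelation along a river beyond the shared elevational
response, species interactions, and occurrence-frequency structure in
the regional pool. Passing tests therefore demonstrate that the
estimators are correct and calibrated under the stated generative
model — not that any particular field system satisfies that model.

## Numerical conventions

- Dissimilarities are symmetrized (`(D + Dᵀ)/2`) against round-off and
  checked for a zero diagonal before embedding.
- CSV I/O parses floats with strtod round-trip precision so
  load → write → load is bit-identical.
- Degenerate inputs are explicit: empty sites give S = 0, H' = 0,
  PD = 0 and undefined FRic (all warned); a constant trait is an error
  for K; constant elevation is an error for the smooth; an exactly
  collinear predictor reports infinite VIF.
- Peak ties break to the lowest elevation; hull degeneracies
  (QhullError) map to undefined FRic, not a crash.

## Known limitations

- FRic beyond `m = 2` axes needs richer sites than these surveys
  typically have; the default trades trait-space fidelity for coverage.
- The permutation test for K tests exchangeability of tips, not any
  specific alternative; its power depends on tree shape.
- The LMM fitter supports exactly one random-intercept factor — the
  design it exists for; crossed or nested random effects are out of
  scope.
- Model-averaged p-values rest on the normal approximation and inherit
  the usual caveats of post-selection inference.
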