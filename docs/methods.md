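# Methods

This note documents the models, the synthetic world the tests run in, the
numerical choices, and the limits of what a green test establishes.

## Data model

A MET observation is one field plot: genotype, location, cropping-season
start year, trial, replicate, the proportion of the plant stand harvested
(p ∈ [0,1]), and trait values. An *environment* is a location × season
combination labelled `<Location><YY>`. Traits carry a direction of merit and
a flag for whether p applies (it does for yield-type traits, not for
compositional ones such as dry matter content). The two-way genotype ×
environment table used by the bilinear models is built per environment as
fixed-genotype BLUEs with sum-coded replicate effects and p centered at its
environment mean, so adjusted means stay on the trait scale; plain cell
means are available as an option. The choice of BLUEs is a documented
default — the alternative (raw means) changes nothing structurally and is
exposed via `adjusted_means(..., method="raw")`.

## REML engine

All variance-component models (single-trial, joint, GEI partition,
per-environment TPE fits) share one REML engine built on Henderson's
mixed-model equations, because the models need crossed random factors and,
for the heterogeneity test, one residual variance per environment — a
combination no installed Python package provides. Implementation points:

* Every random factor's Z'Z block is diagonal (one level per plot), so the
  largest factor (typically the 612-level G×E term) is absorbed through a
  Schur complement; the Cholesky then runs on a system of order ~100, making
  a full joint fit ~0.1–0.2 s.
* With a homogeneous residual, σ²ε is profiled out analytically and the
  optimizer works on log variance *ratios*; with per-environment residuals
  all log variances are optimized directly (cross-products are precomputed
  per environment and reweighted each evaluation).
* Optimizer: L-BFGS-B on log variances, bounds e⁻²⁷…e¹⁸, Powell fallback.
  Variances at the lower bound are reported as 0 and flagged. The restricted
  log-likelihood includes all constants, so fits with different random
  structures or residual models are directly comparable in LRTs.
* Correctness is established in the test suite against (i) a dense
  evaluation of −2ℓ_R from V, agreeing to ~1e−11, (ii) zooming /
  coordinate grid maximizers of the restricted likelihood on small fixtures,
  and (iii) lme4 via Rscript (components agree to ~1e−4 relative).
* BLUP prediction error variances come from the corresponding block of the
  inverted coefficient matrix. Consequently PEV retains grand-mean
  uncertainty: in the noiseless limit the accuracy statistic
  Ac = √(1 − PEV/σ²g) saturates at √(1 − 1/G), not at 1. The same
  convention (SAS/lme4) underlies the Cullis heritability, where
  v̄Δ = mean over genotype pairs of var(BLUP_i − BLUP_j), computed as
  2(q·tr P − 1'P1)/(q(q−1)) from the PEV block P.

## QC statistics and thresholds

CV% = 100·σ̂ε/ȳ, H² = σ²g/(σ²g+σ²ε) (plot basis), Ac = √(1 − PEV/σ²g) with
PEV the genotype-wise mean. Removal thresholds default to H² < 0.1,
Ac < 0.4, CV > 40.5, read as strict inequalities (equality keeps the trial).
A genotypic variance estimated at (or within a factor 10⁻³ of the residual
variance of) zero flags the trial and reports Ac = 0 rather than raising.

## Joint model and tests

Across-environment heritability uses the plot-mean formula
H² = σ²g / (σ²g + σ²ge/e + σ²ε/(e·r)) with r defaulting to the harmonic mean
of trial replicate counts (12 trials at 3 reps + 5 at 2 gives 17/6.5 ≈ 2.6).
The GEI presence test compares the joint model with and without the ge term;
because σ²ge = 0 lies on the boundary, the null is the equal mixture
{point mass at 0, χ²₁} (plain χ²₁ available as a conservative option). The
heterogeneity test compares per-environment vs pooled residual variances
with e − 1 df; the heterogeneous fit is warm-started at the pooled solution
so its likelihood can only improve and the statistic is nonnegative by
construction. Nested fits at a boundary can disagree by ~1e−4 in −2ℓ through
the D vs G⁻¹ cancellation in log|C|; statistics above −0.01 are clamped to
zero, larger deficits raise. The GEI partition refits with random genotype,
location, year, location×year, block, G×L, G×Y, G×L×Y; per-term boundary
LRTs give the significance labels. With a single year the year-involving
terms are reported missing; locations observed in one year only trigger a
confounding warning but the fit proceeds.

## Finlay–Wilkinson

The table is standardized to overall mean 0, SD 1 (denominator n−1) so MSE
values are comparable across traits. The environment index is the column
mean of the standardized table; each genotype's row is regressed on it by
OLS. On complete tables the slope mean is exactly 1 (the index is the
genotype average). Two rankings are emitted, neither silently preferred:
raw slope ascending (the presentation used in cassava MET reports, where the
lowest sensitivity is called most stable) and |β − 1| ascending (the
convention where β = 1 is average stability). The joint-regression ANOVA
decomposes total SS into genotype, environment (common regression),
slope-heterogeneity and residual strata — exact conservation on complete
tables — with the heterogeneity F-test against the residual. Missing cells:
slopes use the available environments (≥3 required), the index uses all
genotypes with data. Note one generator subtlety: the harvested-proportion
covariate adds environment-level variation that sensitivity slopes do not
scale, so *exact* slope recovery from `simulate_fw_met` is only defined with
covariate_beta = 0; with the covariate active, recovery holds statistically
but not to machine precision.

## AMMI and GGE

AMMI takes main effects from marginal means and SVD-decomposes the
doubly-centered residual; GGE centers by environment means only, so genotype
scores carry G and GE jointly. SVD sign ambiguity is fixed by flipping each
axis so its largest-magnitude environment loading is positive. Per-axis
df = G + E − 1 − 2k. ASV uses scores s_ik = λ_k^0.5 α_ik by default (the
symmetric split most AMMI software uses); the exponent is exposed because
the original weighting is ambiguous (raw α corresponds to exponent 0) and
rank order can depend on it. GSI ranks are ordinal with identifier
tie-breaks so the index stays integral. Mega-environments group environments
by the argmax genotype of AMMI-2 fitted values; which-won-where winners are
computed algebraically (inner-product argmax over convex-hull vertices),
with the perpendicular-ray construction used only for plotting — the two are
equivalent and tested as such. Collinear genotype markers fall back to the
two extreme genotypes; an all-origin configuration yields one trivial
sector. EM imputation (row+column-mean initialization, rank-K refill,
default ceiling 20% missing cells, tol 1e−8) completes tables before the
bilinear fits when enabled.

## Superiority index

P_i = Σ_j (X_ij − M_j)²/(2n) with M_j the per-environment best under the
trait direction, decomposed as
[n(X̄i − M̄)² + Σ_j (X_ij − M_j − X̄i + M̄)²]/(2n). The decomposition's inner
term includes −X̄i (required for the identity with the defining formula; the
identity is property-tested on random tables). P_i is invariant to adding a
constant to any single environment.

## TPE representativeness

Environment-specific genotypic BLUPs come from per-environment
genotype-random fits; the reference BLUPs from the joint model. Environments
are ranked by the sum of (descending) ranks of the Pearson correlation and
the Cullis H². The accuracy curve resamples environment subsets of size
1…E−1 (default 50 draws each, module parameter), refits the joint model per
subset (warm-started from the full-data components; size-1 subsets use the
per-environment fits directly), and averages correlations on the raw r scale.
Plateau detection is left to the reader: the module emits the curve and its
finite differences. Clustering uses Pearson correlations between environment
columns of the G×E BLUP matrix and the Euclidean-compatible distance
d = √(2(1−r)) — required for Ward's objective to be meaningful; 1−r is
available behind a flag — with scipy's Ward linkage (ward.D2 semantics).

## The synthetic world

`simulate_met` emits
y = μ + g + e + b + ge + βp + ε with independent Gaussian components and
ge = Σ_k λ_k α_ik γ_jk + white noise, α and γ orthonormal and doubly
centered. Defaults state the study-scale world: 36 genotypes; 20
location-year trials over 11 sites and 3 seasons with 3 dropped (17 kept, 12
at three replicates, 5 at two; 1656 plots); μ = 27.5 t/ha; variances g = 2,
env = 10, block = 0.5, error = 4; interaction split 0.75 low-rank (two axes,
SS ratio 2:1) + 0.25 noise ≈ 1 total; p ~ Uniform(0.7, 1) per plot;
β_p = 5 t/ha per unit p (chosen so the covariate moves yields by a few t/ha
across its range; no distribution is stated for the source system).
`simulate_fw_met` replaces ge with (β_i − 1)e_j + noise for well-posed
sensitivity recovery, and a user-supplied `ge_matrix` can plant arbitrary
structure (used to plant sign-blocks for clustering tests).

What the generator does *not* emulate: spatial field trends, outlier plots,
non-Gaussian traits, genetic relatedness among clones, weather-driven
environmental covariates, and missingness below whole-trial granularity. A
green parameter-recovery test therefore establishes estimator correctness
under the stated Gaussian world, not robustness to real-data pathologies.

One estimator property worth knowing: because the low-rank recipe puts the
whole interaction SS into the doubly-centered (G−1)(E−1) subspace while the
REML model treats ge cells as iid over G·E cells, the fitted σ²ge runs
≈ GE/((G−1)(E−1)) ≈ 9% above the realized interaction mean square at study
dimensions. Recovery tests compare against the truth ledger's realized
component variances and document this inflation rather than hiding it.

## Determinism and budgets

Every stochastic path takes a seed (numpy Generator); pipeline stages derive
per-stage seeds from one root seed via SeedSequence. Monte-Carlo test suites
are sized to keep the default run near a minute: LRT calibration runs 100
seeds at a reduced 20-genotype × 8-environment scale, structure recovery
uses 20 seeds at study scale, and the acceptance accuracy curve uses 8
resamples per subset size (the module default stays 50).
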