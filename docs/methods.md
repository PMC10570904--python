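# Methods

`ctdensity` implements the two dominant paradigms for estimating the
size of unmarked animal populations from camera-trap networks, plus the
statistics used to ask whether they tell the same story about
population *trends*.

## Random encounter model (REM)

The REM treats animals as particles of an ideal gas: a population of
density D (individuals/km²) moving with day range v (km/day) collides
with a camera viewshed of effective radius r (km) and effective angle
θ (rad) at rate

    y/t = D · v · r · (2 + θ) / π

per camera-day, so density is estimated by inverting this with plug-in
component estimates.  Assumptions: detections independent, cameras
placed randomly with respect to movement, individuals moving
independently, population closed over the survey.

**Components.**

* *Encounter rate y/t* — individuals counted on independent sequences
  divided by summed camera-active days.  Each movement in and out of
  the viewshed counts as one encounter.  SE by nonparametric bootstrap
  over cameras (default 1,000 resamples), since cameras — not
  sequences — are the independent sampling units.
* *Effective radius r* — point-transect distance sampling on recorded
  entry radii.  Detected entry distances have pdf ∝ u·g(u) (the area
  element exposes distant crossings more); g is half-normal by default
  (hazard-rate optional).  The effective radius satisfies
  r² = ∫ g(u)·2u du, i.e. an ideal viewshed of radius r detects exactly
  as many passages as the real, imperfect one.  Radii beyond the
  truncation distance (99th percentile by default) are excluded from
  the σ fit only; the pipeline reports the whole-plane half-normal EDR
  σ√2, because the REM encounter rate is *linear* in the effective
  radius — truncating both counts and radius by an area-based rule
  would bias D by the ratio EDR(w)/EDR(∞).  SEs from observed
  information plus the delta method.
* *Effective angle θ* — half-normal fit to |entry angle| on the
  half-field of view; θ is twice the integral of the fitted detection
  curve, so perfect detection returns the full field of view.
* *Day range v* — per-event speeds (path length through the viewshed /
  duration, converted to km/day), averaged within behavioural modes and
  weighted by mode frequency: v = Σ_b w_b·mean_b.  With labels, modes
  are the labelled groups; without, a log-normal mixture is fitted by
  EM (scikit-learn) with the component count chosen by BIC.  The SE
  combines per-mode mean SEs with the multinomial covariance of the
  weights.

**Density uncertainty** uses the independence delta method:
CV²(D) = CV²(y/t) + CV²(v) + CV²(r) + [SE(θ)/(2+θ)]².  Component
covariances are taken as zero (none are estimated from shared data).
Densities are refused below 10 encounters (configurable): with fewer
events neither detection function is estimable in practice.

## Multi-species beta-Poisson N-mixture model (NMM)

Daily counts y_sijt (species s, site i, day j, year t) arise from
latent site abundance:

    y_sijt | N_sit ~ Poisson(N_sit · p_st)   (default)
                   | Binomial(N_sit, p_st)   (variant)
    N_sit ~ Poisson(λ_sit)

The Poisson detection family treats p_st as a per-individual daily
*trapping rate*, so a day may count the same individual more than once
— the feature that prevents the inflation of abundance for frequently
detected species that the binomial family suffers (y ≤ N forces N up
to the largest daily count).

Detection shares information across the community:

    p_st ~ Beta(p_t·τ, (1−p_t)·τ),    logit(p_t) = f(t)

so p_t is the community mean detection rate, τ the similarity between
species, and f a zero-mean GP over years (squared-exponential kernel).

Expected abundance:

    M1: log λ_sit = β_s0          + g_s(t) + h_s(x_i)
    M2: log λ_sit = β_s0 + β_s1·t + g_s(t) + h_s(x_i)

with g_s species-specific GP "trend noise" curves and h_s an optional
reduced-rank (Hilbert-space) GP spatial field on site centroids.  M2's
β_s1 is the directly modelled linear population trend.  Abundances are
*relative* when sites are smaller than home ranges (an individual may
use several sites).

**Marginalization.**  N_sit is summed out to a per-species bound
K_s = max(y_s···) + 100; the bound is far above any posterior mass and
doubling the margin changes log-likelihoods by < 1e-10 (tested).  The
per-unit joint over the latent grid separates into a constant block
plus a term linear in N, so the summation runs as an early-terminating
scan (the log-mass is concave in N) compiled with numba; a pure-numpy
full-grid evaluation is kept as the reference implementation and the
two are compared in the tests.

**HSGP spatial field.**  The field is expanded in m² Laplacian
eigenfunctions of the boundary-inflated rectangle (factor c, default
1.5; m = 20 per dimension by default) with square-root spectral-density
weights.  Fidelity is boundary-limited: with data half-width S, the
implied covariance matches the exact kernel to ~2% when the
lengthscale is ≲ S/3 at c = 1.5; longer lengthscales need a larger c
(tested explicitly).  Sites in this package's surveys sit on km-scale
grids, where spatial correlation lengths of a few cell widths satisfy
this comfortably.

**Priors** (package defaults, overridable): β ~ Normal(0, 2); GP
marginal SDs half-Normal(0, 1); year-GP lengthscales log-normal centred
on half the series span (σ = 0.5); τ half-Normal(0, 5); spatial SD
half-Normal(0, 1) per species with a shared log-normal lengthscale.
The trend-noise curves g_s share their SD/lengthscale across species.

**Sampling.**  The posterior is sampled by an in-package No-U-Turn
sampler with analytic gradients (verified against finite differences
across every model variant).  Parameterization: f and g_s non-centred;
species detection rates non-centred through logit p_st = f_t + u_st/√τ,
which flattens the funnel where large τ pins p_st to p_t.  The kinetic
metric is the regularized posterior covariance — dense below ~150
dimensions, diagonal above (a dense estimate is too noisy for the
spatial basis).  By default one exploratory chain runs the full warmup
and its posterior draws define a single shared metric, step size and
overdispersed starting points for all sampling chains; sharing the
metric removes between-chain adaptation disparity, which is the main
cause of spurious split-R-hat failures at short chain lengths.  A fit
is flagged non-converged when any reported parameter's rank-normalized
split R-hat reaches 1.01 or more than 1% of transitions diverge
(divergences are counted over every sampled transition, retained or
not).  Optional thinning keeps every k-th post-warmup draw — useful
when a fixed number of retained draws must carry as much effective
sample size as the time budget allows — and a bounded restart ladder
re-runs a non-converged fit with a fresh seed, a higher acceptance
target and a longer warmup, the standard practitioner response to a
failed convergence check.  Default run length follows the long-survey
convention (2 chains × 10,000 iterations, half warmup); the test-suite
fits retain 2 × 1,000 draws thinned 3:1.

**Model comparison** uses PSIS-LOO (arviz) with the site-year count
vector as the observation unit — the unit of marginalization; daily
counts within a unit are not conditionally independent given λ alone.
The comparison table reports p_loo, ELPD and its SE, ΔELPD to the best
model, SE(Δ) from pointwise differences, and a Pareto-k health flag
(> 5% of units above k = 0.7).

## Trend comparison

Given yearly REM densities and NMM abundances (posterior means of the
yearly totals Σ_i λ_sit):

* between-year rank agreement: Spearman's S = Σd² with
  ρ = 1 − 6S/(n(n²−1)) for untied data; exact two-sided p by full
  permutation enumeration for n ≤ 9, t-approximation otherwise; the
  community test pools all species-year pairs;
* growth-rate trajectories x_t/x_{t−1} (pairs spanning a missing year
  are skipped, not chained) compared by Pearson correlation with
  t = ρ√((n−2)/(1−ρ²));
* across-years linear slopes by OLS on the year index with t-based CIs
  (for M2 the posterior of β_s1 answers the same question in-model);
* precision via CV = SE/estimate (REM) or posterior SD/mean (NMM),
  flagged against the 0.25 management-grade threshold.

Missing years are dropped pairwise throughout (a species-year without
enough encounters has no REM density).

## Synthetic surveys

The generator is the package's ground-truth instrument; it draws from
*exactly* the structure the models assume, so recovery tests probe the
estimators, not model misspecification.

* `simulate_counts` — the full NMM generative process on a lattice of
  sites.  Defaults emulate a three-species Mediterranean community
  (fox-, wild-boar- and red-deer-like): expected site abundances 0.5,
  2 and 7.5; community detection drifting on the logit scale (GP
  sd 0.75, lengthscale 2 years, centred at rate 0.5/day); τ = 5;
  trend-noise sd 0.25; spatial field off unless requested (when on, it
  is drawn from the *exact* kernel on the centroids, so the fitted
  reduced-rank field is tested against a non-approximate truth).
  Recovery tests use 25 sites × 20 days × 4 years with two species —
  a desk-scale survey sized so the whole replicate battery fits in a
  CI run.  Under the Poisson family the generator accepts detection
  rates above 1 (true double counting); the fitted model keeps
  p_st ∈ (0,1), which is exactly the stress that separates the two
  detection families.
* `simulate_rem_events` — event-level encounters at the REM-implied
  Poisson rate.  Entry radii follow pdf ∝ u·exp(−u²/2σ_r²) truncated at
  r_max, with σ_r solved so the truncated EDR equals the requested
  effective radius exactly; entry angles are uniform over a field of
  view thinned half-normally, with the half-angle solved so the
  effective angle equals the requested θ; speeds come from a log-normal
  behaviour mixture whose weighted mean is the requested day range, and
  each event carries its generating mode as the behaviour label.

What the generator does **not** emulate: trap shyness and other
detection covariates, group (non-independent) movement, correlated
animal trajectories, camera failures mid-survey, and annotation error.
Passing recovery tests therefore demonstrate estimator correctness
under the models' own assumptions, not robustness to their violation.

All generators take explicit integer seeds and use isolated PCG64
streams; identical seeds reproduce every field bit-exactly.

## Numerical choices and degenerate inputs

* Marginal likelihood sums run in log space; impossible states
  (underflowed detection rates, non-finite predictors on divergent
  trajectories) return −inf and are rejected by the sampler.
* GP correlation matrices carry a 1e-10 jitter; lengthscale gradients
  differentiate the Cholesky factor exactly (dL = L·Φ(L⁻¹ dR L⁻ᵀ)).
* Distance fits: all radii equal (zero variance) drive σ→∞ and the
  EDR to the truncation radius; optimizers work on log σ throughout.
* Speed fits: a single distinct speed value yields one mode with zero
  SD; events with zero duration are excluded with a warning.
* Hexagonal grid: flat-top orientation anchored at the bounding box's
  lower-left corner; every cell intersecting the box is kept, so the
  grid covers the box and the cell count exceeds area/cell-area by a
  boundary ring (~10% for study-area-sized boxes).  Cameras on shared
  edges break ties to the lowest cell id.
* Day definition: 24-h blocks anchored at local midnight (configurable
  anchor hour), counted from each year's earliest deployment start.

## Known limitations

* The NMM sampler is tuned for desk-scale surveys (tens of sites, a
  handful of years); national-scale grids would need larger spatial
  bases and the diagonal metric, and correspondingly longer chains.
* PSIS-LOO on site-year units can flag high Pareto k for units with
  extreme totals; the comparison table carries the flag rather than
  refitting with exact cross-validation.
* REM component covariances are assumed zero in the delta method.
* The binomial detection family requires K_s ≥ max count and becomes
  slow for very large counts (the latent scan is linear in the
  posterior spread of N, not in K_s).
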