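# Methods

## The problem

Occupancy surveys often need to answer a causal-screening question from
purely observational data: *all else equal, does a stressor (introduced
fish, packstock grazing, ...) depress the occupancy of a rare species?*
When both the response and the stressor are present in only ~10% of sites,
cross-tabulation runs out of cases, and parametric coefficient tests
inherit every assumption of the fitted model.

`stratperm` implements a two-tier alternative. First, an external
predictive occupancy model — fitted on all useful covariates *except* the
stressor — collapses the confounders into one score: the predicted
suitability for occupancy. Sites are stratified into K quantile bands of
that score, so that sites within a stratum are roughly exchangeable except
for stressor exposure. Second, a stratified permutation test asks whether
the observed stressor–response association, aggregated across strata, is
surprising relative to random re-assignment of the occupancy labels within
strata.

## The test

Within stratum k containing n_k sites of which m_k are occupied:

* **mean_difference** (binary stressor): T_k = mean(response | stressor
  present) − mean(response | stressor absent). Negative values mean the
  stressor is associated with lower occupancy.
* **point_biserial** (continuous stressor): T_k = Pearson correlation of
  the 0/1 response with the stressor intensity, optionally after a
  log(1+x) transform (natural log; heavy-tailed use data are near
  log-normal). The transform base is recorded in output metadata because
  Pearson r is not invariant to it.

The overall statistic is an aggregation of the T_k: the unweighted mean by
default (an association "overall, at the scale of the whole landscape"),
with `weighted_mean`, `mean_abs` and `max_abs` available — `mean_abs`
guards against strong per-stratum associations of opposite signs cancelling.

The null re-assigns each stratum's m_k occupied labels independently across
strata, preserving m_k exactly (otherwise the null would change the
species' prevalence):

* **unweighted**: uniformly over the C(n_k, m_k) arrangements;
* **weighted**: by successive sampling without replacement with selection
  probability proportional to each site's suitability score. This absorbs
  residual suitability variation inside coarse strata.

The two-sided p is the fraction of B permuted aggregate statistics with
|T_b| ≥ |T_obs|; ties count as extreme. The default `raw_proportion` rule
can return exactly 0; `add_one` gives the (#+1)/(B+1) variant that cannot.

## Implementation notes

* Both statistics are linear in the occupancy indicator once group sizes
  are fixed, so each permuted aggregate is a sum of per-site contributions
  over the selected sites. Draws are vectorised per stratum.
* Weighted selection uses the exponential-key equivalence (select the m
  smallest Exp(1)/w_i; Efraimidis & Spirakis 2006), which is exactly the
  successive weighted sampling scheme and vectorises across draws.
* `exact_test_small` enumerates the full cartesian product of per-stratum
  arrangements (cap 10^6 states) with exact probabilities — uniform, or the
  successive-sampling subset probabilities computed by recursion — and is
  the oracle the Monte-Carlo engine is validated against.
* Ties at |T_b| = |T_obs| are compared with an absolute epsilon of 1e-12 so
  the scalar and vectorised code paths cannot disagree in the last ulp.
* One RNG stream per test, seeded from the config, drawn in stratum order;
  identical seed + config + input gives bit-identical results.

## Stratification

Strata are equal-size rank bands: sites sorted by suitability with a stable
sort (ties broken by input order), split into K blocks of floor/ceil(n/K).
Equal sizes maximise within-stratum permutation resolution; the empirical
quantiles at i/K are reported as boundaries. If more than half the sites
share one suitability value the split is refused as degenerate. Strata
without within-stratum variation (no occupied sites, or no stressor
contrast) contribute a statistic of zero and stay in the aggregation
denominator — dropping them would let the permutation change K — and the
feasibility report counts them so the user can coarsen K. Defaults: K=5
for binary-stressor workflows, K=4 for intensity workflows (the shipped
`lake` and `meadow` templates).

## Allocation-uncertainty sensitivity

Where a reported stressor total is shared by a named complex of polygons,
the true split is unknown. The search redistributes each complex's total
over its members in 10% increments (compositions of 10 units; uniform over
the discrete simplex via uniformly random bar placement), evaluates the
observed aggregated statistic for each allocation (100,000 random draws by
default, exhaustive enumeration below 10^5 states), and reruns the
permutation test on the allocations attaining the minimum and maximum.
Complexes are sampled independently; totals are conserved exactly within
each complex. The summarised stressor value is reallocated directly (not
the underlying yearly records).

## Stock-use metrics

Per-year use records are summarised over the five years up to and
including the survey year, with missing years counted as zero:
`max_annual` (peak annual total) and `mean_annual_per_ha` (5-year mean of
annual totals divided by area). Averaging before dividing by area is
equivalent to averaging annual densities here because area is constant per
site and missing years are zero-filled.

## Synthetic landscapes

The generator emulates the double-rarity regime: covariates iid standard
normal; stressor assigned with probability expit(α₀ + γz) where z is the
standardised covariate linear predictor and α₀ is calibrated (Brent root
finding on the realised sample) to the target ~10% stressor prevalence;
response Bernoulli with probability expit(β₀ + βᵀx + βs·t(s)), β₀
calibrated to ~10% response prevalence; intensity-mode stressors multiply
presence by a log-normal draw (meanlog 3, sdlog 1, putting the median near
20 use-nights with a heavy right tail). βs is the true effect on the
log-odds scale; 0 gives an exact null.

γ defaults to 0.5 (mildly positive: the stressor tends to occur where the
species could — the confounding the stratified test is built to absorb);
γ=0 gives a clean null in which occupancy is independent across sites and
the permutation p is uniform. Calibration experiments in the test suite
use the clean null for type-I error (measured rejection ≈ 0.05 at α=0.05
over 1,000 replicates of n=2,000, K=5, B=1,000) and show that under γ=0.5
with no causal effect the *unweighted* test rejects slightly more often
(residual within-stratum confounding) while suitability-weighted
permutation restores nominal calibration — the purpose of the weighted
variant.

A logistic regression (statsmodels ML fit) stands in for the arbitrary
external occupancy model: the test consumes only the score, so any model
can be plugged in through the suitability column. The generator draws
sites independently: no spatial autocorrelation, no detection error, no
repeat surveys, so passing calibration here says nothing about robustness
to those features of real data.

## Problem sizes used in the checks

Monte-Carlo/exact agreement uses 24 fixtures with ≤ 10^6-state spaces at
B=10,000; pipeline calibration uses 1,000 replicates per cell at n=2,000,
B=1,000 (B reduced from the 10,000 a full analysis would use — the p-value
resolution, not the test logic, is what B buys); template runs use n=2,655
(binary) and n=1,151 (intensity) at B=10,000; the allocation search in the
reproduction script uses 8 complexes × 3 members and 100,000 iterations.

## Limitations

* The test is conditional on the stratification: a poorly predicting
  suitability model leaves more residual variation for the stressor to
  "explain", and the method cannot detect that from the data alone.
  `separation_diagnostics` checks the complementary failure mode (stressor
  collinear with the covariates).
* Aggregating signed statistics can hide opposite-sign per-stratum
  effects; use `mean_abs`/`max_abs` to screen for that.
* No detection-error correction and no abundance inference; the response
  is occupancy only.
* The raw-proportion p is slightly anticonservative at very small B;
  prefer `add_one` when B is small.
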