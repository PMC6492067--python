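# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the design decisions taken where the published
method description leaves the implementation open.

## The multiplier model

The multiplier method assumes two data sources over the same population,
time window and area: a count `C` of members visible in a defining source
(active app users over one month) and a representative estimate `p̂` of the
proportion of the population in that source. Under independence of the two
sources and a shared population definition, `N̂ = C / p̂`. The count enters
as a fixed constant: the reported CI divides `C` by the proportion's CI
bounds, so all sampling uncertainty is attributed to the survey. Reported
population figures are rounded half-up at the final step only; intermediate
arithmetic is kept at full precision.

## Counting active users

- **Deduplicated enumeration.** A profile is counted iff sighted on at
  least `min_appearances` distinct days (default 2) with at least two
  sightings `min_spacing_days` apart (default 3). The spacing rule exists
  to exclude short-term visitors; since "several days" has no canonical
  value, the parameter is explicit and surfaced in every config so the
  analyst must own the rule.
- **Capture–recapture.** Lincoln–Petersen `N̂ = n₁n₂/m` with variance
  `n₁n₂(n₁−m)(n₂−m)/m³`, or Chapman's bias-corrected
  `N̂ = (n₁+1)(n₂+1)/(m+1) − 1` with its standard variance. CIs are normal
  approximations with the lower bound floored at `max(n₁, n₂)` (the
  population cannot be smaller than a capture). Chapman is defined at
  `m = 0`; Lincoln–Petersen raises and advises Chapman. Fingerprint
  matching is exact string equality — fuzzy profile matching is out of
  scope.
- **Provider count.** A pass-through with provenance.

## RDS estimators

Both estimators are two-group (the traits of interest are binary app-use
indicators). Missing trait values are excluded listwise with a logged
count.

**RDS-I.** Transition proportions `S_XY` are maximum-likelihood row
proportions of the recruiter→recruit trait matrix (seeds contribute only as
recruiters). An optional `smoothing="reciprocity"` variant averages the
off-diagonal counts before normalising. With harmonic mean degrees
`D_X = n_X / Σ 1/d_i`, the reciprocity balance gives
`P̂_A = S_BA·D_B / (S_AB·D_A + S_BA·D_B)`. Degenerate single-group samples
return 0/1; a group that never recruits (or zero observed cross-recruitment)
leaves the estimate undefined and flagged unreliable rather than silently
falling back.

**Gile's SS.** Successive sampling: `n` draws without replacement with
probability proportional to degree from a finite population of assumed size
`N`. Starting from weights `1/d_i`, the population degree distribution is
estimated by scaling the weighted sample distribution to `N` (largest-
remainder integer allocation, floored at the observed per-degree counts),
inclusion probabilities `π(d)` are estimated by Monte Carlo (default 200
replicate draws, implemented via exponential-key order sampling), weights
are reset to `1/π(d_i)`, and the loop repeats until the estimated degree
distribution moves less than `tol` (max absolute change in class
probabilities) or `max_iter` is reached. `tol` defaults to 5·10⁻³: the
Monte Carlo noise floor of the π estimates at the default replicate count —
a tighter tolerance would chase simulation noise rather than the fixed
point. The point estimate is the Hájek ratio `Σ_A w_i / Σ w_i`. Limits
used as test oracles: equal degrees → the crude proportion; `N → ∞` → the
`1/d`-weighted Hájek estimate.

`N` is an explicit parameter because the estimator genuinely requires one,
even though the multiplier's purpose is to produce it. Where no prior `N`
exists, `ss_multiplier_fixed_point` iterates SS(N) → multiplier → N until
the implied size changes by < 1%; the pipeline uses this mode by default.

**Chain bootstrap.** Each replicate regrows a single pseudo-chain of length
`n`: the starting group is drawn uniformly from {A, B} (chains forget their
seed group within a few waves, so the start has little influence at survey
sizes; uniformity avoids importing seed-selection bias into the CI), each
next group is drawn from the observed transition matrix, and degrees are
resampled with replacement from the empirical per-group pools (seeds
included in the pools). The estimator is applied to each replicate and the
CI is the percentile interval (default 1000 replicates, 95%). If more than
20% of replicates leave the estimator undefined, the CI is flagged
unreliable. The SS bootstrap reuses the same chain mechanism with a reduced
π-simulation budget per replicate (a quarter of the point estimate's, floor
25) to stay tractable.

## Diagnostics and estimator selection

- **Homophily** is recruitment homophily: observed same-group recruitments
  divided by their expectation under random mixing given the recruit pool's
  composition. The convention is 1 = random mixing, > 1 = assortative. The
  selection rule consumes the numeric threshold "< 1" exactly as stated in
  the surveillance protocol this implements, and the report notes record
  the convention so the direction cannot be misread.
- **Convergence**: the estimate is recomputed cumulatively in recruitment
  order (vectorised O(n) paths for RDS-I and the crude proportion);
  converged means every estimate in the final `window_frac` (default 0.25)
  of the series lies within ±`tol` (default 0.02, absolute; a relative mode
  exists because "within 2% of the sample proportion" is ambiguous) of the
  final estimate. The window fraction is a choice — the 2% rule's window is
  not specified anywhere — and is configurable.
- **Bottlenecks**: per-seed cumulative series within each seed's subtree;
  the reported gap is the largest pairwise difference between final
  per-seed estimates. Within-seed estimates default to crude proportions
  because subtree transition matrices are frequently degenerate, which
  would leave RDS-I undefined on many seeds. No numeric bottleneck
  criterion is standard; reports flag a gap above 0.10 by default.
- **Sensitivity**: an estimate is "not sensitive" iff it lies in
  [0.2, 0.8], bounds inclusive ("within the range" is read inclusively).
  Proportions outside the band make `C/p̂` unstable.
- **Selection rule**: RDS-I iff strictly more provinces show homophily < 1
  (the SS bootstrap's underestimation condition) than fail convergence
  (RDS-I's underestimation condition); ties go to Gile's SS, with the tie
  recorded in the rationale.
- **Group comparisons**: equal-variance two-sample t (pooled df
  `n₁+n₂−2`, matching the integer df convention of the reported analyses)
  for continuous outcomes; Pearson χ² without continuity correction for
  binary ones.

## Extrapolation

Each observed province's estimate is converted to a percentage of its male
population 15–49, weighting by the app users' age distribution across the
seven 5-year bands. The survey observes nobody under 18, so the 15–19
band's allocation covers ages 18–19 only; by default it is rescaled by 5/2
under a uniform-age-within-band assumption to bridge to 15–17
(`extend_15_17=False` disables the bridge). This bridge is an assumption,
not data, and is flagged in reports. Unobserved provinces receive their
region's population-weighted mean percentage (unweighted mean and median
are available) applied to their own male population; pilot estimates are
appended as-is. The national CI sums provincial bounds bound-wise — a
conservative choice that assumes no cancellation across provinces and
matches the arithmetic consistency of the published provincial table's
total row. Exact replication of the published provincial points and CIs is
not attempted: they were computed from unrounded proportions that were
never published (only one printed row is consistent with its printed
inputs).

## The synthetic generator

The generator emulates the study conditions, not any measured Vietnamese
network (no such network data exist):

- **Network**: N = 10,000 per province; group A (current app users) at
  prevalence 0.35 (the order of the observed eligible-respondent app-use
  proportions); negative-binomial target degrees with mean 10 (the surveys'
  mean reported network size was ~10.6) and dispersion 3 (SD ≈ 6.5, a
  right-skewed but not extreme personal-network distribution); edges from a
  degree-corrected block model where within-group blocks are tilted by
  `homophily_w` (1 = random mixing) and the total expected edge count is
  preserved. Parallel edges and self-loops are discarded.
- **RDS**: 6 seeds, 3 coupons, target 400; seeds uniform among connected
  nodes (optionally forced into group A by `seed_bias`); recruiters use all
  coupons on uniformly chosen not-yet-sampled neighbours — the standard
  RDS-simulation assumption; chains that die return unused coupons.
  Reported degree equals the realised network degree, with an optional
  multiplicative log-normal noise hook since real network sizes are
  self-reported and unvalidated.
- **Activity log**: group-A members log in independently each day
  (default 0.3/day over 30 days, making a ≥2-sightings-3-days-apart
  appearance near-certain for a genuine user); "visitor" profiles arrive at
  2/day and appear exactly once. Traits: `app_ever` adds a 0.3 fraction of
  non-users (matching the observed ratio of ever-use to 30-day-use);
  sexual-behaviour eligibility answers are generated so all simulated
  respondents are eligible.

All randomness flows from one integer seed through named substreams, so a
fixed seed reproduces network, sample and log byte-for-byte.

**What passing tests show — and don't.** Parameter recovery and CI coverage
hold under this generator: random mixing, truthful degrees, no differential
recruitment, coupon use independent of traits. Real RDS surveys violate
several of these (homophily, degree misreporting, preferential recruitment),
and the diagnostic battery exists precisely because the estimators degrade
there. Tests that demonstrate those degradations (convergence failure and
bottlenecks under strong homophily) are qualitative contrasts, not
calibrations against field data.

## Problem sizes

The recovery and coverage experiments are run at the survey's own scale
(N = 10,000, n = 400): 50 replicate surveys for estimator recovery and the
end-to-end pipeline, 200 datasets × 500 bootstrap replicates for CI
coverage, 200 replicates for capture–recapture recovery. These sizes give
Monte Carlo standard errors comfortably below the assertion tolerances
(e.g. SE ≈ 0.005 on a mean proportion asserted within ±0.03).

## Known limitations

- Two-group traits only; multi-category RDS-I is out of scope.
- The chain bootstrap resamples one chain per replicate and ignores the
  seed forest's branching structure; it slightly understates
  between-chain variance under strong homophily.
- The generator has no geography, age-structured mixing or account churn;
  the activity log's visitors are memoryless one-day profiles.
- National extrapolation quality is bounded by the regional-stratification
  assumption; the bound-wise CI is conservative by construction.
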