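# Methods

## The analysis in brief

The pipeline operationalizes a prospecting hypothesis for ground-nesting
birds: females that revisit, during incubation recesses, foraging patches
they already used during egg laying may fledge more nests. Its quantities
are built from plain geometric rules on a fixed GPS schedule (hourly fixes
05:00–20:00 plus one nightly fix at 23:58:58, local standard time, no
timezone arithmetic anywhere), so every stage is deterministic given its
inputs and thresholds.

### Thresholds and defaults

| parameter | default | meaning |
|---|---|---|
| `dop_max` | 7 | fixes with DOP **> 7** discarded (strict) |
| on-nest / recess radius | 27.5 m | transmitter 90th-percentile error; a fix **> 27.5 m** from the nest during incubation is a recess (strict) |
| nest-visit radius | 20 m | laying onset = first hourly fix **< 20 m** from the nest (strict) |
| laying lookback | 20 d | window searched before incubation onset |
| `min_incubation_days` | 3 | attempts incubated < 3 whole days dropped |
| CLP linkage radius | 150 m | single-linkage threshold merging laying fixes (inclusive ≤) |
| CLP revisit buffer | 45 m | recess-to-centroid distance counted as a revisit (inclusive ≤) |
| dBBMM error / window / margin | 20 m / 7 / 3 | location error and variance-estimation window |
| UD grid resolution | 30 m | matches the landcover raster |
| available points | 500 per range | uniform over the 95% contour |
| collinearity screen | r > 0.60 | greedy Pearson removal |
| MCMC schedule | 4 × 8000, burn-in 1000 | per chain |

Boundary conventions: the data-cleaning and behavioral rules are strict
inequalities (7.0 kept, 27.5 m not a recess, 20.0 m not a visit); the two
spatial clustering radii are inclusive (150.0 m merges, 45.0 m counts), on
the reading that a point "falling within" a buffer includes its boundary.
The 150-m linkage radius, the 45-m (90-m diameter) revisit buffer, and the
27.5-m recess radius are all configurable where ambiguity exists in
practice (e.g. a buffer-overlap reading of patch merging corresponds to a
300-m linkage radius).

## Segmentation

Incubation onset is "the first night spent on the nest". With the nest
supplied (the field-confirmation path) this is literal: the first nightly
fix within 27.5 m that begins a run of on-nest nights. With the nest
unknown it is estimated: nightly fixes are single-linkage clustered at
27.5 m, each cluster's geometric median (Weiszfeld) is a candidate nest,
and runs of on-nest nights are formed with a tolerance of up to 2 missed
nights (a 10-m-noise fix falls outside 27.5 m on ~2% of nights; without
the tolerance a month-long incubation fractures about half the time).
Two robustness rules use the daytime fixes, mirroring what an analyst
inspecting mapped tracks would do:

* a candidate bout must show ≥ 50% of its hourly fixes on-nest (true
  incubation shows ~90%; overnight roost clusters show ~0%, and are the
  dominant false-positive source otherwise);
* the onset walks back one day at a time while the preceding day's hourly
  fixes were ≥ 50% on-nest, recovering onsets hidden by a single noisy
  nightly fix.

Successive non-overlapping bouts of one female become attempts 1, 2, …
ordered by onset; attempt indices are renumbered after the < 3-day filter
so initial/renest labels refer to analyzable attempts. Incubation end is
the last on-nest night + 1 day. Fate is an input label (field observation
in the real workflow; the generative logistic model in simulation).

## Prospecting construction

CLP clustering is single linkage: two laying fixes share a patch iff
connected by a chain of pairwise distances ≤ 150 m (equivalently, each
inside the other's buffer). The partition is exactly reproduced by
union-find over all pairwise distances, which the tests use as an oracle.
Centroids are arithmetic means (unit-sphere means in geographic mode);
patch ids follow the earliest member fix in time. A recess inside
overlapping buffers counts once, attributed to the nearest centroid
(lowest id on exact ties), so the proportion of recesses to CLPs cannot
exceed 1. Recesses are counted at the fix scale, matching a fix-level
recess definition; bout-level aggregation is deliberately not performed.

## dBBMM incubation ranges

The Brownian motion variance σ²ₘ (m²/s) is estimated per fix by
leave-one-out likelihood in a sliding 7-fix window: each odd-indexed
interior fix is scored against the Brownian bridge between its temporal
neighbours, with variance

    σ²ₘ·T·α(1−α) + δ²·((1−α)² + α² + 1),   α = (t−t₀)/T,  δ = 20 m.

The third δ² term is the left-out fix's own measurement error; omitting it
inflates σ̂²ₘ by ≈ 2δ²/(Tα(1−α)) and fails the σ²=400 recovery benchmark.
Each window may place one breakpoint (≥ 3 fixes from either edge) splitting
it into two variance regimes when BIC prefers two; per-fix estimates are
means over all windows covering the fix. The utilization distribution
integrates the bridge density (variance σ²ₘ·T·α(1−α) + δ²((1−α)²+α²) —
here the extra δ² term does *not* apply, since the UD describes the true
position given the observed endpoints) over 10 time steps per bridge on a
30-m grid; a motionless bridge (zero displacement and σ²ₘ = 0) collapses
analytically to a single isotropic Gaussian of sd δ. The grid auto-expands
until < 10⁻⁴ of mass touches its rim. The 95% contour takes cells in
decreasing density order until cumulative mass ≥ 0.95; available points
are area-uniform over the contour. Mixed hourly/nightly gaps need no
special casing — Δt enters every bridge directly.

## Models

**Nest fate.** Hierarchical logit with covariates standardized to unit
*sample* SD, weakly informative priors (Normal(0, 2.5²) on coefficients,
half-Normal(0, 2) on σ_b), and an adaptive random-walk
Metropolis-within-Gibbs sampler in the *non-centered* parameterization
(b = σ_b·u): proposal scales adapt during burn-in toward 25%/35%
acceptance, female intercepts update independently in a vectorized block,
and σ_b updates rescale all intercepts at once — without this the σ_b
chain mixes an order of magnitude more slowly. Summaries: posterior mean,
equal-tailed 95% credible interval, probability of direction
pd = max(P(β>0), P(β<0)) with exact zeros split evenly, and split R-hat
(convergence declared iff all R-hat < 1.1; bit-identical chains return
exactly 1 as the degenerate perfectly-mixed case). The marginal effect of
one additional patch visited is the average over posterior draws and
observed rows of p(z + Δ) − p(z), Δ = 1 patch converted to the
standardized scale, reported in percentage points.

**Resource selection.** Used (recesses assigned to CLPs) versus available
(500 per 95% range) logistic GLMM with a per-female random intercept,
fitted by maximum likelihood with 15-node adaptive Gauss–Hermite
quadrature (per-group posterior modes by Newton iteration; standard errors
from the numerical Hessian). Covariates pass the greedy Pearson screen
(drop the covariate with the largest mean |r| while any |r| > 0.6,
column-order tie-break), then are rescaled by 2 SD so binary and
continuous effects are comparable. Used and available rows are equally
weighted. A negative coefficient on a distance covariate means selection
for proximity. Distance-to-nest is computed for available points from the
same nest as for used points — required for the design even though only
recess distances are defined behaviorally. The fit matches `lme4::glmer`
to within 0.02 on coefficients and 0.01 on SEs in a cross-validation test. Complete
separation raises; a boundary random-effect variance is reported as 0 with
a warning.

## The synthetic population

The generator emulates the study conditions: 12 laying days, 28 incubation
days, 4 foraging patches per female, Poisson(2) recesses/day, revisit
probability 0.57, 10-m isotropic GPS noise, fate coefficients (0 per SD of
proportion, 0.19 per SD of patches visited) and a female intercept SD of
1.2 on the logit scale — values chosen to mirror the covariate and effect
ranges the analysis is designed for. Geometry constraints are generator
constraints, not biology: recess targets 60–900 m from the nest (so the
27.5-m rule separates classes cleanly at realistic noise), patches ≥ 500 m
apart and ≥ 300 m from the nest (so each forms its own CLP), roosts
200–300 m from the nest with 75-m nightly jitter (birds rarely perch at an
identical point twice; a pointlike roost would mimic an incubation bout).
Landcover is a smoothed Gaussian random field rank-thresholded at the
class-mix quantiles (blob-like patches at 30-m granularity); roads are
independent wiggly polylines. A fixed equirectangular projection centered
at 32.5° N exercises the geographic (haversine) code path.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about field data: correlated random-walk movement,
habitat-dependent recess placement (trajectory recesses are habitat-blind;
selection strength for the RSF benchmark is injected by a separate
point-process simulator that generates Bernoulli used/available labels
from known 2-SD-scale coefficients), multi-hour recess bouts (each recess
is one fix), failed-then-renested attempts with partial laying, weather
and season effects, and fix loss beyond the DOP filter. Recovered
proportions sit ~0.02 below the generative revisit rate at 10-m noise
because on-nest fixes displaced past 27.5 m become spurious recesses; this
is a property of the classification rules at that noise level, not a bug,
and the same artifact would affect real data.

## Numerical choices

σ²ₘ maximization is bounded scalar optimization on [0, 100·(track
diagonal)²/duration]; UD Gaussians are accumulated on ±8.5 σ windows
(truncation below double precision); determinism everywhere comes from
`numpy` `SeedSequence` spawning, so a pipeline rerun under an identical
config (whose SHA-256 hash is embedded in every output) is byte-identical.
Problem sizes in the test-suite experiments (100-attempt recovery runs,
20-replicate model calibrations at n = 500 with 4 × 2000 chains, 40-female
acceptance runs) are the package's chosen benchmark sizes: large enough
for the binomial tolerances quoted in the tests, small enough to run
routinely.

## Known limitations

* The overnight-rule nest detector assumes the nightly fix exists;
  transmitters that miss nights degrade onset recovery gracefully (gap
  tolerance) but not indefinitely.
* The dBBMM breakpoint search follows the windowed-likelihood scheme with
  BIC selection; with only ~3 leave-one-out fixes per window the variance
  estimator is conservative (median recovery within ~20% at σ² = 400).
* pd is a sampling-based tail probability; with 28,000 pooled draws its
  resolution is ~10⁻⁴, so "pd = 99.8%"-style statements carry that
  granularity.
* The RSF treats fixes as independent given the female intercept; no
  spatial or serial autocorrelation correction is applied, matching the
  plain used/available GLMM design.
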