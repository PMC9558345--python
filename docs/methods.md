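# Methods

`pulsetrack` implements an inference chain for asking whether carnivores
actively search for the neonates of GPS-collared ungulates, using nothing
but dual-species telemetry and landscape rasters. This note documents the
models, the synthetic-data generators that validate them, and the numerical
and design choices a maintainer should know about.

## The inference chain

### 1. Parturition detection (rolling MCP)

A female ungulate localizes sharply around her birth site. The detector
computes, at every fix time, the area of the minimum convex polygon (MCP)
of the fixes in the trailing 24-h window, and declares a parturition event
at the start of the first run of evaluation times whose area stays at or
below a species-specific threshold — 30 ha for elk, 15 ha for mule deer —
continuously for at least 120 h. No qualifying run means the animal is
treated as not having given birth.

Conventions (the published description leaves these open; they are fixed
here and exercised by tests):

- The window is evaluated at every fix time, not on daily bins; sub-daily
  resolution is what makes timing-error validation in hours meaningful.
- Both comparisons are inclusive: area == threshold qualifies, and a run
  spanning exactly 120 h qualifies. (The deer criterion is stated in the
  literature in a self-contradictory "<15 hectares or less" form; this
  package reads it as <= 15 ha.)
- The window is trailing (past-looking), anchored at the evaluation time;
  the event time is the start of the qualifying run, with no back-shift.
- Windows with fewer than 3 fixes have area 0 (degenerate hull) and still
  qualify if the animal produced at least one fix; a gap longer than one
  window length breaks a run.
- The event site is the centroid of fixes in the run's first 120 h.

### 2. Step-selection function with an encounter covariate

Predator trajectories are decomposed into steps (straight-line moves
between consecutive fixes). Each observed step is matched with K = 20
random steps drawn by taking a Gamma step-length draw and a von Mises
turning-angle draw from kernels fitted by maximum likelihood to the
observed steps, projected from the same start fix given the previous
bearing. Endpoint covariates enter a conditional logistic regression with
the matched set as stratum:

    w(x) ~ exp(b1 enc + b2 canopy + b3 veg class + b4 ruggedness
               + b5 ln dist road + b6 ln dist water
               + b7 ln(step length) + b8 cos(turn))

`enc` is 1 iff the endpoint lies within 200 m (inclusive) of the
contemporaneous fix of a collared female ungulate within 30 days after her
parturition event. "Contemporaneous" means the nearest prey fix within a
tolerance of half the prey's nominal fix interval (15 min for 30-min elk
data), ties broken toward the earlier fix; prey are sampled 4-6x faster
than predators, so a match almost always exists. A positive, significant
`b1` means real steps ended near parturient females more often than
habitat-matched random movement can explain: active search rather than
incidental encounter.

Numerical details:

- The conditional-logistic likelihood is maximized by Newton iteration
  (start 0, step-halving on likelihood decrease, gradient max-norm
  tolerance 1e-8, 100-iteration cap). Standard errors come from the
  inverse observed information. The implementation is cross-checked in the
  tests against dense grid search and against an independent library
  implementation.
- Covariates with no within-stratum variation are unidentifiable and are
  dropped with a record; coefficients walking beyond 15 on standardized
  scales are flagged as separation (non-convergence), never reported
  silently.
- Continuous covariates (canopy, ruggedness, ln distances, ln step length)
  are standardized over the pooled design of the fit — observed plus random
  rows — so coefficients are comparable within a fit. cos(turn) is already
  bounded in [-1, 1] and is left unscaled (configurable). Distances use
  ln(1 + d) so on-feature points are defined.
- Vegetation class enters as dummies with open forest as the reference.
- Random endpoints falling off the raster are dropped; a stratum is dropped
  if its observed endpoint is off-raster or no random endpoint survives.
- One pooled fit per species (or species-sex subset: filter the fixes and
  refit, as for sex-specific bear models); strata are steps, not animals.

### 3. Parturition-habitat RSF

Used points are all fixes of collared females in the 7 days immediately
following a parturition event; availability is 10 uniform random points per
used point drawn (with replacement) over the entire area used by the prey
species, taken as the convex hull of all its fixes (a supplied polygon is
also accepted). A binomial GLM with logit link fits the full 10-covariate
design — canopy, ln distance to road, ln distance to water, ruggedness,
shrub cover, forb cover, slope, aspect, elevation, vegetation class — with
no model selection, since the goal is a predictive surface rather than
inference on individual resources. The selection surface is
w(x) = exp(beta' x_std) per 30-m cell, excluding the intercept (which only
absorbs the availability ratio; the tests verify the surface ranking is
invariant to that ratio). Aspect is circular and is coded as sin/cos by
default; a raw-degrees mode reproduces the single-covariate formula
literally for comparability.

### 4. Birth-pulse phenology tracking

The weekly mean RSF score over each predator's fixes (15 April - 31 July)
is the response of a linear mixed model with a random intercept per animal
and Julian week — linear, or linear plus quadratic — as fixed effects.
Julian week is ceil(day-of-year / 7), week 1 = days 1-7. The week covariate
is centered at the midpoint of its observed range and scaled to unit sd
before squaring, keeping the two terms nearly orthogonal. Fits use maximum
likelihood (not REML) so the likelihood-ratio test between the nested forms
is valid; REML is available behind a flag for variance reporting. Weekly
means are unweighted; records need >= 1 fix (configurable); raw w(x) scores
are used (an optional min-max rescale exists for cross-fit comparability).
A supported concave quadratic with vertex at the birth-pulse peak is the
signature of a predator shifting habitat use to track neonate availability;
`peak_week` back-transforms the vertex -b/(2a) to the week scale.

The ML surface near the random-effect variance boundary can defeat any
single optimizer, so the mixed fit takes the best likelihood over several
optimizers; a variance collapsing to zero is flagged singular and the model
degenerates gracefully to ordinary least squares.

## Synthetic data: what it emulates and what it does not

The generators encode the study conditions all validation rests on:

- **Landscape** — a 4 x 4 km grid of 30-m cells (desk-scale stand-in for a
  study-area raster stack). Canopy, shrub, forb, ruggedness and elevation
  are Gaussian random fields with configurable mean, sd and smoothing
  length scale (scale 0 gives white noise); slope and aspect are derived
  from the elevation gradient so terrain layers are mutually consistent;
  vegetation class (open forest / closed forest / grassland / other, with
  proportions 0.35 / 0.30 / 0.25 / 0.10) is cut from a latent smooth field
  at matching quantiles; roads and water are random transects with true
  Euclidean distance layers.
- **Prey** — elk-like defaults: 30-min fixes; pre-partum correlated random
  walk with Gamma(1.2, 250 m) step lengths and von Mises(0, 0.5) turns
  (daily MCPs almost always far above the 30-ha threshold); birth
  day-of-year Normal(147, 7) — a late-May pulse peaking 27 May, matching
  the reported elk phenology; birth sites placed with probability
  proportional to exp(beta' z) over the landscape (the generative analogue
  of an RSF); from birth, every fix within 50 m of the site for 144 h
  (detectable: >= 120 h), then a disc of allowed radius growing at 15 m/h —
  the herd-rejoining phase, which real data constrain only loosely and
  which is an explicit free choice of the simulator.
- **Predators** — cougar-like defaults: 3-h fixes, offset-jittered per
  animal so exact timestamp coincidence with prey is rare and the
  nearest-fix matching rule is genuinely exercised; each step chosen among
  M = 50 candidate endpoints from the movement kernels with probability
  proportional to exp(beta_true' z + beta_enc * enc), where enc is computed
  by the same code the analysis uses. M is deliberately larger than the
  analysis-side K = 20: it controls sampler fidelity, not estimation. An
  optional Gaussian-in-time attraction to a habitat surface (amplitude 1.5,
  sd 12 d, peaking at the birth pulse) produces the phenology-tracking
  "searching" scenario, and an optional quadratic home-range penalty
  (strength 1 at scale 800 m) produces range residency. Range residency is
  used in the phenology scenarios because the mixed model's random
  intercept describes animals with stable home ranges; an unconstrained
  random walk drifts across the landscape and autocorrelates weekly scores
  beyond what the model assumes. Phenology simulations start two weeks
  before the 15 April window opens: animals begin at their home-range
  center and need a burn-in to equilibrate to the range's stationary
  distribution — without it, the shared relax-outward transient mimics a
  seasonal trend and inflates the null LRT rejection rate (measured ~11-15%
  without burn-in vs ~6% with, against a 5.5% rate when records are drawn
  from the fitted model itself). Weekly records in these scenarios require
  >= 25 of a full week's ~56 fixes, dropping the truncated edge weeks whose
  high-variance means sit at maximum leverage for the quadratic term.

Not emulated: GPS fix failure and location error, neonate mortality (females
that lose young remain "parturient" for the whole window, as in real data
where fates are unknown), uncollared prey, diel activity rhythms, and
multi-year data. Passing tests therefore demonstrate estimator correctness
under the stated movement models, not robustness to these field realities —
all of which dilute rather than inflate an encounter signal.

## Validation quantities and problem sizes

The suite and `scripts/acceptance.py` recompute, from scratch:

- Detector: 30 parturient elk-like animals over 60 d -> sensitivity, mean
  |timing error| (<= 24 h required; field validation of the method reports
  errors of the same order), false-positive rate on 30 non-localizing
  controls (< 10%).
- SSF: mean encounter coefficient over 20 replicates of 15 predators x
  90 d with generative beta_enc = 0.9 (required inside [0.7, 1.1]; residual
  attenuation comes from finite candidate sets and kernel refitting); Wald
  rejection rate over 200 indifferent-predator replicates (6 predators x
  45 d) within the binomial 95% band around 5%.
- RSF: 1000 used points sampled proportional to exp(beta' z) -> every
  generative coefficient within 2 SE (after aligning the generator's
  grid-sd scale with the fit's design-sd scale, an exact reparametrization);
  cell-wise Spearman correlation >= 0.99 between surfaces fitted at
  availability ratios 5 and 10.
- Phenology: quadratic-LRT rejection in >= 80% of 100 searching replicates
  (10 predators x 15 weeks) and near 5% of 100 indifferent replicates; mean
  recovered peak week within 1 week of the generative attraction peak
  (day 147 expressed on the week-bin axis, (147 + 3) / 7 ~ 21.4, since bin
  w is centered on day 7w - 3).
- End to end: detector-inferred events (not truth) feed the SSF and RSF;
  the searching predator's encounter coefficient remains positive and
  significant despite detector timing error.

Sizes were chosen so estimators sit in their asymptotic regime while
hundreds of replicates remain cheap on one core; they are deliberately
smaller than a multi-year field system.

## Known limitations

- The encounter indicator uses the mother as a proxy for the neonate; the
  generators encode the same proxy, so the validation cannot quantify
  mother-neonate separation bias.
- The conditional-logistic fit treats strata as independent; serial
  dependence between consecutive steps is ignored, as in the standard SSF
  formulation.
- The mixed model has no temporal autocorrelation term; under strongly
  drifting (non-resident) predators the LRT is anticonservative.
- Movement kernels are fitted once from observed steps rather than jointly
  with selection (no integrated SSF), which mildly attenuates coefficients.
- Coordinates are exact planar meters; there is no CRS handling.
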