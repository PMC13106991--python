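# Methods

## Scope and data model

`ruffnest` implements a daily nest survival (DSR) analysis for ground-nesting
waders on a grazed coastal meadow, together with a synthetic-data generator
that emulates the study design it was built for: ~275 ruff nests monitored
over six breeding seasons, four competing failure causes (predation,
storm-surge flooding, cattle trampling, abandonment) and a clutch-protection
intervention that replaces high-risk clutches with dummy eggs while the real
clutch is machine-incubated.

A nest is active on the closed day interval [lay_day, end_day]; the model
considers at most 26 daily transitions after laying (t = 0 is the lay day,
alive by definition).  For field data, lay days are back-dated from hatch
dates using a 21-day incubation period and a laying interval of 1.25 days
per egg after the first; the rounding convention (round half up, multiplier
`clutch_size − 1`) is isolated in `exposure.estimate_timeline`.  Activity
recorded beyond 26 days is truncated: a failure past the cap never happens
inside the modeled window, so the nest counts as a window survivor.

## Survival model

Conditional on being alive at t−1, nest i survives day t with probability

    S_it = inv_logit(x_it' β + σ_year · u_year(i)),  u_year ~ N(0, 1)

The design stacks, per nest-day: scaled nest-to-nest distance and its
square, scaled lek distance and its square, scaled lay date, scaled nest
age (the day index t, the only time-varying covariate), the binary
artificial-incubation indicator, and scaled path/edge/shore distances.
Scaling is centring and dividing by the sample SD *within year*; nest-level
covariates are scaled over nests, age over all realized nest-day rows.
Quadratic terms are squares of the scaled linear term (squaring after
scaling; the alternative order is not distinguishable from reported tables
and this choice keeps the intercept interpretable at the covariate mean).

Failures contribute log(1 − S_iT) on their last day, survived transitions
log S_it; censored histories contribute survival terms only.  Censoring on
a failure date means the history is informative through the previous day.
Two conventions matter for protected nests in the naturally-incubated
variant: flood-protected clutches are recorded as *failed* on the
intervention day (the surge was certain to destroy them), while
trampling-protected clutches are *censored alive* on the intervention day
(trampling is an ongoing threat with no predictable failure day).
Protections of 24 h or less do not count as artificial incubation.
Unknown-cause deaths are failures in the overall scenario and censored in
both cause-specific scenarios, because the cause cannot be attributed.

Priors follow a weakly-informative standard set: Gaussian(0, 2) for the
continuous fixed effects (the intercept is treated as one of them),
Cauchy(0, 2) for the categorical incubation effect, N(0, 1) for the
non-centred year deviates, and half-Cauchy(0, 5) for σ_year.  One published
peculiarity is intentionally not replicated: the original report shows
σ_year lower credible bounds of ≈1.01 in every model, which is not a
property of a half-Cauchy posterior; this implementation uses the standard
half-Cauchy and its σ_year intervals can extend below 1.

## Posterior computation

No external probabilistic-programming backend is used; the sampler
(`ruffnest.mcmc` + `dsrmodel._run_chain`) is part of the package and its
contract is the posterior, seed-reproducibility and the diagnostics:

- **Fixed effects**: Hamiltonian Monte Carlo with a fixed dense metric,
  the Schur complement (conditional covariance given the year terms) of a
  Laplace approximation at the posterior mode; dual-averaging step-size
  adaptation toward 0.8 acceptance during warmup; jittered trajectory
  lengths.
- **Year deviates and log σ_year**: stepping-out slice samplers on their
  1-D conditionals (the deviates are conditionally independent given the
  intercept).
- **Interweaving**: two ancillarity-sufficiency moves per iteration — a
  centred re-update of σ_year given the realized year effects a = σ·u
  (likelihood-free), and an exact Gaussian resample of the shift δ in
  (β0 + σδ, u − δ), which the likelihood cannot see.  These remove the two
  slow directions (the u–σ funnel and the intercept–mean(u) ridge) that a
  fixed-metric joint HMC cannot traverse.

Four chains run independently from a jittered Laplace start; 5000
iterations with 2500 warmup reproduce the published protocol, and reduced
protocols (1500–2500 iterations) are used in the test harnesses where
stated.  Identical seeds give byte-identical draws.  Convergence is gated
on the split-chain Gelman–Rubin statistic (chains of length ≥ 4 are halved;
R̂ = sqrt(((n−1)/n·W + B/n)/W)) with the conventional 1.10 threshold; the
implementation agrees with arviz's split R-hat to machine precision and
was validated during development against a JAGS fit of the identical model.
A maximum-likelihood oracle without year effects
(`dsrmodel.mle_oracle_fit`) provides an independent location check on
large simulated datasets.

A design column that is constant across all nest-days (e.g. the incubation
indicator in a dataset with no protected clutch) is dropped with a warning:
its coefficient would simply reproduce its heavy-tailed prior.

## Synthetic-data generator

Geometry is planar and metric (UTM-like; the meadow is km-scale, so no
geodesic math).  The default landscape is a 3000 m × 1270 m meadow with a
wavy shoreline along one long side, the outer fence (meadow edge) along the
other, three shore-parallel paths plus two transects, and 12 leks of which
about four are active in any year.  Nests are uniform in a 430–680 m band
from the shore; with 46 nests/year this density yields a mean daily
nearest-active-neighbour spacing near the 121 m target, and mean distances
to leks/paths/edge/shore near the field study's scales (≈350/65/690/530 m).

Daily fates resolve competing causes in a fixed order — flood → trampling →
predation → abandonment — because floods are day-specific catastrophes and
trampling a site-specific pressure, while predation and abandonment are
background hazards.  Floods are discrete events (year, day, reach from the
shoreline); cattle release happens on a fixed day per year inside a grazing
zone; predation follows the logit model above; abandonment is a small
constant daily hazard.  Each nest owns a counter-based random stream
(Philox keyed by a per-nest seed), so re-walking a nest under a protection
policy replays the same daily uniforms: a policy that only lowers hazards
can never make a nest fail earlier (pathwise monotonicity), and the whole
dataset is byte-identical under a fixed seed.

The protection policy mirrors the field practice: flood-threatened nests
(within the surge's reach) have their clutch replaced on the surge day with
perfect foresight; nests in the grazing zone are protected a configurable
number of days (default 3) before cattle release.  From the intervention
day the natural clutch is immune to the protected cause; while dummy eggs
are in place, predation and abandonment hazards are rescaled by multipliers
(defaults 0.5 and 2.5: predators discriminate dummy eggs, while cattle
disturbance of dummy clutches promotes abandonment).  A flood protection
lasting one day (24 h) is flagged as not artificially incubated.

The cause-specific hazard levels are **calibration choices, not
estimates** — the field study does not identify them.  Defaults (generative
intercept 4.5 on the logit scale, flood lethality 0.9, trampling hazard
0.05/day, abandonment 0.005/day) were fixed once to reproduce the published
fate mix (~40–45% hatching; predation roughly half to two-thirds of
failures; trampling ≈ 14%, with ≈12 flood-protected and ≈30
trampling-protected clutches per six seasons).

Two properties of real data are deliberately not emulated: nest discovery
(histories start at the lay date, as the flotation back-dating reconstructs
them, so the survivor bias of late discovery is reproduced rather than
corrected) and unknown/unknown-cause fates (the generator always knows the
fate; the encoders' handling of unknown fates is exercised with constructed
records in the tests).  Renesting, brood survival and within-season
shoreline movement are out of scope.

## Parameter-recovery harness and what it shows

The recovery harness (`scripts/acceptance.py`, `tests/test_acceptance.py`)
simulates ~275 nests × 6 years with predation as the only active hazard,
fits the Overall model at 4 × 1500 iterations, and counts how often each
coefficient's 95% CrI covers its generative truth over 20 replicates.  The
hard gate applies to the four parameters whose truths define the exercise
(nest-distance linear and quadratic terms, nest age, σ_year), plus a pooled
≥ 80% bound over all coefficients; an individual nuisance coefficient at
~93–95% true coverage can graze the binomial tail of a 20-replicate count,
so per-coefficient counts for the full set are reported rather than gated.

Two subtleties dictated the harness design.  First, the mean daily
nearest-active-neighbour distance is outcome-dependent: a nest that fails
early averages only its early days, when more neighbours are active, so a
covariate recomputed from *realized* windows is endogenous to the outcome
it predicts.  The generator therefore defines spacing from *scheduled*
(full 26-day) windows — generatively, spacing is a nest-level trait fixed
at laying — and the recovery fits use that same covariate table, making the
model correctly specified.  Second, the real intervention only materializes
for nests still alive on the intervention day — selection on survival that
would bias a zero-truth incubation coefficient — so the harness flags
incubation by intention to treat (grazing-zone membership and laying
schedule only).  The analysis-side defaults (`nest_distance_table` on
realized windows, realized protection flags) reproduce the field
constructions, including their survivor effects; passing recovery therefore
validates the encoding, likelihood and sampler, not the field covariates'
freedom from those biases — caveats that apply equally to the original
constructions.

Problem sizes used throughout the harnesses (2000-nest closed-form cohorts,
20 × 276-nest recovery replicates, 2500-iteration gate fits) were chosen so
the whole suite documents the method at useful precision in minutes on a
single core.

## Numerical notes and degenerate inputs

- Zero within-year variance in a covariate scales to 0 with a warning;
  missing nearest-neighbour distances (no concurrently active neighbour)
  are mean-imputed (scaled 0) with a warning.
- Likelihoods use the softplus form y·η − log(1+e^η); an S of exactly 0 or
  1 at an observed transition yields −inf (rejected by the sampler).
- The Laplace Hessian is finite-differenced from the analytic gradient and
  eigenvalue-clipped to stay positive definite.
- Zero failures triggers a warning (intercept identified only by the
  prior); complete separation leaves the MLE oracle ridge-bounded with a
  warning.
- Days with no active neighbour are dropped from the daily-distance mean,
  not imputed; a nest with no temporal overlap at all has a missing
  distance.
- Prediction curves standardize the grid through the across-year average of
  the year-wise scalings and hold the year effect at 0 (fixing rather than
  averaging over years; the difference is a rigid shift of the curve well
  inside its credible band).
- Lek "centres" are the stored lek points; ties in nearest-lek distance
  return the common distance.
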