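# ruffnest

Bayesian daily nest survival (DSR) analysis for ground-nesting waders on
grazed coastal meadows, built around the breeding ecology of the ruff
(*Calidris pugnax*) at the Bothnian Bay: nests fail to predation, storm-surge
flooding, cattle trampling and abandonment, and managers protect high-risk
clutches by swapping the eggs for plastic dummies while the real clutch is
artificially incubated.  The package is for quantitative ecologists who want
a fully testable version of this analysis: a synthetic-data generator with
the same statistical and spatial structure as the field study, the spatial
covariate construction, the censoring/encoding rules, the hierarchical
survival model, and the reporting layer.

## The model

Nest *i* on day *t* after laying survives with probability
*S<sub>it</sub>*, modelled on the logit scale:

```
logit S_it = β0 + β1·nests_i + β2·nests_i² + β3·leks_i + β4·leks_i²
           + β5·laydate_i + β6·age_t + β7·incubation_i
           + β8·paths_i + β9·edge_i + β10·shore_i + σ_year·u_year(i)
```

with the Bernoulli-chain likelihood `y_it ~ Bernoulli(y_i,t-1 · S_it)` over
t = 1..26 (the modeled activity window after laying).  Covariates are
centred and scaled within year; quadratics are squares of the scaled linear
terms.  Priors: Gaussian(0, 2) on continuous fixed effects, Cauchy(0, 2) on
the categorical incubation effect, N(0, 1) on the non-centred year deviates
and half-Cauchy(0, 5) on σ_year.  Three mortality scenarios (overall /
no-predation / predation-only) differ in which fates are failures versus
censorings, and two dataset variants either keep protected nests' final
fates or cut them at the day of intervention.  Effects whose 95% credible
interval excludes zero are reported as "clear".

Sampling runs four independent chains of in-package MCMC (Hamiltonian
updates for the fixed effects with a Laplace-approximation metric, slice
updates for the year deviates and the scale, with interweaving moves), and
convergence is gated on split-chain Gelman–Rubin R-hat < 1.10.

## Worked example

```python
from ruffnest import (ScenarioConfig, simulate_dataset, nest_distance_table,
                      build_design, DsrModelSpec, sample_posterior,
                      posterior_summary_table)

nests, landscape = simulate_dataset(ScenarioConfig(rng_seed=1))
design = build_design(nests, nest_distance_table(nests, landscape),
                      scenario="overall", variant="all_nests")
draws = sample_posterior(DsrModelSpec(chains=4, iterations=2500,
                                      warmup=1000, rng_seed=7), design)
print(posterior_summary_table(draws).round(3).to_string(index=False))
```

prints (abridged; ~30 s on one CPU):

```
     variable   mean    sd  cri_2.5  cri_97.5  clear_effect
    intercept  3.544 0.314    2.904     4.081          True
   dist_nests  0.862 0.126    0.616     1.109          True
dist_nests_sq -0.216 0.049   -0.307    -0.117          True
     nest_age -0.493 0.085   -0.665    -0.330          True
   incubation  1.288 0.289    0.723     1.858          True
   sigma_year  0.569 0.341    0.207     1.401          True
max R-hat 1.002 (converged; gate at 1.1)
```

Read: daily survival peaks at intermediate distances to other nests
(positive linear, negative quadratic), declines with nest age, and
dummy-egg-protected clutches survived better against predation; the year
effect spread σ_year is moderate.  `examples/` contains one short script
per capability (simulation, distances, encodings, fitting, prediction
curves) with commentary on each printed number.

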