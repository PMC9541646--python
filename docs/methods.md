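# Methods

## The model

`dynsad` treats the species abundance distribution (SAD) of a community as
a *dynamic* object generated by multispecies Gompertz population dynamics,
and estimates its parameters by fitting an intercept-only Poisson
generalized linear mixed model (GLMM) to count data.

### Process scale

Log abundance `X_i(t)` of species `i` follows a Gompertz-regulated
diffusion: the expected change over `dt` is `(r_i - gamma * X_i) dt`, with
species-specific environmental noise of variance `sigma2_s dt`, a common
environmental shock of variance `sigma2_E dt` shared by all species, and
growth rates `r_i ~ N(mu_r, sigma2_r)` fixed per species (quenched
heterogeneity).  At stationarity:

* relative log abundance (a species' deviation from the community mean)
  has variance `sigma2_s/(2 gamma) + sigma2_r/gamma^2` — the width of the
  SAD;
* the covariance of one species' log abundance across a lag `u` is
  `sigma2_r/gamma^2 + (sigma2_s/(2 gamma)) e^{-gamma u} +
  (sigma2_E/(2 gamma)) e^{-gamma u}`;
* `1/gamma` is the mean return time to equilibrium and
  `ln K = r/gamma` the log carrying capacity.

### Observation scale

Counts are `y ~ Poisson(exp(eta))` with
`eta = beta0 + h_i + e_it + c_t + eps_ijt + u_jt`, where `h` is an iid
among-species effect (variance `sigma2_h`), `e` a per-species series with
Ornstein–Uhlenbeck correlation `exp(-gamma |t_l - t_k|)` (variance
`sigma2_e`), `c` a common per-time-point series with correlation rate
`gamma_c` (variance `sigma2_c`), `eps` an optional observation-level
(overdispersion) effect and `u` an optional iid sampling-unit effect.
Matching the two covariance functions gives the exact correspondence

    sigma2_h = sigma2_r / gamma^2
    sigma2_e = sigma2_s / (2 gamma)
    sigma2_c = sigma2_E / (2 gamma_c)

so every variance component has a population-dynamic reading.  The
intercept is confounded with sampling intensity `nu` (fraction of the
community counted): `beta0_estimated = ln(nu) + ln K`.

Spatial data use the same machinery with locations as correlated units,
correlation `exp(-alpha d_kl)` in great-circle distance, and time points
as independent groups; temporal models group by location.  Space and time
are always fitted as two separate models, never jointly.

The type carries a separate common-environment rate `gamma_c`
(`alpha_c`), defaulting to the species-specific rate: the single-rate
form is the process-model prediction, while separate rates let the
common-environment synchrony decay on its own scale (e.g. through
competition for shared resources); `ModelSpec(separate_common_rate=True)`
selects it.

Observation-level variance enters the denominator of the
relative-abundance similarity `rho_x(u) = (sigma2_e e^{-gamma u} +
sigma2_h) / (sigma2_e + sigma2_h + sigma2_o)` because it is genuine
lag-0 within-replicate variance; with no observation effect this reduces
to the two-component form.  The mean-abundance similarity is
`rho_xbar(v) = sigma2_c e^{-gamma_c v} / (sigma2_c + sigma2_u)`.

## Estimation

The marginal likelihood integrates the random effects out by a Laplace
approximation: an inner Newton maximisation of the joint log density over
the random-effect vector (backtracking line search, monotone ascent,
gradient tolerance 1e-8), plus half the log determinant of the negative
joint Hessian `Z' W Z + Sigma^{-1}`.  The outer optimisation is L-BFGS-B
over `(beta0, log variances, log rates)` — log scales make the positivity
constraints box-free — with relative function tolerance 1e-9, default
three starts (the data-driven start plus ±50% jitter on the variance
scale).  Starting values: `beta0` from the log grand mean count, the
method-of-moments variance of `log(count+1)` split evenly across
components, rates at 1/(median lag).

Two linear-algebra paths produce identical likelihoods (verified to
1e-13 in the tests):

* **dense** (up to 900 random effects): Cholesky factorisations plus an
  *analytic gradient* of the Laplace objective obtained by implicit
  differentiation through the inner mode and the log-determinant
  (the mode-movement term uses `diag(Z H^{-1} Z')`, cheap because `Z` is
  an indicator matrix);
* **sparse** (larger problems): SuperLU with symmetric minimum-degree
  ordering and finite-difference outer gradients (step 1e-5, chosen to
  sit above the inner-solver noise floor).

On equally spaced grids the OU correlation is an AR(1) whose inverse is
analytically tridiagonal; the model detects this and uses the closed-form
precision and log-determinant (`(T-1) log(1-phi^2)`), falling back to a
dense Cholesky of the kernel matrix for irregular spacings or distance
matrices.  Both routes agree to numerical precision on regular grids.

Variance estimates below 1e-8 are flagged as boundary estimates, not
errors.  `DynamicSADResults.diagnostics()` additionally flags decay rates
whose likelihood is flat over a 10x range and correlated effects
estimated from four or fewer units per group (where decay-rate
uncertainty is necessarily large).

Standard errors come from the parametric bootstrap, not from the outer
Hessian: each replicate simulates counts from the fitted model on the
original observation grid, refits the same specification warm-started at
the original estimates (one dispersed fallback start), and equal-tailed
percentile intervals are taken over converged replicates using empirical
order statistics — so strictly monotone transforms (e.g. return time
`1/gamma`) commute exactly with the interval endpoints.  Replicate refits
use slightly relaxed tolerances (outer 1e-7, inner 1e-6), which perturb
the optimum far below the width of any interval.  Non-converged
replicates are excluded and counted; more than 50% failures is an error.
Per-replicate seeds derive from the master seed by a counter scheme and
are logged in the result.

## The simulator

`simulate()` integrates the discrete-time version of the process:
`X_{t+1} = X_t + r_i - gamma X_t + eta_it + eps_t` (Euler step, dt = 1,
noise added once per step), Poisson-sampling counts with intensity `nu`.
This is an AR(1) with coefficient `1 - gamma`: stationary mean
`mu_r/gamma`, species-deviation variance `sigma2_s/(1-(1-gamma)^2)` —
approaching the continuous value `sigma2_s/(2 gamma)` as `gamma` shrinks
— and lag-u autocorrelation `(1-gamma)^u`.  The deliberate gap between
the discrete generator and the continuous-time model underlying the GLMM
is the point of the simulation study: estimation is accurate under weak
regulation and degrades as `gamma` approaches 0.5, where within-species
variance and the decay rates are overestimated.  Defaults are the
reference study conditions: 100 species, 370 steps with 320 discarded as
burn-in, all species starting at the mean log carrying capacity (10), and
the factorial design grid crosses `gamma ∈ {0.05, 0.1, 0.5}` (a flag
switches to {0.01, 0.1, 0.5}), within-species share
`sigma2_e ∈ {0.2, ..., 0.8}` with `sigma2_h = 1 - sigma2_e`,
`sigma2_c ∈ {0.01, 0.1}` and `nu ∈ {0.01, 0.1, 0.5}`.

Latent log abundances beyond 700 abort the run rather than being clipped;
silent clipping would distort the moments the tests check.

What the generator does *not* emulate: trends or regime shifts in the
environment (the process is stationary), interspecific density
dependence, demographic stochasticity as a separate component,
immigration, and detection processes richer than binomial thinning
(thinning is exactly the Poisson intensity `nu`).  Passing tests
therefore demonstrate correctness of the estimator under the model's own
assumptions, not robustness to their violation.

## Problem sizes used in tests and the acceptance script

Replicated experiments run at reduced scale, chosen once as the smallest
sizes a practitioner would still call a community survey: estimator-bias
checks use the reference cell (100 species, 50 retained time points,
`gamma = 0.05`, `nu = 0.5`, `sigma2_e = 0.2`, `sigma2_c = 0.1`) with 25
replicates in the tests and 15 in the acceptance script; the
strong-regulation bias-direction check uses 30 species and 25 time
points; bootstrap coverage uses 20 species, 10 time points, mean log
carrying capacity 6, with 100 outer replicates x 100 bootstrap replicates
in the tests and 50 x 80 in the acceptance script.  Production analyses
should use the 1000-replicate bootstrap default.

## Data handling

Input is a long table (species, time, location, replicate, count) with
integer counts; a reader for the BioTIME raw-CSV dialect is included with
a configurable column map (column names vary across BioTIME exports), a
choice of location identity (coordinate pair or plot label) and an
optional calendar-date replicate key for repeated within-year sampling.
Zero-filling inserts an explicit zero for every registered species absent
from a recorded (time, location, replicate) sampling event and never
invents new events; it is idempotent.  After splitting by habitat label
the species registry is restricted to species observed in the subset —
each split is modelled as its own community (the global-registry
alternative is a flag away by zero-filling before splitting).  Distances
are great-circle kilometres (Earth radius 6371 km) or a user-supplied
matrix.

## Known limitations

* The Laplace approximation is least accurate for small counts with few
  replicates; the quadrature cross-check bounds the error at 0.05 nll
  units on such instances, but no such bound is available for the full
  correlated models.
* Decay rates estimated from few units (the fish case has four years)
  are weakly identified; the diagnostics flag this rather than fix it.
* Percentile intervals are first-order; BCa or basic intervals are not
  implemented.
* No covariates beyond the intercept, no non-Poisson responses, no
  interspecific interaction (latent-factor) terms, and no joint
  space-time covariance.
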