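# dynsad — dynamic species abundance distributions as Poisson GLMMs

`dynsad` is for community ecologists who want population-dynamic
parameters out of ordinary community count data (species x time x
location tables, e.g. BioTIME exports).  It fits the *dynamic species
abundance distribution*: the distribution of (log) abundances across the
species of a community, together with how it moves in time and space.

## The model

Log abundance of species *i* follows Gompertz-regulated dynamics

    dX_i = (r_i − γ X_i) dt + σ_s dB_i(t) + σ_E dE(t),
    r_i ~ N(μ_r, σ_r²),

with density regulation γ (1/γ = mean return time), species-specific
environmental variance σ_s², common (synchronising) environmental
variance σ_E², and heterogeneity in growth rate / carrying capacity σ_r².
Observed counts are Poisson samples of a fraction ν of the community.

At stationarity this process is *exactly* an intercept-only Poisson
lognormal mixed model with log mean

    η_ijt = β₀ + h_i + e_it + c_t + ε_ijt,

where h ~ N(0, σ_h² I) is among-species heterogeneity,
e has per-species Ornstein–Uhlenbeck correlation e^{−γ|t_l−t_k|}
(variance σ_e²), c is a common time effect with its own rate γ_c
(variance σ_c²), and ε is optional observation-level overdispersion.
The dictionary between the two scales is

    σ_h² = σ_r²/γ²,   σ_e² = σ_s²/2γ,   σ_c² = σ_E²/2γ_c,   β̃₀ = ln ν + ln K.

Spatial data use the same model with locations as correlated units
(correlation e^{−α d} in km) and time points as independent groups.
The package fits the model by maximum likelihood (Laplace-approximated
marginal likelihood, Newton inner solver, analytic or finite-difference
outer gradients), partitions the SAD variance into heterogeneity /
environment / observation shares, evaluates community-similarity curves
ρ_x(u) and ρ_x̄(v), and quantifies uncertainty by parametric bootstrap.
A built-in simulator generates communities from the discrete-time
process, which is also how every test fixture is produced.

## Worked example

Simulate a 30-species community at weak density regulation (γ = 0.1,
log K = 5, ν = 0.5, σ_h² = 0.6, σ_e² = 0.4, σ_c² = 0.1), keep 25 annual
samples, fit the temporal model with separate decay rates, and bootstrap:

```python
from dynsad import SimulationConfig, simulate
from dynsad.model import DynamicSADModel, ModelSpec

g = 0.1
cfg = SimulationConfig(n_species=30, n_steps=345, burn_in=320, gamma=g,
                       mu_r=5*g, sigma2_r=g**2*0.6, sigma2_s=2*g*0.4,
                       sigma2_E=2*g*0.1, nu=0.5, seed=1)
table = simulate(cfg).to_table()

model = DynamicSADModel(table, ModelSpec(separate_common_rate=True))
res = model.fit(seed=0)
print(res.summary(nu=0.5))

boot = res.bootstrap(n_reps=200, seed=0, nu=0.5)
print(boot.intervals.loc[["sigma2_h", "sigma2_e", "sigma2_c", "gamma"]].round(3))
```

```
Dynamic species abundance distribution GLMM (Poisson, Laplace)
================================================================
dimension: temporal    observations: 750
species: 30    units: 25    groups: 1
log-likelihood: -3367.967    converged: True
----------------------------------------------------------------
parameter         estimate
beta0               4.0674
sigma2_h            0.3179
sigma2_e            0.5760
sigma2_c            0.0342
gamma               0.0802
gamma_c             0.3012
1/gamma              12.47  (years)
1/gamma_c             3.32  (years)
----------------------------------------------------------------
relative log abundance variance split: sigma2_h 36%, sigma2_e 64%
mean log abundance variance split:     sigma2_c 100%, sigma2_u 0%
population scale (nu=0.5): logK=4.76, sigma2_r=0.0020, sigma2_s=0.0924, sigma2_E=0.0206

          lower  upper
sigma2_h  0.000  0.690
sigma2_e  0.337  0.953
sigma2_c  0.007  0.083
gamma     0.045  0.147
```

Read the summary the way you would a field study: the point estimates put
36% of the SAD variance on species heterogeneity and 64% on
environmental fluctuations, the estimated return time 1/γ̂ ≈ 12 years,
and the population-scale line undoes the ν-confounding of the intercept
(log K = β̂₀ − ln ν).  The bootstrap intervals — equal-tailed percentile
intervals over refits of data re-simulated from the fitted model — are
wide, as they should be for one 25-year series of 30 species: the
interval for σ_h² comfortably covers the generating value 0.6 even
though the point estimate lands at 0.32, and γ̂'s interval [0.045, 0.147]
brackets the true 0.1.

Real data enter through `dynsad.read_biotime` (configurable column map,
coordinate- or plot-based location identity, calendar-date replicates),
`CommunityTable.zero_fill()` (explicit zeros for species missing from
recorded sampling events — always do this before fitting), and
`split_by_habitat` / `haversine_matrix` for spatial analyses.  A thin CLI
wraps the same calls: `dynsad simulate | fit | partition | similarity |
bootstrap | simstudy` (see `dynsad --help`).

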