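# lungcast

Small-area forecasting of cancer incidence counts. `lungcast` implements the
two-step pipeline used in spatial epidemiology to project, say, lung-cancer
cases ten years ahead for every local government area (LGA) of a state:

1. **Age-period-cohort (APC) projection.** Statewide counts on a Lexis grid
   follow `D_ap ~ Poisson(n_ap * rate_ap)` with a power link,
   `rate_ap = (A_a + d*p + P_p + C_c)^k` (default `k = 5`), detrended period
   and cohort effects, and a drift `d` that is extrapolated (optionally
   attenuated) over the horizon. Projected age-specific rates times
   projected populations give expected counts `e_it` per area and year; for
   observed years `e_it` comes from internal standardization, so
   `sum_i e_it` matches the observed statewide total in every year.

2. **Bayesian spatio-temporal Poisson model.** Area-year counts follow
   `Y_it ~ Poisson(mu_it)` with

       log mu_it = log e_it + alpha + x_i'beta + phi_i + nu_i + T_t

   where `phi` is an intrinsic CAR (ICAR) field on the area adjacency graph,
   `nu` an exchangeable area effect (the BYM convolution), `x_i` optional
   area-level covariate dummies (smoking, elderly, socio-economic quartiles;
   pollution; remoteness), and `T_t` either a centred linear+quadratic trend
   (Model A) or linear trend plus first-order random walk (Model B).
   Random-effect SDs get uniform(0.01, 10) priors, fixed effects vague
   normals. Fitting is by a two-chain Metropolis-within-Gibbs sampler with
   Gelman-Rubin monitoring; model choice uses DIC and a train/validation
   split scored by RMSE/MAE/MAPE.

Real registries of this kind are access-restricted, so the package ships a
first-class synthetic registry generator (lattice adjacency, growing and
ageing age-structured populations, ICAR risk surface, covariate effects,
Poisson counts) that reproduces the statistical structure the models assume;
every stage is tested against it. It is intended for biostatisticians and
cancer-registry analysts who want a transparent, scriptable alternative to
BUGS-style tooling.

## Worked example

Simulate a male-like registry (80 areas, 2001-2018), build offsets, project
rates, fit Model A, and forecast 2019-2028:

```python
import lungcast as lc
from lungcast.synthetic import PopulationPanel

graph = lc.make_lattice_graph(8, 10)                      # 80 areas
config = lc.SimulationConfig(seed=1, sex="male", gamma1=-0.006)
pops_full = lc.simulate_population(graph, 28, config)     # 2001-2028
pops = PopulationPanel(pops_full.areas, pops_full.years[:18],
                       pops_full.age_groups, pops_full.person_years[:, :18],
                       pops_full.age_edges)
covs = lc.sample_covariates(graph, [1, 17])
registry = lc.simulate_registry(graph, pops, covs, config)

rates = lc.age_specific_rates(registry.counts, pops.person_years)
e_obs = lc.expected_counts_observed(pops, rates)
apc = lc.APCModel(power=5.0).fit(lc.build_lexis(registry))
proj = apc.predict_rates(10)

data = lc.STData(registry.counts_total, e_obs, graph, registry.years, covs)
fit = lc.SpatioTemporalModel(temporal="quadratic", iterations=3000,
                             burn_in=1000, seed=1).fit(data)

tail = PopulationPanel(pops_full.areas, pops_full.years[18:],
                       pops_full.age_groups, pops_full.person_years[:, 18:],
                       pops_full.age_edges)
e_proj = lc.expected_counts_projected(tail, proj.rates[1:], proj.years[1:])
table = lc.forecast(fit, e_proj, tail.years, seed=1)
```

Output of the summary lines at the end of this script:

```
observed 2018 state total: 2699
forecast 2028 state total: 3340 (95% CI 2906-3818)
ten-year change: 23.75%
trend shares: {'increasing': 100.0, 'stable': 0.0, 'decreasing': 0.0}
max R-hat: 1.038
```

Reading: the posterior-predictive state total grows from 2,699 observed
cases in the last fitted year to a mean 3,340 in the final horizon year —
a 23.75% rise driven by population growth and ageing (the generative
age-specific rates *decline* slightly, as the fitted APC drift shows) —
and every area's mean projected annual count exceeds its observed average
by at least 5%, so all 80 areas are labelled "increasing". Both chains agree
(all potential-scale-reduction factors at or below 1.04).

The same pipeline is scriptable from the shell:

```sh
lungcast all --out-dir run1 --seed 1 --sex male --horizon 10
```

which writes counts/populations/covariates CSVs, the adjacency edge list,
expected counts, Lexis and projected-rate tables, posterior samples with a
manifest, forecast and trend CSVs into `run1/`.

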