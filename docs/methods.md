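# Methods

`lungcast` implements a two-step small-area forecasting pipeline for cancer
incidence counts, of the kind used to project lung-cancer burden across the
local government areas (LGAs) of an Australian state.

## The two-step model

**Step 1 — age structure.** Statewide age-specific incidence is modelled with
a Poisson age-period-cohort (APC) decomposition on a power scale,

    D_{a,p} ~ Poisson(n_{a,p} * rate_{a,p}),
    rate_{a,p} = (A_a + d * p~ + P_p + C_c)^k,      c = p - a,

with person-years `n` as exposure and `k = 5` by default (the power-5
convention of the cancer-projection literature; `power` is a parameter of
`APCModel`). `P` and `C` enter through bases orthogonal to the constant and
linear contrasts, so they have zero sum and zero slope by construction and
the drift `d` carries the single identifiable time slope. Projection extends
the drift over the horizon; the default "cut-trend" schedule damps the drift
increment to 75%/50%/25% over successive thirds of the horizon, a
conservative convention for decade-scale projections ("none" disables it).
Cohorts never observed in-sample reuse the last estimated cohort effect, so
projected tails cannot run away on an extrapolated cohort slope.

Age-specific rates — observed (internal standardization) for the fitted
years, APC-projected for the horizon — are folded with the (observed or
projected) population age structure into expected counts

    e_it = sum_a  n_{i,t,a} * r_{t,a},

so that for observed years `sum_i e_it` equals the statewide observed total
in every year. These are the multiplicative offsets of step 2; the
published description of the observed-year construction is circular as
written, and the internal-standardization form above is the standard
construction that gives the offsets the calibration property the relative-
risk model requires. Cells with no population have their `e` floored at
1e-6 and are excluded from the likelihood.

**Step 2 — space and time.** Area-year counts follow a Bayesian
spatio-temporal Poisson model,

    Y_it ~ Poisson(mu_it)
    log mu_it = log e_it + alpha + x_i' beta + phi_i + nu_i + T_t

with `T_t = gamma1*t~ + gamma2*t~^2` (Model A, "quadratic") or
`T_t = gamma1*t~ + omega_t` with a first-order random walk `omega`
(Model B, "rw1"); `t~` is the centred year index, which decorrelates the
linear and quadratic coefficients. `phi` is an intrinsic CAR (ICAR) field
on the area adjacency graph — each area's effect conditionally normal around
the mean of its neighbours with variance `sigma_phi^2 / n_i` — and `nu` is
exchangeable normal ("unstructured"); together they form the usual BYM
convolution. Identification: `phi` (and `omega`) are constrained to sum to
zero; degree-0 areas have `phi` pinned at 0 and rely on `nu`. Priors follow
the study design: uniform(0.01, 10) on every random-effect SD and N(0, 100^2)
on the intercept, covariate and temporal coefficients. Covariates are
area-level categories coded as dummies (quartile 1 / "none" / "metro" as
references). Two temporal reductions, `"linear"` and `"none"`, exist purely
for nesting checks and low-dimensional oracle comparisons.

Spatio-temporal interaction effects are deliberately out of scope: the
temporal terms are shared across areas, so area-specific trend departures
are not modelled.

## MCMC

`SpatioTemporalModel.fit` runs two (or more) Metropolis-within-Gibbs chains
from different initial values (chain 1 at prior means; chain 2 dispersed,
with `alpha` offset by 1 and SDs at 0.1 and 5). One sweep:

* `phi`, block-updated over graph colour classes (no two areas in a class
  adjacent, so their full conditionals are independent). The proposal is the
  Gaussian given by a Newton (second-order) approximation of the exact full
  conditional — Poisson likelihood of the area's row plus the ICAR
  conditional — whose parameters depend only on the data and the other
  areas, so the Metropolis correction is exact. Acceptance is ~99% at the
  study's count magnitudes.
* An exact Gibbs swap of `phi_i` vs `nu_i` holding their sum fixed (the
  likelihood only sees the sum, so the conditional is Gaussian). This is
  what lets the two variance parameters of the BYM convolution mix.
* Random-walk Metropolis for `nu` (per-area), `alpha`, each `beta_j`,
  `gamma1`, `gamma2`, and the RW1 states (even/odd alternation), with
  per-block proposal scales adapted toward 30-45% acceptance during burn-in
  only (Robbins-Monro on the log scale, frozen afterwards).
* Exact Gibbs translations along likelihood-invariant directions:
  `(alpha, nu)`, `(beta_j, nu over its areas)` and `(gamma1, omega)`; these
  remove the fixed-effect / random-field confounding that otherwise makes
  the scalar chains crawl.
* Log-scale Metropolis for `sigma_phi`, `sigma_nu`, `sigma_omega`, with the
  ICAR kernel exponent `n - (number of connected components)`.
* Recentring of `phi` (and `omega`) to zero sum, with the removed mean
  absorbed into `alpha` so the likelihood is untouched.

Deviance (`-2 log L`, including the `log Y!` terms) is stored per retained
sample. Convergence is monitored with the classic Gelman-Rubin potential
scale reduction factor on the scalar parameters and the deviance; R-hat
above 1.1 attaches a warning to the fit but is never fatal. At the default
2 x 4000 iterations (1000 burn-in) on an 80-area, 18-year panel, all
monitored R-hat values sit at or below ~1.02 and a fit costs a few seconds.

## Model comparison, validation, forecasting

* **DIC** uses the plug-in deviance at the posterior mean of the linear-
  predictor parameters (`pD = Dbar - D(theta_bar)`), the classic BUGS focus
  on `mu`.
* **Train/validation:** models are fitted to the first years (the study used
  2001-2013), and later years are predicted by extending the temporal
  structure — the quadratic analytically, the RW1 by forward simulation per
  posterior sample, so the predictive mean integrates over the walk. The
  validation offset follows the two-step design: APC fitted to the training
  Lexis table, projected over the validation horizon, applied to the
  observed validation populations. RMSE, MAE and MAPE are computed on
  area-year cells; MAPE averages only over cells with positive observed
  counts (no pseudo-counts), and is NaN when no such cell exists. Selection
  is by validation MAPE, ties broken toward fewer covariates.
* **Unexplained area-level variation** is summarised by the empirical
  variances across areas of the posterior-mean `phi` and `nu`; the
  structured fraction `s2_phi / (s2_phi + s2_nu)` quantifies how spatial the
  residual risk surface is, and drops when a spatially smooth covariate that
  drives the surface is added to the model.
* **Forecasts** extend the fitted temporal structure over a 10-year horizon
  against APC-derived projected offsets; state totals are aggregated per
  posterior sample so their intervals respect the joint posterior. Each
  area's trajectory is labelled from the percent change of its mean
  projected annual count against the mean of all observed years: below 0%
  decreasing, 0-5% stable, 5%+ increasing. The decreasing label is added
  for logical completeness (published summaries typically report only the
  rising and stable shares).

## The synthetic registry

Real registry data of this kind are access-restricted, so the package ships
a first-class generator that emulates exactly the structure the models
assume: an 8 x 10 rook lattice (80 areas, close to the 79 LGAs of the
motivating study), 18 observed plus 10 projection years, 5-year age bands
0-4 ... 85+, lognormal area sizes around 60k person-years growing at
1.6%/yr with the 65+ shares drifting upward (ageing), lung-cancer-like
age-specific baseline rates (crude rate ~3.7e-4, i.e. a few tens of cases
per area-year; the female variant scales rates by 0.65), an ICAR risk
surface (SD 0.15), exchangeable noise (SD 0.10), categorical area
covariates with optional spatially smooth assignment, and quadratic or RW1
temporal trends. Counts are Poisson at the age-cell level; the latent truth
(including the generative `e_it`) is stored for recovery experiments.

What the generator does *not* emulate: real geography (no shapefiles,
no irregular adjacency), migration, registry reporting lags, diagnostic-
practice shocks, or any spatio-temporal interaction. Passing tests
therefore demonstrate that the estimation machinery recovers the assumed
structure at realistic magnitudes — not that the model is adequate for any
particular real registry.

## Numerical choices and test scale

* ICAR draws use the eigen-decomposition of the graph Laplacian
  (`N(0, sd^2 L+)`), exact at fixture scale; per-component zero sums are
  enforced after the draw.
* The APC likelihood is maximised by GLM IRLS (Poisson family, power link
  on the rate scale with person-years as variance weights), with start
  values from marginal age rates and a penalized L-BFGS fallback; the
  identifiability constraints are built into the design bases, not imposed
  post hoc.
* Caches (`eta`, `exp(eta)`) are rebuilt from the state every 250 sweeps to
  stop incremental drift; a test asserts stored deviances match from-scratch
  recomputation.
* Statistical test sizes were chosen to make each check sharp but cheap:
  coverage runs use 20 replicates of the full 80-area design with 2 x 4000
  iterations; model-selection and variance-decomposition experiments use 20
  replicates of a 40-area design with 1200-1500 iterations; the
  MCMC-vs-quadrature comparison uses a 3-area path graph where a dense grid
  is tractable. The whole suite runs in under ten minutes on one CPU.

## Known limitations

* The power link makes the APC likelihood non-convex in principle; the IRLS
  path converges reliably from the rate-based start on realistic tables, but
  heavily zero-inflated Lexis tables may need the fallback optimizer.
* `gamma1` and the RW1 states of Model B are only softly separated (the walk
  can absorb a linear trend); forecasts use their sum, which is identified,
  but the individual posteriors are diffuse.
* With internally standardized offsets the shared temporal terms absorb
  almost nothing in-sample (the offsets already carry the statewide trend);
  the temporal structure matters chiefly for out-of-sample extension and
  for the DIC contrast between the quadratic and RW1 variants.
* MAPE on small counts is volatile; comparisons should lean on RMSE/MAE when
  typical counts are below ~10 per cell.
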