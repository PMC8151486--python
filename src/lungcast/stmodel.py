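"""Bayesian spatio-temporal Poisson models for small-area incidence.

Two model variants, fitted by Metropolis-within-Gibbs MCMC:

* Model A ("quadratic"):  log mu_it = log e_it + alpha + x_i'beta + phi_i
  + nu_i + gamma1*t~ + gamma2*t~^2
* Model B ("rw1"):        log mu_it = log e_it + alpha + x_i'beta + phi_i
  + nu_i + gamma1*t~ + omega_t

with Y_it ~ Poisson(mu_it).  phi carries an intrinsic CAR prior on the area
adjacency graph (sum-to-zero), nu is exchangeable normal, omega a first-order
random walk (sum-to-zero), t~ the centred year index.  Random-effect SDs get
uniform(0.01, 10) priors; fixed effects vague normal priors (SD 100).

Two further temporal modes, "linear" and "none", are diagnostic reductions
used to nest the variants and to enable low-dimensional oracle checks; they
are not part of the study's model grid.

The sampler sweeps: structured effects phi block-updated over graph colour
classes with proposals centred at the ICAR full-conditional mean;
unstructured effects, intercept, covariate and temporal coefficients by
(adaptive, burn-in only) random-walk Metropolis; SDs by Metropolis on the
log scale.  phi (and omega) are recentred to sum to zero after every sweep,
with the mean absorbed into the intercept so the likelihood is untouched.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .graph import AreaGraph
from .design import covariate_design

TEMPORAL_MODES = ("quadratic", "rw1", "linear", "none")


@dataclass
class ModelSpec:
    """Which temporal structure and which area-level covariates to include."""

    temporal: str = "quadratic"
    covariates: tuple = ()

    def __post_init__(self):
        if self.temporal not in TEMPORAL_MODES:
            raise ValueError(f"temporal must be one of {TEMPORAL_MODES}")
        self.covariates = tuple(self.covariates)
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("covariate names must be unique")


@dataclass
class Priors:
    sd_lower: float = 0.01
    sd_upper: float = 10.0
    beta_sd: float = 100.0

    def __post_init__(self):
        if not 0 < self.sd_lower < self.sd_upper:
            raise ValueError("need 0 < sd_lower < sd_upper")


@dataclass
class MCMCConfig:
    chains: int = 2
    iterations: int = 4000
    burn_in: int = 1000
    thin: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")
        if self.chains < 2:
            raise ValueError("at least two chains are required")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class STData:
    """Aligned area-year counts, expected-count offsets, graph, covariates."""

    Y: np.ndarray                 # (n_areas, n_years) observed counts
    E: np.ndarray                 # (n_areas, n_years) expected counts > 0
    graph: AreaGraph
    years: np.ndarray
    covariates: object = None     # CovariateTable or None

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.Y.shape != self.E.shape:
            raise ValueError("Y and E shapes differ")
        if self.Y.shape[0] != self.graph.n_areas:
            raise ValueError("row count does not match graph areas")
        if np.any(self.Y < 0):
            raise ValueError("negative counts")
        if np.any(self.E <= 0):
            raise ValueError("expected counts must be positive (offset error)")
        self.years = np.asarray(self.years)
        if self.years.shape[0] != self.Y.shape[1]:
            raise ValueError("years do not match columns of Y")
        # floored expected counts mark zero-population cells: drop from likelihood
        self.mask = self.E > 1e-5

    @property
    def n_areas(self) -> int:
        return self.Y.shape[0]

    @property
    def n_years(self) -> int:
        return self.Y.shape[1]

    def time_index(self) -> np.ndarray:
        """Centred year index t~."""
        t = np.arange(self.n_years, dtype=float)
        return t - t.mean()


def default_state(spec: ModelSpec, data: STData, n_cov: int) -> dict:
    return {
        "alpha": 0.0,
        "beta": np.zeros(n_cov),
        "gamma1": 0.0,
        "gamma2": 0.0,
        "phi": np.zeros(data.n_areas),
        "nu": np.zeros(data.n_areas),
        "omega": np.zeros(data.n_years),
        "sigma_phi": 1.0,
        "sigma_nu": 1.0,
        "sigma_omega": 1.0,
    }


def _time_effects(state: dict, spec: ModelSpec, tt: np.ndarray) -> np.ndarray:
    if spec.temporal == "quadratic":
        return state["gamma1"] * tt + state["gamma2"] * tt ** 2
    if spec.temporal == "rw1":
        return state["gamma1"] * tt + state["omega"]
    if spec.temporal == "linear":
        return state["gamma1"] * tt
    return np.zeros_like(tt)


def linear_predictor(state: dict, spec: ModelSpec, data: STData,
                     i: int, t: int, X: np.ndarray | None = None) -> float:
    """log mu_it for one cell under the given parameter state."""
    if not 0 <= t < data.n_years:
        raise ValueError("year index outside the modelled range")
    if data.E[i, t] <= 0:
        raise ValueError("offset error: e_it must be positive")
    if X is None:
        X, _ = covariate_design(data.covariates, spec.covariates) \
            if spec.covariates else (np.zeros((data.n_areas, 0)), [])
    xb = float(X[i] @ state["beta"]) if X.shape[1] else 0.0
    tt = data.time_index()
    return (np.log(data.E[i, t]) + state["alpha"] + xb
            + state["phi"][i] + state["nu"][i]
            + float(_time_effects(state, spec, tt)[t]))


def log_posterior(state: dict, spec: ModelSpec, priors: Priors, data: STData,
                  include_unstructured: bool = True) -> float:
    """Joint log posterior density (up to the uniform-prior constant).

    Returns -inf when any SD lies outside its uniform prior support.
    """
    for key in _active_sds(spec, include_unstructured):
        if not priors.sd_lower <= state[key] <= priors.sd_upper:
            return -np.inf
    X, _ = covariate_design(data.covariates, spec.covariates) \
        if spec.covariates else (np.zeros((data.n_areas, 0)), [])
    tt = data.time_index()
    eta = (np.log(data.E) + state["alpha"]
           + (X @ state["beta"] + state["phi"]
              + (state["nu"] if include_unstructured else 0.0))[:, None]
           + _time_effects(state, spec, tt)[None, :])
    m = data.mask
    lp = float(np.sum((data.Y * eta - np.exp(eta) - gammaln(data.Y + 1))[m]))

    # fixed-effect priors
    s0 = priors.beta_sd
    lp += -0.5 * state["alpha"] ** 2 / s0 ** 2
    lp += -0.5 * float(state["beta"] @ state["beta"]) / s0 ** 2
    if spec.temporal in ("quadratic", "rw1", "linear"):
        lp += -0.5 * state["gamma1"] ** 2 / s0 ** 2
    if spec.temporal == "quadratic":
        lp += -0.5 * state["gamma2"] ** 2 / s0 ** 2

    # ICAR kernel for phi
    lap = data.graph.laplacian()
    rank = data.graph.n_areas - len(data.graph.connected_components())
    qf = float(state["phi"] @ (lap @ state["phi"]))
    sp = state["sigma_phi"]
    lp += -rank * np.log(sp) - qf / (2 * sp ** 2)

    if include_unstructured:
        sn = state["sigma_nu"]
        lp += (-data.n_areas * np.log(sn)
               - float(state["nu"] @ state["nu"]) / (2 * sn ** 2))
    if spec.temporal == "rw1":
        so = state["sigma_omega"]
        d = np.diff(state["omega"])
        lp += -(data.n_years - 1) * np.log(so) - float(d @ d) / (2 * so ** 2)
    return lp


def _active_sds(spec: ModelSpec, include_unstructured: bool) -> list[str]:
    keys = ["sigma_phi"]
    if include_unstructured:
        keys.append("sigma_nu")
    if spec.temporal == "rw1":
        keys.append("sigma_omega")
    return keys


def icar_full_conditional(i: int, phi: np.ndarray, graph: AreaGraph,
                          sigma_phi: float) -> tuple[float, float]:
    """Mean and variance of phi_i given its neighbours under the ICAR prior."""
    nb = graph.neighbors[i]
    if nb.size == 0:
        raise ValueError(f"area {i} has no neighbours (island)")
    return float(phi[nb].mean()), sigma_phi ** 2 / nb.size


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor for one scalar parameter.

    ``chains`` is an (m, n) array of m >= 2 equal-length chains.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 equal-length chains")
    m, n = x.shape
    w = x.var(axis=1, ddof=1).mean()
    b = n * x.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0 if b <= 0 else np.inf
    v = (n - 1) / n * w + b / n
    return float(np.sqrt(v / w))


class SpatioTemporalModel(BaseEstimator):
    """MCMC-fitted Bayesian spatio-temporal Poisson model.

    Parameters mirror :class:`ModelSpec`, :class:`Priors` and
    :class:`MCMCConfig`; see the module docstring for the model equations.

    Attributes
    ----------
    samples_ : dict of str -> ndarray
        Posterior draws with leading axes (chains, n_kept).
    deviance_ : ndarray of shape (chains, n_kept)
        -2 log-likelihood per retained sample.
    rhat_ : dict of str -> float
        Gelman-Rubin statistics for the monitored scalar parameters.
    warnings_ : list of str
        Convergence warnings (R-hat > 1.1), never fatal.
    acceptance_ : dict of str -> float
        Mean post-burn-in acceptance rates per update block.
    """

    def __init__(self, temporal: str = "quadratic", covariates: tuple = (),
                 include_unstructured: bool = True,
                 sd_lower: float = 0.01, sd_upper: float = 10.0,
                 beta_sd: float = 100.0, chains: int = 2,
                 iterations: int = 4000, burn_in: int = 1000, thin: int = 2,
                 seed: int = 0, target_accept: float = 0.38):
        self.temporal = temporal
        self.covariates = covariates
        self.include_unstructured = include_unstructured
        self.sd_lower = sd_lower
        self.sd_upper = sd_upper
        self.beta_sd = beta_sd
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.target_accept = target_accept

    # -- public API --------------------------------------------------------

    def fit(self, data: STData, y=None) -> "SpatioTemporalModel":
        spec = ModelSpec(self.temporal, tuple(self.covariates))
        priors = Priors(self.sd_lower, self.sd_upper, self.beta_sd)
        mcmc = MCMCConfig(self.chains, self.iterations, self.burn_in,
                          self.thin, self.seed)
        X, labels = covariate_design(data.covariates, spec.covariates) \
            if spec.covariates else (np.zeros((data.n_areas, 0)), [])

        per_chain = []
        accs = []
        for c in range(mcmc.chains):
            rng = np.random.default_rng([mcmc.seed, 7919, c])
            out = _run_chain(data, spec, priors, mcmc, X, rng,
                             chain_index=c,
                             include_unstructured=self.include_unstructured,
                             target=self.target_accept)
            per_chain.append(out)
            accs.append(out.pop("_acceptance"))

        self.samples_ = {k: np.stack([pc[k] for pc in per_chain])
                         for k in per_chain[0] if k != "deviance"}
        self.deviance_ = np.stack([pc["deviance"] for pc in per_chain])
        self.X_ = X
        self.coef_labels_ = labels
        self.spec_ = spec
        self.priors_ = priors
        self.mcmc_ = mcmc
        self.data_ = data
        self.tt_ = data.time_index()
        self.acceptance_ = {k: float(np.mean([a[k] for a in accs]))
                            for k in accs[0]}

        self.rhat_ = {}
        monitored = {"alpha": self.samples_["alpha"],
                     "deviance": self.deviance_}
        for j, lbl in enumerate(labels):
            monitored[lbl] = self.samples_["beta"][:, :, j]
        if spec.temporal in ("quadratic", "rw1", "linear"):
            monitored["gamma1"] = self.samples_["gamma1"]
        if spec.temporal == "quadratic":
            monitored["gamma2"] = self.samples_["gamma2"]
        monitored["sigma_phi"] = self.samples_["sigma_phi"]
        if self.include_unstructured:
            monitored["sigma_nu"] = self.samples_["sigma_nu"]
        if spec.temporal == "rw1":
            monitored["sigma_omega"] = self.samples_["sigma_omega"]
        self.warnings_ = []
        for name, arr in monitored.items():
            self.rhat_[name] = gelman_rubin(arr)
            if self.rhat_[name] > 1.1:
                self.warnings_.append(
                    f"R-hat {self.rhat_[name]:.3f} > 1.1 for {name}")
        if self.warnings_:
            _warnings.warn("; ".join(self.warnings_))
        return self

    def get_samples(self, name: str) -> np.ndarray:
        """Posterior draws flattened across chains (first axis = sample)."""
        if name == "deviance":
            return self.deviance_.reshape(-1)
        arr = self.samples_[name]
        if arr.ndim == 2:
            return arr.reshape(-1)
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    def n_samples(self) -> int:
        return self.deviance_.size

    def relative_risk_terms(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample area terms (S, n) and in-sample time terms (S, T)."""
        alpha = self.get_samples("alpha")
        beta = self.get_samples("beta")
        phi = self.get_samples("phi")
        nu = self.get_samples("nu")
        area = alpha[:, None] + phi + nu
        if self.X_.shape[1]:
            area = area + beta @ self.X_.T
        tt = self.tt_
        g1 = self.get_samples("gamma1")[:, None]
        if self.spec_.temporal == "quadratic":
            time = g1 * tt + self.get_samples("gamma2")[:, None] * tt ** 2
        elif self.spec_.temporal == "rw1":
            time = g1 * tt + self.get_samples("omega")
        elif self.spec_.temporal == "linear":
            time = g1 * tt
        else:
            time = np.zeros((alpha.size, tt.size))
        return area, time

    def future_time_effects(self, horizon: int, rng=None) -> np.ndarray:
        """Per-sample temporal terms (S, horizon) for years past the data.

        Quadratic/linear trends are extrapolated analytically; the RW1 state
        is forward-simulated per posterior sample using its own sigma_omega.
        """
        if horizon < 0:
            raise ValueError("horizon must be nonnegative")
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        s = self.n_samples()
        ttf = self.tt_[-1] + np.arange(1, horizon + 1)
        g1 = self.get_samples("gamma1")[:, None]
        if self.spec_.temporal == "quadratic":
            return g1 * ttf + self.get_samples("gamma2")[:, None] * ttf ** 2
        if self.spec_.temporal == "linear":
            return g1 * ttf
        if self.spec_.temporal == "none":
            return np.zeros((s, horizon))
        omega_last = self.get_samples("omega")[:, -1]
        so = self.get_samples("sigma_omega")
        steps = so[:, None] * rng.standard_normal((s, horizon))
        omega_future = omega_last[:, None] + np.cumsum(steps, axis=1)
        return g1 * ttf + omega_future

    def eta_for(self, state: dict) -> np.ndarray:
        """(n, T) linear predictor for a single parameter state dict."""
        data = self.data_
        xb = self.X_ @ state["beta"] if self.X_.shape[1] else 0.0
        return (np.log(data.E) + state["alpha"]
                + (xb + state["phi"] + state["nu"])[:, None]
                + _time_effects(state, self.spec_, self.tt_)[None, :])

    def posterior_mean_state(self) -> dict:
        """Posterior means of all linear-predictor parameters."""
        out = {}
        for k in ("alpha", "gamma1", "gamma2"):
            out[k] = float(self.get_samples(k).mean())
        for k in ("beta", "phi", "nu", "omega"):
            out[k] = self.get_samples(k).mean(axis=0)
        for k in ("sigma_phi", "sigma_nu", "sigma_omega"):
            out[k] = float(self.get_samples(k).mean())
        return out


def sample_posterior(spec: ModelSpec, priors: Priors, data: STData,
                     mcmc: MCMCConfig, **kwargs) -> SpatioTemporalModel:
    """Fit the model by MCMC; thin wrapper over :class:`SpatioTemporalModel`."""
    est = SpatioTemporalModel(
        temporal=spec.temporal, covariates=spec.covariates,
        sd_lower=priors.sd_lower, sd_upper=priors.sd_upper,
        beta_sd=priors.beta_sd, chains=mcmc.chains,
        iterations=mcmc.iterations, burn_in=mcmc.burn_in,
        thin=mcmc.thin, seed=mcmc.seed, **kwargs)
    return est.fit(data)


def posterior_predict(fit: SpatioTemporalModel, E: np.ndarray,
                      seed=None) -> dict:
    """Posterior-predictive summaries of mu_it (and Poisson counts) for the
    fitted years under the supplied expected counts.

    Returns a dict with "mean", "lo95", "hi95" for mu and "count_lo95",
    "count_hi95" for Poisson-sampled counts, each (n_areas, n_years).
    """
    E = np.asarray(E, dtype=float)
    if E.shape != (fit.data_.n_areas, fit.data_.n_years):
        raise ValueError("expected counts must cover the fitted areas and years")
    area, time = fit.relative_risk_terms()
    mu = E[None, :, :] * np.exp(area[:, :, None] + time[:, None, :])
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mu)
    return {
        "mean": mu.mean(axis=0),
        "lo95": np.quantile(mu, 0.025, axis=0),
        "hi95": np.quantile(mu, 0.975, axis=0),
        "count_lo95": np.quantile(counts, 0.025, axis=0),
        "count_hi95": np.quantile(counts, 0.975, axis=0),
    }


# ----------------------------------------------------------------------------
# sampler internals
# ----------------------------------------------------------------------------

def _initial_state(chain_index: int, spec, priors, data, n_cov):
    st = default_state(spec, data, n_cov)
    prior_mean_sd = 0.5 * (priors.sd_lower + priors.sd_upper)
    if chain_index % 2 == 0:
        st["sigma_phi"] = st["sigma_nu"] = st["sigma_omega"] = prior_mean_sd
    else:  # dispersed start
        st["alpha"] = 1.0 if chain_index % 4 == 1 else -1.0
        st["sigma_phi"] = 0.1
        st["sigma_nu"] = 5.0
        st["sigma_omega"] = 0.1
    return st


def _run_chain(data: STData, spec: ModelSpec, priors: Priors, mcmc: MCMCConfig,
               X: np.ndarray, rng, chain_index: int,
               include_unstructured: bool, target: float) -> dict:
    n, T = data.n_areas, data.n_years
    q = X.shape[1]
    graph = data.graph
    logE = np.log(data.E)
    mask = data.mask
    Yw = np.where(mask, data.Y, 0.0)
    Yrow = Yw.sum(axis=1)
    Ycol = Yw.sum(axis=0)
    Ytot = Yw.sum()
    gl_const = float(gammaln(data.Y + 1)[mask].sum())
    tt = data.time_index()
    tt2 = tt ** 2
    s0sq = priors.beta_sd ** 2
    lo, hi = priors.sd_lower, priors.sd_upper

    W = graph.adjacency()
    deg = graph.neighbor_counts.astype(float)
    colors = graph.coloring()
    wc = [W[idx] for idx in colors]
    lap = graph.laplacian()
    comps = graph.connected_components()
    rank = n - len(comps)
    non_island = np.flatnonzero(deg > 0)
    exact_recenter = non_island.size == n   # islands break intercept absorption

    use_g1 = spec.temporal in ("quadratic", "rw1", "linear")
    use_g2 = spec.temporal == "quadratic"
    use_omega = spec.temporal == "rw1"
    use_nu = include_unstructured
    use_phi = non_island.size > 0

    st = _initial_state(chain_index, spec, priors, data, q)
    alpha = st["alpha"]
    beta = st["beta"].copy()
    g1, g2 = st["gamma1"], st["gamma2"]
    phi = st["phi"].copy()
    nu = st["nu"].copy()
    omega = st["omega"].copy()
    s_phi, s_nu, s_om = st["sigma_phi"], st["sigma_nu"], st["sigma_omega"]

    def time_eff():
        out = np.zeros(T)
        if use_g1:
            out += g1 * tt
        if use_g2:
            out += g2 * tt2
        if use_omega:
            out += omega
        return out

    def rebuild():
        eta = (logE + alpha + (X @ beta + phi + nu)[:, None]
               + time_eff()[None, :])
        return eta, np.where(mask, np.exp(eta), 0.0)

    eta, expEta = rebuild()

    # adaptive log proposal scales
    ls_nu = np.full(n, np.log(0.1))
    ls_omega = np.full(T, np.log(0.1))
    ls_scalar = {k: np.log(0.1) for k in
                 ("alpha", "gamma1", "gamma2", "sigma_phi", "sigma_nu",
                  "sigma_omega", *range(q))}
    acc_count: dict = {k: 0.0 for k in ("phi", "nu", "alpha", "beta", "gamma1",
                                        "gamma2", "omega", "sigma")}
    acc_n: dict = {k: 0 for k in acc_count}

    keep = (mcmc.iterations - mcmc.burn_in + mcmc.thin - 1) // mcmc.thin
    out = {
        "alpha": np.empty(keep), "beta": np.empty((keep, q)),
        "gamma1": np.empty(keep), "gamma2": np.empty(keep),
        "phi": np.empty((keep, n)), "nu": np.empty((keep, n)),
        "omega": np.empty((keep, T)),
        "sigma_phi": np.empty(keep), "sigma_nu": np.empty(keep),
        "sigma_omega": np.empty(keep), "deviance": np.empty(keep),
    }
    ksample = 0

    for it in range(mcmc.iterations):
        adapting = it < mcmc.burn_in
        gam = 2.0 * (it + 20) ** -0.6 if adapting else 0.0
        post = not adapting

        if it % 250 == 0:
            eta, expEta = rebuild()

        # --- structured spatial effects, one colour class at a time -------
        # Metropolis with a Gaussian proposal matching the Newton (2nd-order)
        # approximation of the exact full conditional: Poisson likelihood of
        # the area's row plus the ICAR conditional N(mean of neighbours,
        # sigma^2/n_i).  The proposal parameters depend only on data and the
        # other areas' values, so the MH correction is exact.
        if use_phi and s_phi > 0:
            for idx, w_c in zip(colors, wc):
                m = np.asarray(w_c @ phi).ravel() / deg[idx]
                v = s_phi ** 2 / deg[idx]
                a = Yrow[idx]
                b = np.maximum(expEta[idx].sum(axis=1) * np.exp(-phi[idx]), 1e-300)
                x = np.where(a > 0, np.log(np.maximum(a, 0.5)) - np.log(b), m)
                for _ in range(8):
                    ex = b * np.exp(np.clip(x, -40, 40))
                    x = x - (a - ex - (x - m) / v) / (-ex - 1.0 / v)
                ex = b * np.exp(np.clip(x, -40, 40))
                sd = 1.0 / np.sqrt(ex + 1.0 / v)
                phi_star = x + sd * rng.standard_normal(idx.size)

                def _f(p):
                    return a * p - b * np.exp(p) - 0.5 * (p - m) ** 2 / v

                la = (_f(phi_star) - _f(phi[idx])
                      - 0.5 * ((phi[idx] - x) ** 2 - (phi_star - x) ** 2) / sd ** 2)
                acc = np.log(rng.random(idx.size)) < la
                if np.any(acc):
                    sel = idx[acc]
                    dphi = phi_star[acc] - phi[sel]
                    eta[sel] += dphi[:, None]
                    expEta[sel] *= np.exp(dphi)[:, None]
                    phi[sel] = phi_star[acc]
                if post:
                    acc_count["phi"] += acc.sum()
                    acc_n["phi"] += acc.size

        # --- exact Gibbs swap between phi_i and nu_i ----------------------
        # Holding phi_i + nu_i fixed leaves the likelihood invariant; the
        # conditional of phi_i is then Gaussian, so this move is a free
        # remix of structured vs unstructured variation (helps the SDs mix).
        if use_phi and use_nu and s_phi > 0:
            for idx, w_c in zip(colors, wc):
                m = np.asarray(w_c @ phi).ravel() / deg[idx]
                v = s_phi ** 2 / deg[idx]
                tot = phi[idx] + nu[idx]
                prec = 1.0 / v + 1.0 / s_nu ** 2
                mean = (m / v + tot / s_nu ** 2) / prec
                phi[idx] = mean + rng.standard_normal(idx.size) / np.sqrt(prec)
                nu[idx] = tot - phi[idx]

        # --- unstructured effects ------------------------------------------
        if use_nu:
            rowsum = expEta.sum(axis=1)
            dnu = np.exp(ls_nu) * rng.standard_normal(n)
            dll = dnu * Yrow - rowsum * np.expm1(dnu)
            dpr = -0.5 * ((nu + dnu) ** 2 - nu ** 2) / s_nu ** 2
            acc = np.log(rng.random(n)) < dll + dpr
            if np.any(acc):
                eta[acc] += dnu[acc][:, None]
                expEta[acc] *= np.exp(dnu[acc])[:, None]
                nu[acc] += dnu[acc]
            if adapting:
                ls_nu += gam * (acc.astype(float) - target)
            if post:
                acc_count["nu"] += acc.sum()
                acc_n["nu"] += acc.size

        # --- intercept -----------------------------------------------------
        d = np.exp(ls_scalar["alpha"]) * rng.standard_normal()
        la = (d * Ytot - expEta.sum() * np.expm1(d)
              - 0.5 * ((alpha + d) ** 2 - alpha ** 2) / s0sq)
        acc = np.log(rng.random()) < la
        if acc:
            alpha += d
            eta += d
            expEta *= np.exp(d)
        if adapting:
            ls_scalar["alpha"] += gam * (float(acc) - target)
        if post:
            acc_count["alpha"] += acc
            acc_n["alpha"] += 1

        # --- covariate coefficients ----------------------------------------
        for j in range(q):
            xj = X[:, j]
            d = np.exp(ls_scalar[j]) * rng.standard_normal()
            deta = d * xj
            rowsum = expEta.sum(axis=1)
            la = (float(deta @ Yrow) - float(rowsum @ np.expm1(deta))
                  - 0.5 * ((beta[j] + d) ** 2 - beta[j] ** 2) / s0sq)
            acc = np.log(rng.random()) < la
            if acc:
                beta[j] += d
                eta += deta[:, None]
                expEta *= np.exp(deta)[:, None]
            if adapting:
                ls_scalar[j] += gam * (float(acc) - target)
            if post:
                acc_count["beta"] += acc
                acc_n["beta"] += 1

        # --- temporal coefficients ------------------------------------------
        for name, basis, active in (("gamma1", tt, use_g1), ("gamma2", tt2, use_g2)):
            if not active:
                continue
            cur = g1 if name == "gamma1" else g2
            d = np.exp(ls_scalar[name]) * rng.standard_normal()
            deta = d * basis
            colsum = expEta.sum(axis=0)
            la = (float(deta @ Ycol) - float(colsum @ np.expm1(deta))
                  - 0.5 * ((cur + d) ** 2 - cur ** 2) / s0sq)
            acc = np.log(rng.random()) < la
            if acc:
                if name == "gamma1":
                    g1 += d
                else:
                    g2 += d
                eta += deta[None, :]
                expEta *= np.exp(deta)[None, :]
            if adapting:
                ls_scalar[name] += gam * (float(acc) - target)
            if post:
                acc_count[name] += acc
                acc_n[name] += 1

        # --- random-walk temporal states ------------------------------------
        if use_omega and s_om > 0:
            for parity in (0, 1):
                tsel = np.arange(parity, T, 2)
                colsum = expEta.sum(axis=0)
                d = np.exp(ls_omega[tsel]) * rng.standard_normal(tsel.size)
                dll = d * Ycol[tsel] - colsum[tsel] * np.expm1(d)
                dpr = np.zeros(tsel.size)
                for k_, t_ in enumerate(tsel):
                    for s_ in (t_ - 1, t_ + 1):
                        if 0 <= s_ < T:
                            dpr[k_] += ((omega[t_] - omega[s_]) ** 2
                                        - (omega[t_] + d[k_] - omega[s_]) ** 2)
                dpr /= 2 * s_om ** 2
                acc = np.log(rng.random(tsel.size)) < dll + dpr
                if np.any(acc):
                    sel = tsel[acc]
                    eta[:, sel] += d[acc][None, :]
                    expEta[:, sel] *= np.exp(d[acc])[None, :]
                    omega[sel] += d[acc]
                if adapting:
                    ls_omega[tsel] += gam * (acc.astype(float) - target)
                if post:
                    acc_count["omega"] += acc.sum()
                    acc_n["omega"] += acc.size

        # --- likelihood-invariant Gibbs translations -------------------------
        # Shifting (alpha, nu), (beta_j, nu over its areas) or (gamma1, omega)
        # along a direction that leaves every eta_it unchanged has a Gaussian
        # conditional determined purely by the priors; sampling it exactly
        # breaks the fixed-effect / random-field confounding.
        if use_nu:
            prec = n / s_nu ** 2 + 1.0 / s0sq
            mean = (nu.sum() / s_nu ** 2 - alpha / s0sq) / prec
            dlt = mean + rng.standard_normal() / np.sqrt(prec)
            alpha += dlt
            nu -= dlt
            for j in range(q):
                xj = X[:, j]
                prec = float(xj @ xj) / s_nu ** 2 + 1.0 / s0sq
                mean = (float(xj @ nu) / s_nu ** 2 - beta[j] / s0sq) / prec
                dlt = mean + rng.standard_normal() / np.sqrt(prec)
                beta[j] += dlt
                nu -= dlt * xj
        if use_omega and use_g1:
            dom = np.diff(omega)
            prec = (T - 1) / s_om ** 2 + 1.0 / s0sq
            mean = (dom.sum() / s_om ** 2 - g1 / s0sq) / prec
            dlt = mean + rng.standard_normal() / np.sqrt(prec)
            g1 += dlt
            omega -= dlt * tt

        # --- random-effect SDs (log-scale Metropolis) ------------------------
        if use_phi:
            qf = float(phi @ (lap @ phi))
            s_phi = _update_sd(s_phi, qf, rank, lo, hi, ls_scalar, "sigma_phi",
                               rng, gam, target, acc_count, acc_n, post)
        if use_nu:
            s_nu = _update_sd(s_nu, float(nu @ nu), n, lo, hi, ls_scalar,
                              "sigma_nu", rng, gam, target, acc_count, acc_n, post)
        if use_omega:
            dif = np.diff(omega)
            s_om = _update_sd(s_om, float(dif @ dif), T - 1, lo, hi, ls_scalar,
                              "sigma_omega", rng, gam, target, acc_count, acc_n, post)

        # --- recentre sum-to-zero effects ------------------------------------
        if use_phi:
            if exact_recenter:
                m_ = phi.mean()
                phi -= m_
                alpha += m_
            else:
                for comp in comps:
                    if comp.size > 1:
                        phi[comp] -= phi[comp].mean()
                eta, expEta = rebuild()
        if use_omega:
            m_ = omega.mean()
            omega -= m_
            alpha += m_

        # --- record ----------------------------------------------------------
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            ll = float((Yw * eta)[mask].sum() - expEta.sum()) - gl_const
            out["alpha"][ksample] = alpha
            out["beta"][ksample] = beta
            out["gamma1"][ksample] = g1
            out["gamma2"][ksample] = g2
            out["phi"][ksample] = phi
            out["nu"][ksample] = nu
            out["omega"][ksample] = omega
            out["sigma_phi"][ksample] = s_phi
            out["sigma_nu"][ksample] = s_nu
            out["sigma_omega"][ksample] = s_om
            out["deviance"][ksample] = -2.0 * ll
            ksample += 1

    out["_acceptance"] = {k: (acc_count[k] / acc_n[k]) if acc_n[k] else np.nan
                          for k in acc_count}
    return out


def _update_sd(s, qf, dof, lo, hi, ls_scalar, key, rng, gam, target,
               acc_count, acc_n, post):
    d = np.exp(ls_scalar[key]) * rng.standard_normal()
    s_star = s * np.exp(d)
    acc = False
    if lo <= s_star <= hi:
        la = ((-dof * np.log(s_star) - qf / (2 * s_star ** 2))
              - (-dof * np.log(s) - qf / (2 * s ** 2))
              + np.log(s_star) - np.log(s))   # Jacobian of the log-scale walk
        acc = np.log(rng.random()) < la
        if acc:
            s = s_star
    if gam:
        ls_scalar[key] += gam * (float(acc) - target)
    if post:
        acc_count["sigma"] += acc
        acc_n["sigma"] += 1
    return s
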