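"""Power-link Age-Period-Cohort modelling and rate projection.

Statewide incidence is decomposed into age effects, a linear drift, and
detrended period and cohort residuals.  The Poisson rate for age ``a`` and
period ``p`` (cohort ``c = p - a``) is modelled on a power scale,

    rate_{a,p} = (A_a + d*p~ + P_p + C_c)^k,      counts ~ Poisson(n * rate)

with ``k = 5`` by default (the power-5 convention of cancer-projection
practice) and person-years ``n`` as multiplicative exposure.  ``P`` and
``C`` are constrained to zero sum and zero slope by construction: they enter
through bases orthogonal to the constant and linear contrasts, so the drift
``d`` carries the only identifiable time slope.

Projection extends the drift into the horizon with an optional "cut-trend"
attenuation (75%/50%/25% of the drift increment over successive thirds of
the horizon) and carries the last estimated cohort effect forward for
cohorts never observed in-sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator


class ConvergenceError(RuntimeError):
    pass


@dataclass
class APCData:
    """Statewide Lexis table: counts and person-years by age x period."""

    counts: np.ndarray        # (n_ages, n_periods)
    person_years: np.ndarray  # (n_ages, n_periods)
    ages: tuple
    periods: np.ndarray       # calendar years

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        if self.counts.shape != self.person_years.shape:
            raise ValueError("counts and person-years shapes differ")
        if self.counts.shape != (len(self.ages), len(self.periods)):
            raise ValueError("Lexis table shape does not match labels")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        self.periods = np.asarray(self.periods)

    @property
    def n_ages(self) -> int:
        return self.counts.shape[0]

    @property
    def n_periods(self) -> int:
        return self.counts.shape[1]

    @property
    def n_cohorts(self) -> int:
        return self.n_ages + self.n_periods - 1

    def cohort_index(self) -> np.ndarray:
        """(n_ages, n_periods) integer cohort index c = p - a, shifted to 0-based."""
        a = np.arange(self.n_ages)[:, None]
        p = np.arange(self.n_periods)[None, :]
        return (self.n_ages - 1) - a + p


def build_lexis(counts, pops=None) -> APCData:
    """Aggregate an (area, year, age) panel to a statewide Lexis table.

    Accepts a :class:`~lungcast.synthetic.SimulatedRegistry` or a raw counts
    array together with its :class:`~lungcast.synthetic.PopulationPanel`.
    """
    if pops is None:  # registry-like object
        registry = counts
        counts_arr, pops = registry.counts, registry.pops
    else:
        counts_arr = counts
    counts_arr = np.asarray(counts_arr, dtype=float)
    if counts_arr.shape != pops.person_years.shape:
        raise ValueError("ragged panel: counts and populations do not align")
    d = counts_arr.sum(axis=0).T            # (n_ages, n_years)
    n = pops.person_years.sum(axis=0).T
    if np.any((n <= 0) & (d > 0)):
        raise ValueError("counts observed in a cell with zero person-years")
    return APCData(counts=d, person_years=n, ages=tuple(pops.age_groups),
                   periods=np.asarray(pops.years))


@dataclass
class APCProjection:
    """Projected age-specific rates; row 0 is the last in-sample period."""

    years: np.ndarray
    rates: np.ndarray         # (horizon + 1, n_ages)
    attenuation: str


def _detrended_basis(levels: int) -> np.ndarray:
    """Orthonormal basis of R^levels orthogonal to the constant and linear
    contrasts; empty for fewer than 3 levels."""
    if levels < 3:
        return np.zeros((levels, 0))
    x = np.arange(levels, dtype=float)
    x0 = np.column_stack([np.ones(levels), x - x.mean()])
    q0, _ = np.linalg.qr(x0)
    resid = np.eye(levels) - q0 @ q0.T
    u, s, _ = np.linalg.svd(resid)
    return u[:, s > 1e-8]


class APCModel(BaseEstimator):
    """Poisson Age-Period-Cohort model with a power link.

    Parameters
    ----------
    power : float, default 5.0
        Link power k; rates are modelled as (linear predictor)^k.
    attenuation : {"cut-trend", "none"}, default "cut-trend"
        Default drift-damping schedule used by :meth:`predict_rates`.
    max_iter : int
        Iteration cap for the IRLS fit (and the quasi-Newton fallback).

    Attributes
    ----------
    age_effects_ : ndarray of shape (n_ages,)
        Age effects A_a on the power scale.
    drift_ : float
        Common linear time slope per period on the power scale.
    period_ : ndarray of shape (n_periods,)
        Detrended period residuals (zero sum, zero slope).
    cohort_ : ndarray of shape (n_cohorts,)
        Detrended cohort residuals (zero sum, zero slope).
    deviance_ : float
        Poisson deviance of the fit on the count scale.
    converged_ : bool
    fitted_rates_ : ndarray of shape (n_ages, n_periods)
    """

    def __init__(self, power: float = 5.0, attenuation: str = "cut-trend",
                 max_iter: int = 200):
        self.power = power
        self.attenuation = attenuation
        self.max_iter = max_iter

    # -- fitting -----------------------------------------------------------

    def _design(self, data: APCData):
        a_idx = np.repeat(np.arange(data.n_ages), data.n_periods)
        p_idx = np.tile(np.arange(data.n_periods), data.n_ages)
        c_idx = data.cohort_index().ravel()
        p_tilde = p_idx - (data.n_periods - 1) / 2.0
        zp = _detrended_basis(data.n_periods)
        zc = _detrended_basis(data.n_cohorts)
        x = np.hstack([
            np.eye(data.n_ages)[a_idx],
            p_tilde[:, None],
            zp[p_idx],
            zc[c_idx],
        ])
        return x, zp, zc

    def fit(self, data: APCData, y=None) -> "APCModel":
        if data.n_ages < 3 or data.n_periods < 3:
            raise ValueError("APC fit needs at least 3 ages and 3 periods")
        if np.any(data.person_years <= 0):
            raise ValueError("zero person-years cell in Lexis table")
        k = float(self.power)
        x, zp, zc = self._design(data)
        d_flat = data.counts.ravel()
        n_flat = data.person_years.ravel()
        rate0 = np.maximum(data.counts.sum(1) / data.person_years.sum(1), 1e-12)
        beta0 = np.concatenate([rate0 ** (1.0 / k),
                                np.zeros(1 + zp.shape[1] + zc.shape[1])])

        beta, converged = self._fit_irls(x, d_flat, n_flat, beta0, k)
        if beta is None:
            beta, converged = self._fit_quasi_newton(x, d_flat, n_flat, beta0, k)
        if beta is None:
            raise ConvergenceError("APC fit failed to converge")

        na = data.n_ages
        self.age_effects_ = beta[:na]
        self.drift_ = float(beta[na])
        self.period_ = zp @ beta[na + 1: na + 1 + zp.shape[1]]
        self.cohort_ = zc @ beta[na + 1 + zp.shape[1]:]
        eta = (x @ beta).reshape(data.n_ages, data.n_periods)
        self.fitted_rates_ = np.maximum(eta, 0.0) ** k
        mu = data.person_years * self.fitted_rates_
        self.deviance_ = float(_poisson_deviance(data.counts, mu))
        self.converged_ = bool(converged)
        self.data_ = data
        return self

    def _fit_irls(self, x, d, n, beta0, k):
        """Primary path: GLM IRLS via statsmodels on the rate scale."""
        try:
            import warnings

            import statsmodels.api as sm
            fam = sm.families.Poisson(link=sm.families.links.Power(power=1.0 / k),
                                      check_link=False)
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(d / n, x, family=fam, var_weights=n).fit(
                    start_params=beta0, maxiter=self.max_iter)
            beta = np.asarray(res.params)
            if not np.all(np.isfinite(beta)):
                return None, False
            eta = x @ beta
            if np.any(eta <= 0):
                return None, False
            return beta, bool(getattr(res, "converged", True))
        except Exception:
            return None, False

    def _fit_quasi_newton(self, x, d, n, beta0, k):
        """Fallback: penalized Poisson likelihood maximised by L-BFGS."""
        eps = 1e-10

        def negloglik(beta):
            eta = x @ beta
            pen = 1e6 * np.sum(np.minimum(eta, 0.0) ** 2)
            eta_c = np.maximum(eta, eps)
            mu = n * eta_c ** k
            ll = np.sum(d * np.log(mu) - mu)
            g_eta = (d / np.maximum(mu, 1e-300) - 1.0) * n * k * eta_c ** (k - 1)
            g_eta = np.where(eta > 0, g_eta, 2e6 * np.minimum(eta, 0.0))
            grad = -(x.T @ g_eta)
            return -(ll) + pen, grad

        res = optimize.minimize(negloglik, beta0, jac=True, method="L-BFGS-B",
                                options={"maxiter": 50 * self.max_iter})
        if not np.all(np.isfinite(res.x)):
            return None, False
        return res.x, bool(res.success)

    # -- projection --------------------------------------------------------

    def predict_rates(self, horizon: int, attenuation: str | None = None) -> APCProjection:
        """Age-specific rates for the last in-sample period plus ``horizon`` years."""
        if horizon < 0:
            raise ValueError("horizon must be nonnegative")
        if not hasattr(self, "age_effects_"):
            raise RuntimeError("model is not fitted")
        att = self.attenuation if attenuation is None else attenuation
        data = self.data_
        k = float(self.power)
        np_, na = data.n_periods, data.n_ages
        p_tilde_last = (np_ - 1) / 2.0
        factors = _attenuation_factors(att, horizon)
        drift_path = np.concatenate([[0.0], np.cumsum(factors) * self.drift_])

        c_last = data.n_cohorts - 1
        rates = np.empty((horizon + 1, na))
        for j in range(horizon + 1):
            c_idx = np.minimum((na - 1) - np.arange(na) + (np_ - 1) + j, c_last)
            eta = (self.age_effects_ + self.drift_ * p_tilde_last + drift_path[j]
                   + self.period_[-1] + self.cohort_[c_idx])
            rates[j] = np.maximum(eta, 0.0) ** k
        years = data.periods[-1] + np.arange(horizon + 1)
        return APCProjection(years=years, rates=rates, attenuation=att)


def _attenuation_factors(att: str, horizon: int) -> np.ndarray:
    if att == "none":
        return np.ones(horizon)
    if att == "cut-trend":
        j = np.arange(1, horizon + 1)
        t1 = int(np.ceil(horizon / 3))
        t2 = int(np.ceil(2 * horizon / 3))
        return np.where(j <= t1, 0.75, np.where(j <= t2, 0.5, 0.25))
    raise ValueError(f"unknown attenuation schedule {att!r}")


def _poisson_deviance(d, mu):
    mu = np.maximum(mu, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(d > 0, d * np.log(np.maximum(d, 1e-300) / mu), 0.0)
    return 2.0 * np.sum(term - (d - mu))


def fit_apc(data: APCData, power: float = 5.0, **kwargs) -> APCModel:
    """Fit a power-link APC model; thin wrapper over :class:`APCModel`."""
    return APCModel(power=power, **kwargs).fit(data)


def project_age_specific_rates(fit: APCModel, horizon: int,
                               attenuation: str | None = None) -> APCProjection:
    """Project age-specific rates ``horizon`` years past the data."""
    return fit.predict_rates(horizon, attenuation=attenuation)
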