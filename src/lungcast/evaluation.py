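"""Model comparison and validation.

DIC with the plug-in deviance at the posterior mean of the linear-predictor
parameters (the classic BUGS construction), forecast-error metrics
(RMSE/MAE/MAPE) on a train/validation year split, the structured share of
unexplained area-level variation, and Pearson standardized residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .apc import APCModel, build_lexis
from .standardize import (age_specific_rates, expected_counts_observed,
                          expected_counts_projected)
from .stmodel import (MCMCConfig, ModelSpec, Priors, STData,
                      SpatioTemporalModel, sample_posterior)
from .synthetic import PopulationPanel


@dataclass
class ErrorReport:
    rmse: float
    mae: float
    mape: float
    n_used: int
    n_excluded: int


@dataclass
class VarianceDecomposition:
    s2_phi: float
    s2_nu: float
    fraction_structured: float


def dic(fit: SpatioTemporalModel) -> dict:
    """Deviance information criterion: Dbar + pD, pD = Dbar - D(theta_bar)."""
    if not hasattr(fit, "deviance_") or fit.deviance_.size == 0:
        raise ValueError("fit carries no posterior samples")
    dbar = float(fit.deviance_.mean())
    eta = fit.eta_for(fit.posterior_mean_state())
    data = fit.data_
    m = data.mask
    ll = float((data.Y * eta - np.exp(eta) - gammaln(data.Y + 1))[m].sum())
    d_at_mean = -2.0 * ll
    pd_ = dbar - d_at_mean
    return {"Dbar": dbar, "D_at_mean": d_at_mean, "pD": pd_, "DIC": dbar + pd_}


def forecast_errors(observed, predicted) -> ErrorReport:
    """RMSE, MAE and MAPE; MAPE averages only over cells with observed > 0."""
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size != p.size or o.size == 0:
        raise ValueError("observed and predicted must align and be nonempty")
    err = o - p
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    pos = o > 0
    if pos.any():
        mape = float(100.0 * np.mean(np.abs(err[pos]) / o[pos]))
    else:
        mape = np.nan  # undefined: every observed count is zero
    return ErrorReport(rmse=rmse, mae=mae, mape=mape,
                       n_used=int(pos.sum()), n_excluded=int((~pos).sum()))


def spatial_fraction(fit: SpatioTemporalModel) -> VarianceDecomposition:
    """Share of area-level variation carried by the structured (CAR) effect.

    Empirical variances across areas of the posterior-mean phi and nu; the
    structured fraction s2_phi / (s2_phi + s2_nu) is the usual summary of
    how much unexplained area-level variation is spatial.
    """
    phi = fit.get_samples("phi").mean(axis=0)
    nu = fit.get_samples("nu").mean(axis=0)
    if phi.size < 2:
        raise ValueError("variance decomposition needs at least 2 areas")
    s2p = float(np.var(phi))
    s2n = float(np.var(nu))
    frac = s2p / (s2p + s2n) if (s2p + s2n) > 0 else np.nan
    return VarianceDecomposition(s2_phi=s2p, s2_nu=s2n, fraction_structured=frac)


def standardized_residuals(observed, predicted_mean,
                           threshold: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Pearson residuals (o - p)/sqrt(p) with outlier flags at |r| > 2."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted_mean, dtype=float)
    if np.any(p <= 0):
        raise ValueError("predicted means must be positive")
    r = (o - p) / np.sqrt(p)
    return r, np.abs(r) > threshold


def _spec_label(spec: ModelSpec) -> str:
    base = {"quadratic": "Model A", "rw1": "Model B"}.get(spec.temporal,
                                                          spec.temporal)
    if spec.covariates:
        return base + " + " + " + ".join(spec.covariates)
    return base


def train_validate(registry, specs, split_year: int,
                   mcmc: MCMCConfig | None = None,
                   priors: Priors | None = None,
                   apc_power: float = 5.0,
                   attenuation: str = "cut-trend",
                   seed: int | None = None) -> dict:
    """Fit each candidate spec on years <= split_year, score later years.

    The expected-count offset follows the study's two-step design: internal
    standardization on the training years; APC rates fitted to the training
    Lexis table and projected over the validation horizon, applied to the
    observed validation populations.  The winner is the spec with lowest
    validation MAPE (ties broken toward fewer covariates).

    Returns a dict with the comparison ``table`` (a DataFrame), the
    ``selected`` ModelSpec, its index, and the fitted models.
    """
    specs = [s if isinstance(s, ModelSpec) else ModelSpec(**s) for s in specs]
    if not specs:
        raise ValueError("empty model grid")
    years = np.asarray(registry.years)
    if split_year < years[0] + 2 or split_year >= years[-1]:
        raise ValueError("split year must leave >=3 training and >=1 validation years")
    mcmc = mcmc or MCMCConfig()
    priors = priors or Priors()
    tmask = years <= split_year
    vmask = ~tmask

    pops = registry.pops
    train_pops = PopulationPanel(pops.areas, years[tmask], pops.age_groups,
                                 pops.person_years[:, tmask], pops.age_edges)
    val_pops = PopulationPanel(pops.areas, years[vmask], pops.age_groups,
                               pops.person_years[:, vmask], pops.age_edges)
    y_train = registry.counts_total[:, tmask]
    y_val = registry.counts_total[:, vmask]

    rates = age_specific_rates(registry.counts[:, tmask], train_pops.person_years)
    e_train = expected_counts_observed(train_pops, rates)

    apc = APCModel(power=apc_power, attenuation=attenuation).fit(
        build_lexis(registry.counts[:, tmask], train_pops))
    h = int(vmask.sum())
    proj = apc.predict_rates(h)
    e_val = expected_counts_projected(val_pops, proj.rates[1:])

    rows, fits = [], []
    rng = np.random.default_rng(seed if seed is not None else mcmc.seed)
    for spec in specs:
        fit = sample_posterior(spec, priors,
                               STData(y_train, e_train, registry.graph,
                                      years[tmask], registry.covs),
                               mcmc)
        area, time = fit.relative_risk_terms()
        mu_train = (e_train[None] * np.exp(area[:, :, None] + time[:, None, :])
                    ).mean(axis=0)
        time_f = fit.future_time_effects(h, rng)
        mu_val = (e_val[None] * np.exp(area[:, :, None] + time_f[:, None, :])
                  ).mean(axis=0)
        tr = forecast_errors(y_train, mu_train)
        va = forecast_errors(y_val, mu_val)
        rows.append({
            "model": _spec_label(spec), "n_covariates": len(spec.covariates),
            "train_rmse": tr.rmse, "train_mae": tr.mae, "train_mape": tr.mape,
            "dic": dic(fit)["DIC"],
            "val_rmse": va.rmse, "val_mae": va.mae, "val_mape": va.mape,
        })
        fits.append(fit)

    table = pd.DataFrame(rows)
    order = np.lexsort((table["n_covariates"].to_numpy(),
                        table["val_mape"].to_numpy()))
    best = int(order[0])
    return {"table": table, "selected": specs[best], "selected_index": best,
            "fits": fits, "apc": apc}
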