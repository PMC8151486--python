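"""Out-of-sample forecasting, percent-change summaries, trend classification.

Forecasts extend the fitted spatio-temporal structure over a projection
horizon: the quadratic trend analytically, the RW1 state by forward
simulation per posterior sample.  Expected counts for the horizon come from
APC-projected age-specific rates applied to projected populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stmodel import SpatioTemporalModel


@dataclass
class ForecastTable:
    """Per-area and state-level predictive summaries over the horizon."""

    area_frame: pd.DataFrame    # area, year, mean, lo95, hi95, count_lo95, count_hi95
    state_frame: pd.DataFrame   # year, mean, lo95, hi95

    def area_means(self) -> pd.DataFrame:
        return self.area_frame.pivot(index="area", columns="year", values="mean")


@dataclass
class TrendLabel:
    label: str                  # increasing | stable | decreasing
    percent_change: float


def forecast(fit: SpatioTemporalModel, e_proj: np.ndarray, horizon_years,
             seed=None) -> ForecastTable:
    """Posterior-predictive forecast of area counts over the horizon.

    ``e_proj`` is the (n_areas, horizon) expected-count offset for the
    projection years; ``horizon_years`` labels its columns.  State totals are
    aggregated per posterior sample, so their intervals respect the joint
    posterior.
    """
    horizon_years = np.asarray(horizon_years)
    e_proj = np.asarray(e_proj, dtype=float)
    h = horizon_years.size
    if h == 0:
        empty = pd.DataFrame(columns=["area", "year", "mean", "lo95", "hi95",
                                      "count_lo95", "count_hi95"])
        return ForecastTable(area_frame=empty,
                             state_frame=pd.DataFrame(columns=["year", "mean",
                                                               "lo95", "hi95"]))
    if e_proj.shape != (fit.data_.n_areas, h):
        raise ValueError("projected expected counts must cover every horizon year")
    if np.any(e_proj <= 0):
        raise ValueError("projected expected counts must be positive")

    rng = np.random.default_rng(seed)
    area, _ = fit.relative_risk_terms()
    time_f = fit.future_time_effects(h, rng)
    mu = e_proj[None, :, :] * np.exp(area[:, :, None] + time_f[:, None, :])
    counts = rng.poisson(mu)

    areas = fit.data_.graph.area_ids
    rows = pd.DataFrame({
        "area": np.repeat(areas, h),
        "year": np.tile(horizon_years, len(areas)),
        "mean": mu.mean(axis=0).ravel(),
        "lo95": np.quantile(mu, 0.025, axis=0).ravel(),
        "hi95": np.quantile(mu, 0.975, axis=0).ravel(),
        "count_lo95": np.quantile(counts, 0.025, axis=0).ravel(),
        "count_hi95": np.quantile(counts, 0.975, axis=0).ravel(),
    })
    totals = mu.sum(axis=1)   # (S, h)
    state = pd.DataFrame({
        "year": horizon_years,
        "mean": totals.mean(axis=0),
        "lo95": np.quantile(totals, 0.025, axis=0),
        "hi95": np.quantile(totals, 0.975, axis=0),
    })
    return ForecastTable(area_frame=rows, state_frame=state)


def percent_change(baseline: float, value: float) -> float:
    """100 * (value - baseline) / baseline, to 2 decimals."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (value - baseline) / baseline, 2)


def classify_trend(history, projection) -> TrendLabel:
    """Label an area's trajectory from observed history to projected means.

    The change is the percent difference between the mean projected and mean
    historical annual count; below 5% counts as stable (the study's rule),
    negative as decreasing, 5% or more as increasing.
    """
    hist = np.asarray(history, dtype=float)
    proj = np.asarray(projection, dtype=float)
    if hist.size == 0 or proj.size == 0:
        raise ValueError("history and projection must be nonempty")
    base = hist.mean()
    if base <= 0:
        raise ValueError("unclassifiable: historical mean count is zero")
    c = percent_change(base, proj.mean())
    if c >= 5.0:
        label = "increasing"
    elif c >= 0.0:
        label = "stable"
    else:
        label = "decreasing"
    return TrendLabel(label=label, percent_change=c)


def trend_summary(labels) -> dict:
    """Percentage of areas per trend label, to 2 decimals."""
    labels = [lb.label if isinstance(lb, TrendLabel) else str(lb) for lb in labels]
    if not labels:
        raise ValueError("no areas to summarise")
    n = len(labels)
    return {k: round(100.0 * labels.count(k) / n, 2)
            for k in ("increasing", "stable", "decreasing")}
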