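"""Synthetic cancer-registry generator.

Emulates a multi-area cancer registry with the exact statistical structure
the downstream models assume: age-structured growing populations, a smooth
spatial risk surface (intrinsic CAR), exchangeable unstructured area effects,
area-level categorical covariates, and quadratic or random-walk temporal
trends driving Poisson counts.  The defaults are calibrated to a Victorian
lung-cancer-like scale: ~80 areas, ~60k person-years per area, and a few tens
of incident cases per area-year.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import effects_vector
from .graph import AreaGraph, write_edge_list

__all__ = [
    "SimulationConfig", "PopulationPanel", "CovariateTable", "SimulatedRegistry",
    "sample_icar", "simulate_population", "sample_covariates", "simulate_registry",
    "default_age_groups", "write_registry",
]

POLLUTION_LEVELS = ("high", "medium", "low", "none")
REMOTENESS_LEVELS = ("metro", "regional")

# 5-year bands 0-4 ... 85+ (18 bands).
_N_AGE = 18

# Baseline age-specific incidence per person-year, rising steeply with age
# (lung-cancer-like); crude rate ~3.7e-4, i.e. ~22 cases per 60k person-years.
_MALE_RATES = np.array([
    1e-6, 1e-6, 1e-6, 1e-6, 2e-6, 4e-6, 8e-6, 1.5e-5, 3e-5, 7e-5,
    1.6e-4, 3.5e-4, 7e-4, 1.2e-3, 1.9e-3, 2.7e-3, 3.4e-3, 3.8e-3,
])
_FEMALE_FACTOR = 0.65

# Age composition of the synthetic population (normalised in __post_init__).
_AGE_SHARES = np.array([
    .062, .063, .064, .065, .066, .069, .072, .071, .069, .067,
    .064, .059, .053, .045, .035, .027, .018, .012,
])


def default_age_groups() -> list[str]:
    """Labels for the default 5-year age bands 0-4 ... 85+."""
    labels = [f"{5 * a}-{5 * a + 4}" for a in range(_N_AGE - 1)]
    return labels + ["85+"]


def default_baseline_rates(sex: str = "male") -> np.ndarray:
    if sex == "male":
        return _MALE_RATES.copy()
    if sex == "female":
        return _MALE_RATES * _FEMALE_FACTOR
    raise ValueError(f"unknown sex {sex!r}")


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    The linear predictor for the area-year log relative risk is
    ``alpha + x_i'beta + phi_i + nu_i + time_t`` with ``time_t`` either a
    centred quadratic (``gamma1*t + gamma2*t^2``) or a first-order random
    walk with innovation SD ``sigma_omega``.  Age-specific counts are
    Poisson with mean ``person_years * baseline_rate_a * exp(predictor)``.
    """

    alpha: float = 0.0
    covariate_effects: dict = field(default_factory=dict)
    sigma_phi: float = 0.15
    sigma_nu: float = 0.10
    sigma_omega: float = 0.05
    temporal: str = "quadratic"          # "quadratic" | "rw1"
    gamma1: float = 0.012
    gamma2: float = 0.0
    baseline_rates: np.ndarray = field(default_factory=lambda: _MALE_RATES.copy())
    age_shares: np.ndarray = field(default_factory=lambda: _AGE_SHARES.copy())
    base_person_years: float = 60_000.0
    area_size_sd: float = 0.5            # lognormal spread of area sizes
    growth_rate: float = 0.016           # annual population growth
    ageing_rate: float = 0.012           # annual relative growth of 65+ shares
    start_year: int = 2001
    sex: str = "male"
    seed: int = 0

    def __post_init__(self):
        self.baseline_rates = np.asarray(self.baseline_rates, dtype=float)
        self.age_shares = np.asarray(self.age_shares, dtype=float)
        if np.any(self.baseline_rates <= 0):
            raise ValueError("baseline rates must be positive")
        if self.baseline_rates.shape != self.age_shares.shape:
            raise ValueError("baseline_rates and age_shares must align")
        for name in ("sigma_phi", "sigma_nu", "sigma_omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.temporal not in ("quadratic", "rw1"):
            raise ValueError("temporal mode must be 'quadratic' or 'rw1'")
        self.age_shares = self.age_shares / self.age_shares.sum()

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_rates"] = list(map(float, self.baseline_rates))
        d["age_shares"] = list(map(float, self.age_shares))
        return d


@dataclass
class PopulationPanel:
    """Person-years at risk by (area, year, age group)."""

    areas: tuple
    years: np.ndarray
    age_groups: tuple
    person_years: np.ndarray  # (n_areas, n_years, n_ages)
    age_edges: np.ndarray = field(default_factory=lambda: np.arange(0, 90, 5))

    def __post_init__(self):
        self.person_years = np.asarray(self.person_years, dtype=float)
        if self.person_years.shape != (len(self.areas), len(self.years), len(self.age_groups)):
            raise ValueError("person_years shape does not match index sets")
        if np.any(self.person_years < 0):
            raise ValueError("person-years must be nonnegative")
        years = np.asarray(self.years)
        if years.size > 1 and np.any(np.diff(years) != 1):
            raise ValueError("years must be contiguous")
        self.years = years

    def elderly_proportion(self, min_age: int = 65) -> np.ndarray:
        """Share of person-years at or above ``min_age``, per (area, year)."""
        old = self.age_edges >= min_age
        tot = self.person_years.sum(axis=2)
        return self.person_years[:, :, old].sum(axis=2) / np.where(tot > 0, tot, np.nan)

    def to_frame(self, sex: str = "all") -> pd.DataFrame:
        return _array_to_long(self.person_years, self.areas, self.years,
                              self.age_groups, sex)


@dataclass
class CovariateTable:
    """Area-level categorical risk-factor covariates."""

    areas: tuple
    smoking_q: np.ndarray
    elderly_q: np.ndarray
    irsd_q: np.ndarray
    pollution: np.ndarray
    remoteness: np.ndarray

    def __post_init__(self):
        n = len(self.areas)
        for name in ("smoking_q", "elderly_q", "irsd_q"):
            v = np.asarray(getattr(self, name), dtype=int)
            if v.shape != (n,) or v.min() < 1 or v.max() > 4:
                raise ValueError(f"{name} must be quartiles 1..4 for every area")
            setattr(self, name, v)
        self.pollution = np.asarray(self.pollution, dtype=object)
        self.remoteness = np.asarray(self.remoteness, dtype=object)
        if not set(self.pollution) <= set(POLLUTION_LEVELS):
            raise ValueError("pollution categories must be high/medium/low/none")
        if not set(self.remoteness) <= set(REMOTENESS_LEVELS):
            raise ValueError("remoteness must be metro/regional")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "area": self.areas, "smoking_q": self.smoking_q,
            "elderly_q": self.elderly_q, "irsd_q": self.irsd_q,
            "pollution": self.pollution, "remoteness": self.remoteness,
        })


@dataclass
class SimulatedRegistry:
    """Poisson counts plus the latent truth used to generate them."""

    graph: AreaGraph
    pops: PopulationPanel
    covs: CovariateTable
    config: SimulationConfig
    counts: np.ndarray            # (n_areas, n_years, n_ages) integers
    latent: dict                  # phi, nu, time_effects, theta, e, ...

    @property
    def counts_total(self) -> np.ndarray:
        """Counts aggregated over age: the Y_it of the spatio-temporal model."""
        return self.counts.sum(axis=2)

    @property
    def years(self) -> np.ndarray:
        return self.pops.years

    def to_frame(self) -> pd.DataFrame:
        return _array_to_long(self.counts, self.graph.area_ids, self.pops.years,
                              self.pops.age_groups, self.config.sex)


def _array_to_long(values, areas, years, age_groups, sex) -> pd.DataFrame:
    n, t, a = np.asarray(values).shape
    idx = pd.MultiIndex.from_product([areas, years, age_groups],
                                     names=["area", "year", "age_group"])
    df = pd.DataFrame({"value": np.asarray(values).reshape(-1)}, index=idx).reset_index()
    df.insert(3, "sex", sex)
    return df


def sample_icar(graph: AreaGraph, sd: float, seed=None) -> np.ndarray:
    """One draw of the intrinsic CAR field, sum-to-zero within each component.

    The ICAR kernel is exp(-phi' L phi / (2 sd^2)) with L the graph
    Laplacian; the draw is N(0, sd^2 L+) via eigen-decomposition of L, which
    is exact at fixture scale and automatically places islands at zero.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    n = graph.n_areas
    if sd == 0:
        return np.zeros(n)
    if not any(len(c) >= 2 for c in graph.connected_components()):
        raise GraphStructureError("no connected component of size >= 2 to sample from")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lap = graph.laplacian().toarray()
    w, v = np.linalg.eigh(lap)
    keep = w > 1e-9 * max(w.max(), 1.0)
    z = rng.standard_normal(int(keep.sum()))
    phi = sd * (v[:, keep] @ (z / np.sqrt(w[keep])))
    # numerical cleanup: enforce the per-component zero sums exactly
    for comp in graph.connected_components():
        phi[comp] -= phi[comp].mean()
    return phi


class GraphStructureError(ValueError):
    pass


def simulate_population(graph: AreaGraph, years: int,
                        config: SimulationConfig) -> PopulationPanel:
    """Age-structured person-years growing at the configured rate.

    Area sizes are lognormal around ``base_person_years``; when
    ``ageing_rate > 0`` the 65+ age shares grow relative to the rest so the
    elderly proportion rises over time, emulating an ageing population.
    """
    if years < 1:
        raise ValueError("need at least one year")
    rng = np.random.default_rng([config.seed, 1])
    n = graph.n_areas
    sizes = config.base_person_years * np.exp(
        config.area_size_sd * rng.standard_normal(n) - config.area_size_sd ** 2 / 2)
    growth = 1.0 + config.growth_rate
    if growth < 0:
        warnings.warn("growth rate below -100%/yr: person-years clamped at 0")
        growth = 0.0
    age_edges = np.arange(0, 5 * len(config.age_shares), 5)
    old = age_edges >= 65
    pys = np.empty((n, years, len(config.age_shares)))
    for t in range(years):
        shares = config.age_shares.copy()
        shares[old] *= (1.0 + config.ageing_rate) ** t
        shares /= shares.sum()
        pys[:, t, :] = sizes[:, None] * growth ** t * shares[None, :]
    return PopulationPanel(
        areas=graph.area_ids,
        years=np.arange(config.start_year, config.start_year + years),
        age_groups=tuple(default_age_groups()[: len(config.age_shares)]),
        person_years=pys,
        age_edges=age_edges,
    )


def _quartiles(x: np.ndarray) -> np.ndarray:
    ranks = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    return 1 + (4 * ranks) // x.size


def sample_covariates(graph: AreaGraph, seed=None,
                      spatial: tuple = ()) -> CovariateTable:
    """Draw area-level covariates.

    Quartile covariates named in ``spatial`` are derived from a smooth ICAR
    surface (so they carry genuine spatial structure); the rest are
    exchangeable across areas.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = graph.n_areas

    def q(name):
        if name in spatial:
            return _quartiles(sample_icar(graph, 1.0, rng))
        return _quartiles(rng.standard_normal(n))

    return CovariateTable(
        areas=graph.area_ids,
        smoking_q=q("smoking"),
        elderly_q=q("elderly"),
        irsd_q=q("irsd"),
        pollution=rng.choice(POLLUTION_LEVELS, size=n, p=[0.15, 0.25, 0.30, 0.30]),
        remoteness=rng.choice(REMOTENESS_LEVELS, size=n, p=[0.55, 0.45]),
    )


class RateOverflowError(ValueError):
    pass


def simulate_registry(graph: AreaGraph, pops: PopulationPanel,
                      covs: CovariateTable, config: SimulationConfig) -> SimulatedRegistry:
    """Draw Poisson counts from the full generative model.

    Returns the registry with the latent truth (structured / unstructured
    effects, temporal path, and the expected counts ``e_it`` implied by the
    baseline rates) stored alongside the counts.
    """
    if tuple(pops.areas) != tuple(graph.area_ids):
        raise ValueError("population panel and graph disagree on areas")
    rng = np.random.default_rng([config.seed, 3])
    n, t_len, n_age = pops.person_years.shape

    phi = sample_icar(graph, config.sigma_phi, rng)
    nu = config.sigma_nu * rng.standard_normal(n)
    tt = np.arange(t_len) - (t_len - 1) / 2.0
    if config.temporal == "quadratic":
        time_eff = config.gamma1 * tt + config.gamma2 * tt ** 2
        omega = None
    else:
        omega = np.cumsum(config.sigma_omega * rng.standard_normal(t_len))
        omega -= omega.mean()
        time_eff = config.gamma1 * tt + omega
    xb = effects_vector(covs, config.covariate_effects)

    theta = config.alpha + (xb + phi + nu)[:, None] + time_eff[None, :]
    lam = config.baseline_rates[:n_age]
    with np.errstate(divide="ignore"):
        log_mu = np.log(pops.person_years * lam[None, None, :]) + theta[:, :, None]
    if np.any(log_mu > 50):
        i, t, a = np.unravel_index(int(np.argmax(log_mu)), log_mu.shape)
        raise RateOverflowError(
            f"linear predictor overflow at area={pops.areas[i]} "
            f"year={pops.years[t]} age={pops.age_groups[a]}")
    mu = pops.person_years * lam[None, None, :] * np.exp(theta[:, :, None])
    counts = rng.poisson(mu)

    e_it = (pops.person_years * lam[None, None, :]).sum(axis=2)
    latent = {"phi": phi, "nu": nu, "omega": omega, "time_effects": time_eff,
              "xb": xb, "theta": theta, "e": e_it, "mu": mu}
    return SimulatedRegistry(graph=graph, pops=pops, covs=covs, config=config,
                             counts=counts, latent=latent)


def write_registry(registry: SimulatedRegistry, outdir) -> None:
    """Persist a registry as plain-text artefacts (CSV + edge list + manifest)."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    registry.to_frame().to_csv(out / "counts.csv", index=False)
    registry.pops.to_frame(registry.config.sex).to_csv(out / "populations.csv", index=False)
    registry.covs.to_frame().to_csv(out / "covariates.csv", index=False)
    write_edge_list(registry.graph, out / "adjacency.txt")
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": registry.config.to_manifest()}, fh, indent=2)


def read_panel_csv(path) -> tuple[tuple, np.ndarray, tuple, np.ndarray]:
    """Read a long-format area,year,age_group,sex,value CSV back into an array."""
    df = pd.read_csv(path)
    areas = tuple(pd.unique(df["area"]))
    years = np.sort(pd.unique(df["year"]))
    ages = tuple(pd.unique(df["age_group"]))
    arr = (df.set_index(["area", "year", "age_group"])["value"]
             .unstack(["year", "age_group"])
             .reindex(list(areas))
             .reindex(columns=pd.MultiIndex.from_product([years, ages]))
             .to_numpy().reshape(len(areas), len(years), len(ages)))
    return areas, years, ages, arr
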