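"""Age standardization and expected counts.

Age-specific rates, directly age-standardized rates (ASR per 100,000), and
the expected counts e_it that enter the spatio-temporal model as a
multiplicative offset.  Observed-year expected counts use internal
standardization — statewide year-by-age rates applied to each area's age
structure — so that expected and observed totals match in every year.
Projected-year expected counts apply APC-projected age-specific rates to
projected populations.
"""

from __future__ import annotations

import numpy as np

E_FLOOR = 1e-6  # keeps log e_it finite for zero-population cells


class DataIntegrityError(ValueError):
    """Counts observed where the population at risk is zero."""


def age_specific_rates(counts: np.ndarray, person_years: np.ndarray,
                       statewide: bool = True) -> np.ndarray:
    """Cases per person-year by age category.

    With ``statewide=True`` (the default) area-shaped inputs
    (n_areas, n_years, n_ages) are pooled over areas first, returning a
    (n_years, n_ages) table; otherwise rates are cellwise at the given shape.
    Cells with zero person-years and zero counts get rate 0.
    """
    counts = np.asarray(counts, dtype=float)
    person_years = np.asarray(person_years, dtype=float)
    if counts.shape != person_years.shape:
        raise ValueError("counts and person-years shapes differ")
    if statewide and counts.ndim == 3:
        counts = counts.sum(axis=0)
        person_years = person_years.sum(axis=0)
    if np.any((counts > 0) & (person_years <= 0)):
        raise DataIntegrityError("positive counts with zero person-years")
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(person_years > 0, counts / np.where(person_years > 0,
                                                             person_years, 1.0), 0.0)
    return rates


def standard_weights(person_years: np.ndarray) -> np.ndarray:
    """Age weights of a standard population (proportions summing to 1).

    Accepts any array whose trailing axis is age; leading axes are pooled.
    """
    py = np.asarray(person_years, dtype=float)
    w = py.reshape(-1, py.shape[-1]).sum(axis=0)
    tot = w.sum()
    if tot <= 0:
        raise ValueError("standard population has no person-years")
    return w / tot


def direct_asr(rates: np.ndarray, weights: np.ndarray) -> np.ndarray | float:
    """Directly age-standardized rate per 100,000.

    ``rates`` has age on the trailing axis; ``weights`` must cover the same
    age groups and sum to 1.
    """
    rates = np.asarray(rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.shape[-1] != rates.shape[-1]:
        raise ValueError("weights do not cover the age groups of the rates")
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("standard weights must sum to 1")
    out = 1e5 * rates @ weights
    return float(out) if np.ndim(out) == 0 else out


def expected_counts_observed(pops, statewide_rates: np.ndarray) -> np.ndarray:
    """Internal-standardization expected counts for observed years.

    e_it = sum_a n_{i,t,a} * r_{t,a}, with r the statewide year-age rates
    computed from the same panel.  By construction sum_i e_it equals the
    statewide observed total in every year.
    """
    py = np.asarray(pops.person_years, dtype=float)
    r = np.asarray(statewide_rates, dtype=float)
    if r.shape != py.shape[1:]:
        raise ValueError("statewide rates must be (n_years, n_ages) matching the panel")
    e = (py * r[None, :, :]).sum(axis=2)
    return np.maximum(e, E_FLOOR)


def expected_counts_projected(projected_pops, apc_rates: np.ndarray,
                              rate_years=None) -> np.ndarray:
    """Expected counts for projection years from APC-projected rates.

    e_it = sum_a N_{i,t,a} * lambda_hat_{t,a}.  When ``rate_years`` is given,
    the rate table rows are aligned to the population panel's years and every
    panel year must be present.
    """
    py = np.asarray(projected_pops.person_years, dtype=float)
    r = np.asarray(apc_rates, dtype=float)
    if rate_years is not None:
        rate_years = list(np.asarray(rate_years).tolist())
        missing = [y for y in projected_pops.years if y not in rate_years]
        if missing:
            raise ValueError(f"projection years missing from APC rates: {missing}")
        r = r[[rate_years.index(y) for y in projected_pops.years]]
    if r.shape != py.shape[1:]:
        raise ValueError("rate table must be (n_years, n_ages) matching the panel")
    e = (py * r[None, :, :]).sum(axis=2)
    return np.maximum(e, E_FLOOR)
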