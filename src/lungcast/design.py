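"""Dummy coding of area-level categorical covariates.

Quartile covariates (smoking, elderly, IRSD) enter as indicators for
quartiles 2-4 with quartile 1 as reference; pollution uses "none" and
remoteness uses "metro" as reference categories.
"""

from __future__ import annotations

import numpy as np

QUARTILE_COVARIATES = {"smoking": "smoking_q", "elderly": "elderly_q", "irsd": "irsd_q"}
POLLUTION_DUMMIES = ("high", "medium", "low")   # reference: none
REMOTENESS_DUMMY = "regional"                   # reference: metro
KNOWN_COVARIATES = tuple(QUARTILE_COVARIATES) + ("pollution", "remoteness")


def covariate_design(covs, names) -> tuple[np.ndarray, list[str]]:
    """Build the (n_areas, q) dummy design matrix for the named covariates."""
    names = tuple(names)
    if len(set(names)) != len(names):
        raise ValueError("covariate names must be unique")
    cols, labels = [], []
    for name in names:
        if name in QUARTILE_COVARIATES:
            q = getattr(covs, QUARTILE_COVARIATES[name])
            for lvl in (2, 3, 4):
                cols.append((q == lvl).astype(float))
                labels.append(f"{name}_q{lvl}")
        elif name == "pollution":
            for lvl in POLLUTION_DUMMIES:
                cols.append((covs.pollution == lvl).astype(float))
                labels.append(f"pollution_{lvl}")
        elif name == "remoteness":
            cols.append((covs.remoteness == REMOTENESS_DUMMY).astype(float))
            labels.append("remoteness_regional")
        else:
            raise ValueError(f"unknown covariate {name!r}")
    if not cols:
        return np.zeros((len(covs.areas), 0)), []
    return np.column_stack(cols), labels


def effects_vector(covs, covariate_effects: dict) -> np.ndarray:
    """Per-area linear-predictor contribution of configured covariate effects.

    ``covariate_effects`` maps covariate name to a {level: coefficient} dict,
    e.g. ``{"elderly": {"q4": 0.4}, "pollution": {"high": 0.2}}``; omitted
    levels (including the references) contribute zero.
    """
    n = len(covs.areas)
    out = np.zeros(n)
    for name, levels in covariate_effects.items():
        if name in QUARTILE_COVARIATES:
            q = getattr(covs, QUARTILE_COVARIATES[name])
            for lvl, coef in levels.items():
                out += float(coef) * (q == int(str(lvl).lstrip("qQ")))
        elif name == "pollution":
            for lvl, coef in levels.items():
                out += float(coef) * (covs.pollution == lvl)
        elif name == "remoteness":
            for lvl, coef in levels.items():
                out += float(coef) * (covs.remoteness == lvl)
        else:
            raise ValueError(f"unknown covariate {name!r}")
    return out
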