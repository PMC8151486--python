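import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lungcast as lc

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lattice():
    """4x5 rook lattice: 20 areas, the small test fixture."""
    return lc.make_lattice_graph(4, 5)


@pytest.fixture(scope="session")
def registry(lattice):
    """Small synthetic registry with mild spatial and temporal structure."""
    cfg = lc.SimulationConfig(seed=11, alpha=0.0, sigma_phi=0.15, sigma_nu=0.1,
                              gamma1=0.01, gamma2=0.0,
                              base_person_years=50_000.0)
    pops = lc.simulate_population(lattice, 12, cfg)
    covs = lc.sample_covariates(lattice, 7)
    return lc.simulate_registry(lattice, pops, covs, cfg)


@pytest.fixture(scope="session")
def small_fit(registry):
    """Quick Model A fit on the small registry (truth offsets)."""
    data = lc.STData(registry.counts_total, registry.latent["e"],
                     registry.graph, registry.years, registry.covs)
    return lc.SpatioTemporalModel(temporal="quadratic", iterations=1200,
                                  burn_in=400, thin=2, seed=5).fit(data)


def zero_out_samples(fit):
    """Return the fit with every posterior draw replaced by zeros (RR = 1)."""
    for k, arr in fit.samples_.items():
        if not k.startswith("sigma"):
            fit.samples_[k] = np.zeros_like(arr)
    return fit
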