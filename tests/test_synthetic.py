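import dataclasses

import numpy as np
import pytest

import lungcast as lc
from lungcast.graph import AreaGraph
from lungcast.synthetic import GraphStructureError, RateOverflowError


# ---------------------------------------------------------------------------
# intrinsic CAR sampling
# ---------------------------------------------------------------------------

def icar_pairwise_variance(graph, sd, i, j):
    """Oracle: Var(phi_i - phi_j) from the Laplacian pseudo-inverse."""
    lap = graph.laplacian().toarray()
    w, v = np.linalg.eigh(lap)
    keep = w > 1e-9
    lplus = (v[:, keep] / w[keep]) @ v[:, keep].T
    return sd ** 2 * (lplus[i, i] + lplus[j, j] - 2 * lplus[i, j])


def test_icar_draw_sums_to_zero(lattice):
    phi = lc.sample_icar(lattice, 1.3, seed=0)
    assert phi.shape == (lattice.n_areas,)
    assert abs(phi.sum()) < 1e-10


def test_icar_zero_sd_degenerates_to_zero(lattice):
    assert np.all(lc.sample_icar(lattice, 0.0, seed=0) == 0)


@pytest.mark.parametrize("edges,pair", [
    ([(0, 1)], (0, 1)),                     # single edge
    ([(0, 1), (1, 2)], (0, 2)),             # 3-node path, endpoints
    ([(0, 1), (1, 2)], (0, 1)),             # 3-node path, edge
])
def test_icar_pairwise_difference_variance_matches_pseudoinverse(edges, pair):
    n = max(max(e) for e in edges) + 1
    g = AreaGraph([f"a{i}" for i in range(n)], edges)
    sd = 1.0
    rng = np.random.default_rng(42)
    draws = np.array([lc.sample_icar(g, sd, rng) for _ in range(10_000)])
    i, j = pair
    emp = np.var(draws[:, i] - draws[:, j])
    assert emp == pytest.approx(icar_pairwise_variance(g, sd, i, j), rel=0.05)


def test_icar_two_node_antisymmetric():
    g = AreaGraph(["a", "b"], [(0, 1)])
    phi = lc.sample_icar(g, 1.0, seed=3)
    assert phi[0] == pytest.approx(-phi[1])


def test_icar_requires_an_edge():
    g = AreaGraph(["a", "b"], [])
    with pytest.raises(GraphStructureError):
        lc.sample_icar(g, 1.0, seed=0)


def test_icar_islands_pinned_at_zero():
    g = AreaGraph(["a", "b", "c"], [(0, 1)])
    phi = lc.sample_icar(g, 1.0, seed=1)
    assert phi[2] == 0.0


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

def test_zero_growth_gives_identical_years(lattice):
    cfg = lc.SimulationConfig(seed=1, growth_rate=0.0, ageing_rate=0.0)
    pops = lc.simulate_population(lattice, 2, cfg)
    np.testing.assert_allclose(pops.person_years[:, 0], pops.person_years[:, 1])


def test_compound_growth():
    g = lc.make_lattice_graph(1, 2)
    cfg = lc.SimulationConfig(seed=1, base_person_years=1000.0,
                              area_size_sd=0.0, growth_rate=0.02,
                              ageing_rate=0.0)
    pops = lc.simulate_population(g, 6, cfg)
    assert pops.person_years[0, 5].sum() == pytest.approx(1000 * 1.02 ** 5)


def test_ageing_raises_elderly_share_monotonically(lattice):
    cfg = lc.SimulationConfig(seed=1, ageing_rate=0.02)
    pops = lc.simulate_population(lattice, 10, cfg)
    prop = pops.elderly_proportion()
    assert np.all(np.diff(prop, axis=1) > 0)


def test_catastrophic_negative_growth_clamps_with_warning():
    g = lc.make_lattice_graph(1, 2)
    cfg = lc.SimulationConfig(seed=1, growth_rate=-1.5)
    with pytest.warns(UserWarning):
        pops = lc.simulate_population(g, 3, cfg)
    assert np.all(pops.person_years >= 0)
    assert pops.person_years[:, 1:].sum() == 0


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def test_covariates_have_valid_categories(lattice):
    covs = lc.sample_covariates(lattice, 3)
    for q in (covs.smoking_q, covs.elderly_q, covs.irsd_q):
        assert set(q) <= {1, 2, 3, 4}
    assert set(covs.pollution) <= {"high", "medium", "low", "none"}
    assert set(covs.remoteness) <= {"metro", "regional"}


def test_spatial_covariate_is_smoother_than_random(lattice):
    """Quartiles from an ICAR surface agree more between neighbours."""
    def neighbour_agreement(q):
        same = [q[i] == q[j] for i, j in lattice.edges]
        return np.mean(same)
    smooth = [neighbour_agreement(
        lc.sample_covariates(lattice, s, spatial=("elderly",)).elderly_q)
        for s in range(10)]
    rough = [neighbour_agreement(lc.sample_covariates(lattice, s).elderly_q)
             for s in range(10)]
    assert np.mean(smooth) > np.mean(rough)


# ---------------------------------------------------------------------------
# registry simulation
# ---------------------------------------------------------------------------

def test_counts_conserve_over_age(registry):
    assert np.array_equal(registry.counts_total, registry.counts.sum(axis=2))
    assert registry.counts.dtype.kind in "iu"
    assert np.all(registry.counts >= 0)


def test_seed_determinism(lattice):
    cfg = lc.SimulationConfig(seed=99)
    pops = lc.simulate_population(lattice, 5, cfg)
    covs = lc.sample_covariates(lattice, 1)
    r1 = lc.simulate_registry(lattice, pops, covs, cfg)
    r2 = lc.simulate_registry(lattice, pops, covs,
                              dataclasses.replace(cfg))
    assert np.array_equal(r1.counts, r2.counts)
    np.testing.assert_array_equal(r1.latent["phi"], r2.latent["phi"])


def test_poisson_mean_with_all_effects_off():
    """With a flat linear predictor the cell mean equals n * lambda."""
    g = lc.make_lattice_graph(25, 20)
    cfg = lc.SimulationConfig(
        seed=5, alpha=0.0, sigma_phi=0.0, sigma_nu=0.0, gamma1=0.0,
        gamma2=0.0, growth_rate=0.0, ageing_rate=0.0, area_size_sd=0.0,
        base_person_years=10_000.0,
        baseline_rates=np.array([2e-3, 2e-3]),
        age_shares=np.array([0.5, 0.5]))
    pops = lc.simulate_population(g, 10, cfg)
    covs = lc.sample_covariates(g, 2)
    reg = lc.simulate_registry(g, pops, covs, cfg)
    c = 10_000.0 * 0.5 * 2e-3          # = 10 expected per cell
    n_cells = reg.counts.size           # 500 * 10 * 2 = 10,000 cells
    se = np.sqrt(c / n_cells)
    assert abs(reg.counts.mean() - c) < 3 * se


def test_intercept_scales_totals():
    g = lc.make_lattice_graph(5, 8)
    base = lc.SimulationConfig(seed=7, sigma_phi=0.0, sigma_nu=0.0,
                               gamma1=0.0)
    pops = lc.simulate_population(g, 10, base)
    covs = lc.sample_covariates(g, 2)
    tot0 = lc.simulate_registry(g, pops, covs, base).counts.sum()
    cfg2 = dataclasses.replace(base, alpha=np.log(2.0))
    tot2 = lc.simulate_registry(g, pops, covs, cfg2).counts.sum()
    assert tot2 / tot0 == pytest.approx(2.0, rel=0.03)


def test_rate_overflow_names_the_cell():
    g = lc.make_lattice_graph(1, 2)
    cfg = lc.SimulationConfig(seed=1, alpha=60.0)
    pops = lc.simulate_population(g, 2, cfg)
    covs = lc.sample_covariates(g, 1)
    with pytest.raises(RateOverflowError, match="area="):
        lc.simulate_registry(g, pops, covs, cfg)


def test_latent_truth_stored(registry):
    assert abs(registry.latent["phi"].sum()) < 1e-9
    assert registry.latent["e"].shape == registry.counts_total.shape


def test_registry_roundtrip_via_csv(tmp_path, registry):
    from lungcast.synthetic import read_panel_csv
    lc.write_registry(registry, tmp_path)
    areas, years, ages, counts = read_panel_csv(tmp_path / "counts.csv")
    assert np.array_equal(counts, registry.counts)
    assert tuple(areas) == registry.graph.area_ids
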