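import numpy as np
import pytest
from scipy.special import gammaln

import lungcast as lc
from lungcast.graph import AreaGraph
from lungcast.stmodel import (MCMCConfig, ModelSpec, Priors, STData,
                              default_state)


def tiny_data(temporal_cells=None):
    """3-area path graph, 2 years, moderate counts."""
    g = AreaGraph(["a", "b", "c"], [(0, 1), (1, 2)])
    y = np.array([[45.0, 50.0], [52.0, 55.0], [70.0, 66.0]])
    e = np.array([[40.0, 40.0], [50.0, 50.0], [60.0, 60.0]])
    return STData(y, e, g, np.array([2001, 2002]))


# -- linear predictor --------------------------------------------------------

def test_null_state_returns_log_offset(small_fit):
    data = small_fit.data_
    spec = ModelSpec("quadratic")
    st = default_state(spec, data, 0)
    assert lc.linear_predictor(st, spec, data, 3, 2) == pytest.approx(
        np.log(data.E[3, 2]))


def test_intercept_shifts_offset(small_fit):
    data = small_fit.data_
    spec = ModelSpec("quadratic")
    st = default_state(spec, data, 0)
    st["alpha"] = np.log(2.0)
    assert lc.linear_predictor(st, spec, data, 0, 0) == pytest.approx(
        np.log(2.0 * data.E[0, 0]))


def test_quadratic_with_zero_curvature_nests_linear():
    data = tiny_data()
    st = default_state(ModelSpec("quadratic"), data, 0)
    st["gamma1"], st["gamma2"] = 0.17, 0.0
    st_lin = dict(st)
    for t in range(data.n_years):
        assert lc.linear_predictor(st, ModelSpec("quadratic"), data, 1, t) == \
            pytest.approx(lc.linear_predictor(st_lin, ModelSpec("linear"),
                                              data, 1, t))


def test_year_outside_range_rejected():
    data = tiny_data()
    st = default_state(ModelSpec("quadratic"), data, 0)
    with pytest.raises(ValueError):
        lc.linear_predictor(st, ModelSpec("quadratic"), data, 0, 99)


# -- log posterior -----------------------------------------------------------

def test_single_cell_poisson_term_closed_form():
    """One island area, Y = 2, mu = 2: the likelihood part equals
    2 log 2 - 2 - log 2! ~ -1.30685 and nothing else contributes."""
    g = AreaGraph(["solo"], [])
    data = STData(np.array([[2.0]]), np.array([[2.0]]), g, np.array([2001]))
    spec = ModelSpec("none")
    st = default_state(spec, data, 0)
    lp = lc.log_posterior(st, spec, Priors(), data, include_unstructured=False)
    assert lp == pytest.approx(2 * np.log(2) - 2 - np.log(2), abs=1e-10)


def test_sd_outside_uniform_support_is_minus_inf():
    data = tiny_data()
    spec = ModelSpec("quadratic")
    st = default_state(spec, data, 0)
    st["sigma_phi"] = 11.0
    assert lc.log_posterior(st, spec, Priors(), data) == -np.inf
    st["sigma_phi"] = 0.005
    assert lc.log_posterior(st, spec, Priors(), data) == -np.inf


def test_model_variants_agree_on_matched_linear_states():
    """Model A with gamma2 = 0 and Model B with omega = 0 (sigma_omega = 1)
    collapse to the linear-trend model in the log posterior."""
    data = tiny_data()
    base = default_state(ModelSpec("linear"), data, 0)
    base["gamma1"] = 0.05
    base["phi"] = np.array([0.1, -0.05, -0.05])
    lp_lin = lc.log_posterior(base, ModelSpec("linear"), Priors(), data)
    lp_quad = lc.log_posterior(base, ModelSpec("quadratic"), Priors(), data)
    st_rw = dict(base)
    st_rw["sigma_omega"] = 1.0
    lp_rw = lc.log_posterior(st_rw, ModelSpec("rw1"), Priors(), data)
    assert lp_quad == pytest.approx(lp_lin, abs=1e-12)
    assert lp_rw == pytest.approx(lp_lin, abs=1e-12)


# -- ICAR full conditional ---------------------------------------------------

def test_icar_full_conditional_examples():
    g = AreaGraph(["a", "b", "c"], [(0, 1), (0, 2)])
    phi = np.array([0.0, 2.0, 4.0])
    m, v = lc.icar_full_conditional(0, phi, g, 1.0)
    assert (m, v) == (3.0, 0.5)
    m, v = lc.icar_full_conditional(1, phi, g, 2.0)
    assert (m, v) == (0.0, 4.0)


def test_icar_full_conditional_smoothing_fixed_point():
    g = lc.make_lattice_graph(3, 3)
    phi = np.full(9, 0.7)
    for i in range(9):
        m, _ = lc.icar_full_conditional(i, phi, g, 1.0)
        assert m == pytest.approx(0.7)


def test_icar_full_conditional_island_rejected():
    g = AreaGraph(["a", "b", "c"], [(0, 1)])
    with pytest.raises(ValueError, match="island"):
        lc.icar_full_conditional(2, np.zeros(3), g, 1.0)


# -- Gelman-Rubin ------------------------------------------------------------

def test_gelman_rubin_identical_chains():
    x = np.random.default_rng(0).standard_normal(500)
    assert lc.gelman_rubin(np.stack([x, x])) <= 1.0 + 1e-6


def test_gelman_rubin_disjoint_constants_diverges():
    assert lc.gelman_rubin(np.array([[1.0] * 50, [2.0] * 50])) == np.inf


def test_gelman_rubin_iid_normal_chains_near_one():
    rng = np.random.default_rng(7)
    chains = rng.standard_normal((2, 5000))
    assert lc.gelman_rubin(chains) < 1.01


def test_gelman_rubin_single_chain_rejected():
    with pytest.raises(ValueError):
        lc.gelman_rubin(np.ones((1, 100)))


# -- sampler integrity -------------------------------------------------------

def test_zero_iterations_rejected():
    with pytest.raises(ValueError):
        MCMCConfig(iterations=0)
    with pytest.raises(ValueError):
        MCMCConfig(iterations=100, burn_in=100)
    with pytest.raises(ValueError):
        MCMCConfig(chains=1)


def test_sum_to_zero_maintained_in_every_sample(small_fit):
    phi = small_fit.get_samples("phi")
    assert np.max(np.abs(phi.sum(axis=1))) < 1e-9


def test_rw1_sum_to_zero_and_sigma_in_support(registry):
    data = STData(registry.counts_total, registry.latent["e"],
                  registry.graph, registry.years, registry.covs)
    fit = lc.SpatioTemporalModel(temporal="rw1", iterations=600, burn_in=200,
                                 seed=3).fit(data)
    om = fit.get_samples("omega")
    assert np.max(np.abs(om.sum(axis=1))) < 1e-9
    so = fit.get_samples("sigma_omega")
    assert np.all((so >= 0.01) & (so <= 10.0))


def test_stored_deviance_matches_recomputation(small_fit):
    """The sampler's incremental bookkeeping must agree with a from-scratch
    deviance evaluation at retained states."""
    data = small_fit.data_
    for s in (0, small_fit.n_samples() // 2, small_fit.n_samples() - 1):
        st = {k: small_fit.get_samples(k)[s] for k in
              ("alpha", "beta", "gamma1", "gamma2", "phi", "nu", "omega")}
        eta = small_fit.eta_for(st)
        m = data.mask
        ll = float((data.Y * eta - np.exp(eta) - gammaln(data.Y + 1))[m].sum())
        assert small_fit.get_samples("deviance")[s] == pytest.approx(
            -2 * ll, rel=1e-8)


def test_retained_sample_count(small_fit):
    expected = (1200 - 400 + 1) // 2 * 2   # per chain ceil(800/2)=400, 2 chains
    assert small_fit.n_samples() == 2 * ((1200 - 400 + 1) // 2)
    assert np.all(np.isfinite(small_fit.get_samples("deviance")))


def test_offset_must_be_positive(registry):
    e = registry.latent["e"].copy()
    e[0, 0] = 0.0
    with pytest.raises(ValueError, match="positive"):
        STData(registry.counts_total, e, registry.graph, registry.years)


# -- posterior prediction ----------------------------------------------------

def test_zeroed_samples_predict_the_offset(small_fit):
    from conftest import zero_out_samples
    import copy
    fit = zero_out_samples(copy.deepcopy(small_fit))
    out = lc.posterior_predict(fit, fit.data_.E, seed=0)
    np.testing.assert_allclose(out["mean"], fit.data_.E, rtol=1e-12)


def test_predictive_mean_linear_in_offset(small_fit):
    out1 = lc.posterior_predict(small_fit, small_fit.data_.E, seed=0)
    out2 = lc.posterior_predict(small_fit, 2 * small_fit.data_.E, seed=0)
    np.testing.assert_allclose(out2["mean"], 2 * out1["mean"], rtol=1e-10)


def test_predictive_shape_mismatch_rejected(small_fit):
    with pytest.raises(ValueError):
        lc.posterior_predict(small_fit, small_fit.data_.E[:, :3])


def test_posterior_mean_bias_shrinks_with_data_size():
    """Average posterior-mean error for alpha and the elderly coefficient
    decreases from a 20-area/8-year design to an 80-area/18-year design."""
    import warnings as w

    def mean_bias(rows, cols, years, iters, seeds):
        g = lc.make_lattice_graph(rows, cols)
        err_a, err_b = [], []
        for s in seeds:
            cfg = lc.SimulationConfig(
                seed=7000 + s, alpha=0.3, sigma_phi=0.12, sigma_nu=0.08,
                gamma1=0.01, covariate_effects={"elderly": {"q4": 0.4}})
            pops = lc.simulate_population(g, years, cfg)
            covs = lc.sample_covariates(g, [7100, s])
            reg = lc.simulate_registry(g, pops, covs, cfg)
            data = STData(reg.counts_total, reg.latent["e"], g, reg.years, covs)
            with w.catch_warnings():
                w.simplefilter("ignore")
                fit = lc.SpatioTemporalModel(
                    "quadratic", covariates=("elderly",), iterations=iters,
                    burn_in=iters // 3, seed=s).fit(data)
            err_a.append(fit.get_samples("alpha").mean() - 0.3)
            err_b.append(fit.get_samples("beta")[:, 2].mean() - 0.4)
        return abs(np.mean(err_a)), abs(np.mean(err_b))

    small = mean_bias(4, 5, 8, 900, range(5))
    large = mean_bias(8, 10, 18, 1500, range(5))
    assert large[0] < small[0]
    assert large[1] < small[1]


def test_in_sample_prediction_beats_null_when_spatial_effects_exist(registry):
    """With genuine spatial variation the model's in-sample predictive means
    track observed counts better than the offset-only null."""
    data = STData(registry.counts_total, registry.latent["e"],
                  registry.graph, registry.years, registry.covs)
    fit = lc.SpatioTemporalModel(iterations=1000, burn_in=400, seed=2).fit(data)
    pred = lc.posterior_predict(fit, data.E, seed=0)["mean"]
    mape_model = lc.forecast_errors(data.Y, pred).mape
    mape_null = lc.forecast_errors(data.Y, data.E).mape
    assert mape_model < mape_null
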