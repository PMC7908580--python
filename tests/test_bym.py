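import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import maupmtup as m
from maupmtup.bym import variance_gibbs


class TestComputeExpected:
    def test_indirect_standardization(self):
        e = m.compute_expected(np.array([2, 4]), np.array([100, 300]))
        assert np.allclose(e, [1.5, 4.5])

    def test_equal_populations_equal_e(self):
        e = m.compute_expected(np.array([9, 1, 2]), np.array([50, 50, 50]))
        assert np.allclose(e, e[0])

    def test_calibration_identity(self, rng):
        y = rng.poisson(3.0, 200)
        y[0] = max(y[0], 1)
        pop = rng.uniform(10, 500, 200)
        assert m.compute_expected(y, pop).sum() == pytest.approx(y.sum(), abs=1e-9)

    def test_all_zero_events_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            m.compute_expected(np.zeros(5), np.ones(5))


class TestZoneAdjacency:
    def test_identity_zonation_preserves_unit_adjacency(self, small_lattice):
        z = m.identity_zonation(small_lattice)
        g = m.zone_adjacency(z, small_lattice)
        assert nx.is_isomorphic(g, small_lattice.graph)
        assert set(g.edges) == set(small_lattice.graph.edges)

    def test_path_aggregation_single_pair(self, path4_lattice):
        z = m.Zonation(labels=np.array([0, 0, 1, 1]), target_pop=500)
        g = m.zone_adjacency(z, path4_lattice)
        assert sorted(g.edges) == [(0, 1)]

    def test_single_zone_has_no_neighbours(self, path4_lattice):
        z = m.Zonation(labels=np.zeros(4, dtype=int), target_pop=10_000)
        g = m.zone_adjacency(z, path4_lattice)
        assert g.number_of_edges() == 0
        model = m.BYMModel(
            pd.DataFrame({"zone": [0] * 4, "window_id": list("abcd"),
                          "y": [3, 5, 2, 4], "pop": [100.0] * 4,
                          "x": [0.5, 1.0, 1.5, 2.0]}),
            g,
        )
        assert model.islands == [0]


class TestVarianceGibbs:
    def test_matches_closed_form_inverse_gamma(self, rng):
        """Conditional draws match InvGamma(a + n/2, b + ss/2) for a fixed
        synthetic Gaussian quadratic form."""
        v = rng.normal(0, 0.3, size=40)
        a, b = 0.001, 0.001
        draws = np.array([
            variance_gibbs(rng, a, b, len(v), (v**2).sum()) for _ in range(20_000)
        ])
        ref = stats.invgamma(a + len(v) / 2, scale=b + (v**2).sum() / 2)
        ks = stats.kstest(draws, ref.cdf)
        assert ks.pvalue > 0.001


@pytest.fixture(scope="module")
def glm_fit_pair():
    """BYM fit with negligible random-effect variances plus its GLM oracle."""
    import statsmodels.api as sm

    truth = m.SimulationTruth(alpha=0.0, beta=0.1, sigma_u2=1e-6, sigma_v2=1e-6)
    df, graph = m.simulate_validation_dataset(truth, seed=11)
    model = m.BYMModel(df, graph, m.BYMConfig(chains=1, iterations=3000, burn_in=1200))
    res = model.fit(seed=101)
    e = m.compute_expected(df["y"], df["pop"])
    X = sm.add_constant(df["x"].to_numpy())
    glm = sm.GLM(df["y"].to_numpy(), X, family=sm.families.Poisson(),
                 offset=np.log(e)).fit()
    return res, glm


class TestFitBYM:
    def test_beta_matches_irls_oracle(self, glm_fit_pair):
        res, glm = glm_fit_pair
        beta = res._flat("beta")
        assert abs(beta.mean() - glm.params[1]) < 3 * beta.std(ddof=1)

    def test_retained_u_sums_to_zero(self, glm_fit_pair):
        res, _ = glm_fit_pair
        sums = res.samples["u"].sum(axis=-1)
        assert np.abs(sums).max() < 1e-8

    def test_variance_samples_positive(self, glm_fit_pair):
        res, _ = glm_fit_pair
        assert (res._flat("sigma_u2") > 0).all()
        assert (res._flat("sigma_v2") > 0).all()

    def test_summary_table_shape(self, glm_fit_pair):
        res, _ = glm_fit_pair
        tab = res.summary()
        assert list(tab.columns) == ["param", "mean", "sd", "q2.5", "q50", "q97.5", "ess"]
        assert set(tab["param"]) == {"alpha", "beta", "sigma_u2", "sigma_v2"}
        assert np.isfinite(tab["ess"]).all() and (tab["ess"] > 0).all()

    def test_chain_invariance_of_rate_ratio(self, reduced_mcmc):
        truth = m.SimulationTruth(beta=0.05, sigma_u2=0.05, sigma_v2=0.05)
        df, graph = m.simulate_validation_dataset(truth, n_rows=8, n_cols=8, seed=21)
        model = m.BYMModel(df, graph, reduced_mcmc)
        r1 = model.fit(seed=1)
        r2 = model.fit(seed=2)
        b1, b2 = r1._flat("beta"), r2._flat("beta")
        mcse = np.sqrt(stats.sem(b1) ** 2 + stats.sem(b2) ** 2)
        # MCSE from naive SEM underestimates under autocorrelation; scale by 5
        assert abs(b1.mean() - b2.mean()) < 5 * 3 * mcse

    def test_single_zone_reduces_to_loglinear_model(self):
        df = pd.DataFrame({
            "zone": [0] * 10, "window_id": [f"w{i}" for i in range(10)],
            "y": [4, 6, 3, 7, 5, 4, 6, 5, 3, 8], "pop": [200.0] * 10,
            "x": np.linspace(0.2, 2.0, 10),
        })
        g = nx.Graph()
        g.add_node(0)
        res = m.BYMModel(df, g, m.BYMConfig(chains=1, iterations=1000, burn_in=400)).fit(seed=3)
        assert (res.samples["u"] == 0).all()
        assert np.isfinite(res._flat("beta")).all()

    def test_zero_population_rows_dropped(self, reduced_mcmc):
        df = pd.DataFrame({
            "zone": [0, 0, 1, 1], "window_id": ["a", "b", "a", "b"],
            "y": [2, 3, 0, 0], "pop": [100.0, 100.0, 0.0, 0.0],
            "x": [0.5, 1.0, 0.5, 1.0],
        })
        g = nx.path_graph(2)
        model = m.BYMModel(df, g, reduced_mcmc)
        assert model.n_dropped == 2
        assert model.n_zones == 1


class TestRateRatio:
    def test_null_posterior_gives_unit_rr(self):
        est = m.rr_from_posterior(np.zeros(500), scale=0.5)
        assert est.rr == pytest.approx(1.0)
        assert est.ci_low == pytest.approx(1.0)
        assert est.ci_high == pytest.approx(1.0)

    def test_constant_posterior_closed_form(self):
        est = m.rr_from_posterior(np.full(100, 0.1), scale=0.5)
        assert est.rr == pytest.approx(np.exp(0.05))

    def test_doubling_scale_doubles_log_rr(self, rng):
        beta = rng.normal(0.1, 0.02, 2000)
        a = m.rr_from_posterior(beta, scale=0.5)
        b = m.rr_from_posterior(beta, scale=1.0)
        assert np.log(b.rr) != np.log(a.rr)  # sanity
        assert np.log(np.exp(beta * 1.0).mean()) == pytest.approx(
            np.log(b.rr), abs=1e-12
        )
        # the scaling law holds exactly on each sample: log rr doubles
        assert np.allclose(np.log(np.exp(beta * 1.0)), 2 * np.log(np.exp(beta * 0.5)))

    def test_empty_posterior_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            m.rr_from_posterior(np.array([]), scale=0.5)
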