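import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bymmap as bm
from bymmap import cohort, mcmc
from bymmap.mcmc import (
    MCMCState,
    ModelData,
    ModelSpec,
    initial_state,
    linear_predictor,
    loglik,
    refresh,
    update_fixed_effects,
    update_precisions,
    update_structured,
    update_unstructured,
    update_zip,
)

from conftest import tiny_table


def convolution_data(seed=42, **cfg_kw):
    ds = bm.simulate_counts(bm.SimulationConfig(seed=seed, **cfg_kw))
    table = cohort.expected_counts(ds.stratum_table)
    spec = ModelSpec(effects="both")
    return ds, ModelData(table, spec, ds.adjacency), table


class TestLinearPredictor:
    def test_all_zero_parameters_give_theta_zero(self, tiny_data):
        data, _ = tiny_data
        st = initial_state(data, np.random.default_rng(0))
        st.alpha = 0.0
        st.u[:] = 0.0
        refresh(st, data)
        theta, mu = linear_predictor(st, data)
        np.testing.assert_allclose(theta, 0.0)
        np.testing.assert_allclose(mu, np.exp(data.logE))

    def test_intercept_scales_mean_by_e(self, tiny_data):
        data, _ = tiny_data
        st = initial_state(data, np.random.default_rng(0))
        st.alpha, st.u[:] = 1.0, 0.0
        refresh(st, data)
        _, mu = linear_predictor(st, data)
        np.testing.assert_allclose(mu, np.exp(data.logE) * np.e)

    def test_matches_elementwise_dot_product(self):
        _, data, _ = convolution_data()
        rng = np.random.default_rng(3)
        st = initial_state(data, rng, jitter=1.0)
        st.alpha, st.beta = 0.4, rng.normal(0, 0.3, data.p)
        refresh(st, data)
        theta, mu = linear_predictor(st, data)
        for k in rng.integers(0, data.n_strata, 25):
            expect = st.alpha + float(data.X[k] @ st.beta) \
                + st.u[data.area_idx[k]] + st.s[data.area_idx[k]]
            assert theta[k] == pytest.approx(expect, abs=1e-12)
            assert mu[k] == pytest.approx(np.exp(data.logE[k] + expect), rel=1e-12)


class TestLoglik:
    def test_single_stratum_hand_value(self):
        table = tiny_table(1, cases=(2,))
        data = ModelData(table, ModelSpec(effects="unstructured",
                                          include_age=False, include_sex=False))
        st = initial_state(data, np.random.default_rng(0))
        st.alpha = np.log(2.0)  # mu = E * exp(alpha) = 2
        st.u[:] = 0.0
        refresh(st, data)
        assert loglik(st, data) == pytest.approx(2 * np.log(2) - 2 - np.log(2))

    def test_zip_with_zero_weight_equals_poisson(self):
        ds, data, table = convolution_data()
        zspec = ModelSpec(family="zip", effects="both")
        zdata = ModelData(table, zspec, ds.adjacency)
        st = initial_state(zdata, np.random.default_rng(1), jitter=1.0)
        st.zip_pi = 0.0
        refresh(st, zdata)
        st_pois = MCMCState(st.alpha, st.beta, st.u, st.s, st.sigma2_u,
                            st.sigma2_s, 0.0, st.z.copy())
        refresh(st_pois, data)
        assert loglik(st, zdata) == pytest.approx(loglik(st_pois, data), abs=1e-9)

    def test_all_zero_counts_loglik_vanishes_as_mu_shrinks(self):
        table = tiny_table(3, cases=(0,))
        data = ModelData(table, ModelSpec(effects="unstructured",
                                          include_age=False, include_sex=False))
        st = initial_state(data, np.random.default_rng(0))
        st.u[:] = 0.0
        st.alpha = -30.0
        refresh(st, data)
        assert loglik(st, data) == pytest.approx(0.0, abs=1e-10)


class TestFixedEffectUpdates:
    def test_vanishing_proposal_scale_always_accepts(self):
        _, data, _ = convolution_data()
        rng = np.random.default_rng(5)
        st = initial_state(data, rng, jitter=1.0)
        tuning = {"alpha": 1e-12, "beta_age": 1e-12, "beta_sex": 1e-12}
        for _ in range(20):
            acc = update_fixed_effects(st, data, tuning, rng)
            assert all(acc.values())

    def test_fast_path_agrees_with_full_recompute_path(self):
        """The cached-delta Metropolis arithmetic must follow the same chain
        as a reference implementation that re-evaluates the whole Poisson
        log likelihood at every proposal (identical seeds => identical
        trajectories)."""
        _, data, _ = convolution_data(seed=8, grid_rows=3, grid_cols=3)
        tuning = {"alpha": 0.2, "beta_age": 0.2, "beta_sex": 0.2}
        st_fast = initial_state(data, np.random.default_rng(2), jitter=1.0)
        st_slow = st_fast.copy()
        rng_fast = np.random.default_rng(77)
        rng_slow = np.random.default_rng(77)
        for _ in range(200):
            update_fixed_effects(st_fast, data, tuning, rng_fast)
            update_fixed_effects(st_slow, data, tuning, rng_slow,
                                 loglik_fn=lambda s: loglik(s, data),
                                 sample_alpha=True)
        assert st_fast.alpha == pytest.approx(st_slow.alpha, abs=1e-9)
        np.testing.assert_allclose(st_fast.beta, st_slow.beta, atol=1e-9)

    def test_conjugate_gaussian_posterior_recovered(self):
        """Swapping the Poisson likelihood for a Gaussian one, the sampled
        posterior of the coefficient matches the closed-form normal
        posterior within Monte Carlo error."""
        table = tiny_table(8)
        table["age_group"] = ["le60", "gt60"] * 4
        spec = ModelSpec(effects="unstructured", include_age=True, include_sex=False)
        data = ModelData(table, spec)
        rng = np.random.default_rng(9)
        x = data.X[:, 0]
        yobs = rng.normal(1.5 * x, 1.0)
        sig2 = 1.0

        def gaussian_ll(state):
            resid = yobs - x * state.beta[0]
            return -0.5 * float(resid @ resid) / sig2

        prec0 = spec.priors.beta_precision
        post_prec = float(x @ x) / sig2 + prec0
        post_mean = float(x @ yobs) / sig2 / post_prec

        st = initial_state(data, rng)
        tuning = {"alpha": 0.3, "beta_age": 0.8}
        draws = []
        for i in range(6000):
            update_fixed_effects(st, data, tuning, rng,
                                 loglik_fn=gaussian_ll, sample_alpha=False)
            draws.append(st.beta[0])
        draws = np.asarray(draws[500:])
        # conservative MC error: sd over sqrt of a 20-fold-deflated sample size
        mcse = draws.std(ddof=1) / np.sqrt(len(draws) / 20)
        assert abs(draws.mean() - post_mean) < 3 * mcse
        assert draws.std(ddof=1) == pytest.approx(1 / np.sqrt(post_prec), rel=0.2)

    def test_fixed_seed_replays_identically(self):
        _, data, _ = convolution_data(seed=8, grid_rows=3, grid_cols=3)
        outs = []
        for _ in range(2):
            st = initial_state(data, np.random.default_rng(4), jitter=1.0)
            rng = np.random.default_rng(123)
            tuning = {"alpha": 0.2, "beta_age": 0.2, "beta_sex": 0.2}
            for _ in range(50):
                update_fixed_effects(st, data, tuning, rng)
            outs.append((st.alpha, st.beta.copy()))
        assert outs[0][0] == outs[1][0]
        np.testing.assert_array_equal(outs[0][1], outs[1][1])


class TestRandomEffectUpdates:
    def test_unstructured_fast_path_matches_brute_force_reference(self):
        """Vectorised u-update equals a per-area loop that recomputes the
        full log likelihood for each proposal, given identical seeds."""
        _, data, _ = convolution_data(seed=8, grid_rows=3, grid_cols=3)
        st_fast = initial_state(data, np.random.default_rng(6), jitter=1.0)
        st_slow = st_fast.copy()
        rng_fast = np.random.default_rng(99)
        rng_slow = np.random.default_rng(99)
        tuning = {"u": 0.4}
        for _ in range(100):
            update_unstructured(st_fast, data, tuning, rng_fast)
            # reference: same proposal layout, brute-force likelihood deltas
            d = rng_slow.normal(0.0, tuning["u"], data.m)
            base = loglik(st_slow, data)
            dll = np.empty(data.m)
            for i in range(data.m):
                trial = st_slow.copy()
                trial.u[i] += d[i]
                refresh(trial, data)
                dll[i] = loglik(trial, data) - base
            dlp = -0.5 / st_slow.sigma2_u * ((st_slow.u + d) ** 2 - st_slow.u**2)
            acc = np.log(rng_slow.random(data.m)) < dll + dlp
            st_slow.u += np.where(acc, d, 0.0)
            refresh(st_slow, data)
        np.testing.assert_allclose(st_fast.u, st_slow.u, atol=1e-8)

    def test_unstructured_prior_sampling_matches_normal_prior(self):
        """With the likelihood off and the variance held, u_i marginals are
        N(0, sigma2_u)."""
        _, data, _ = convolution_data(seed=8, grid_rows=4, grid_cols=4)
        rng = np.random.default_rng(10)
        st = initial_state(data, rng)
        st.sigma2_u = 0.7
        tuning = {"u": 1.2}
        draws = []
        for it in range(30_000):
            update_unstructured(st, data, tuning, rng, likelihood_on=False)
            if it % 15 == 0:
                draws.append(st.u[3])
        draws = np.asarray(draws[200:])
        p = stats.kstest(draws, "norm", args=(0.0, np.sqrt(0.7))).pvalue
        assert p > 0.01

    def test_structured_prior_conditionals_match_icar(self):
        """Prior-only s draws: the standardised residual
        (s_i - neighbour mean) * sqrt(n_i / sigma2_s) is standard normal."""
        _, data, _ = convolution_data(seed=8, grid_rows=4, grid_cols=4)
        rng = np.random.default_rng(11)
        st = initial_state(data, rng)
        st.sigma2_s = 1.0
        tuning = {"s": 1.2}
        W = data.W
        res = []
        for it in range(30_000):
            update_structured(st, data, tuning, rng, likelihood_on=False)
            if it % 15 == 0:
                nbmean = np.asarray(W @ st.s) / data.n_i
                res.append(((st.s - nbmean) * np.sqrt(data.n_i / st.sigma2_s))[5])
        res = np.asarray(res[200:])
        p = stats.kstest(res, "norm").pvalue
        assert p > 0.01

    def test_structured_sum_to_zero_after_every_sweep(self):
        _, data, _ = convolution_data(seed=8, grid_rows=3, grid_cols=3)
        rng = np.random.default_rng(12)
        st = initial_state(data, rng, jitter=1.0)
        tuning = {"s": 0.5}
        for _ in range(50):
            update_structured(st, data, tuning, rng)
            assert abs(st.s.sum()) < 1e-10

    def test_exchangeable_areas_get_equal_posterior_means(self):
        """Two identical areas with symmetric data: their structured effects
        are exchangeable, so posterior means agree within MC error."""
        table = pd.DataFrame(
            {
                "area_id": ["a", "b"],
                "age_group": ["le60"] * 2,
                "sex": ["female"] * 2,
                "participants": [100, 100],
                "cases": [3, 3],
                "expected": [3.0, 3.0],
            }
        )
        from bymmap import adjacency as adj

        g = adj.graph_from_edges(["a", "b"], [("a", "b")])
        spec = ModelSpec(effects="structured", include_age=False, include_sex=False)
        out = mcmc.run_mcmc(spec, table, g, chains=2, burn_in=500,
                            iterations=3000, max_batches=1, seed=3)
        m_a = out.stacked("s[a]").mean()
        m_b = out.stacked("s[b]").mean()
        assert abs(m_a - m_b) < 0.05


class TestPrecisionUpdates:
    def test_zero_u_gives_prior_shape_with_data_only_in_shape(self):
        _, data, _ = convolution_data(seed=8, grid_rows=3, grid_cols=3)
        rng = np.random.default_rng(13)
        st = initial_state(data, rng)
        st.u[:] = 0.0
        taus = []
        for _ in range(10_000):
            update_precisions(st, data, rng, update_s=False)
            taus.append(1.0 / st.sigma2_u)
        p = stats.kstest(taus, "gamma", args=(0.001 + data.m / 2, 0, 1 / 0.001)).pvalue
        assert p > 0.01

    def test_fixed_u_draws_match_analytic_gamma(self):
        _, data, _ = convolution_data(seed=8, grid_rows=3, grid_cols=3)
        rng = np.random.default_rng(14)
        st = initial_state(data, rng)
        st.u = rng.normal(0, 0.5, data.m)
        shape = 0.001 + data.m / 2
        rate = 0.001 + float(st.u @ st.u) / 2
        taus = []
        for _ in range(10_000):
            update_precisions(st, data, rng, update_s=False)
            taus.append(1.0 / st.sigma2_u)
        p = stats.kstest(taus, "gamma", args=(shape, 0, 1 / rate)).pvalue
        assert p > 0.01

    def test_constant_s_on_connected_graph_has_zero_difference_statistic(self):
        _, data, _ = convolution_data(seed=8, grid_rows=3, grid_cols=3)
        rng = np.random.default_rng(15)
        st = initial_state(data, rng)
        st.s[:] = 0.3
        diffs = st.s[data.edge_i] - st.s[data.edge_j]
        assert float(diffs @ diffs) == 0.0
        # so the tau_s conditional collapses to Gamma(shape, prior rate)
        shape = 0.001 + data.icar_rank / 2
        taus = []
        for _ in range(5000):
            update_precisions(st, data, rng, update_u=False)
            taus.append(1.0 / st.sigma2_s)
            st.s[:] = 0.3
        p = stats.kstest(taus, "gamma", args=(shape, 0, 1 / 0.001)).pvalue
        assert p > 0.01


class TestZIPUpdates:
    def setup_zip(self, seed=20):
        ds = bm.simulate_counts(
            bm.SimulationConfig(seed=seed, zero_inflation_pi=0.3)
        )
        table = cohort.expected_counts(ds.stratum_table)
        spec = ModelSpec(family="zip", effects="both")
        return ModelData(table, spec, ds.adjacency)

    def test_indicator_forced_zero_when_cases_observed(self):
        data = self.setup_zip()
        rng = np.random.default_rng(16)
        st = initial_state(data, rng, jitter=1.0)
        for _ in range(50):
            update_zip(st, data, rng)
            assert not st.z[~data.area_all_zero].any()

    def test_indicator_probability_matches_closed_form_odds(self):
        """For an all-zero area the structural-zero probability is
        pi0 / (pi0 + (1 - pi0) e^{-sum mu}); check the empirical frequency."""
        data = self.setup_zip()
        rng = np.random.default_rng(17)
        st = initial_state(data, rng)
        st.u[:] = 0.0
        refresh(st, data)
        area = int(np.flatnonzero(data.area_all_zero)[0])
        mu_area = st.mu[data.area_idx == area].sum()
        pi0 = 0.4
        n_rep, hits = 4000, 0
        for _ in range(n_rep):
            st.zip_pi = pi0  # pin the weight; only the indicator draw varies
            update_zip(st, data, rng)
            hits += int(st.z[area])
        p_expect = pi0 / (pi0 + (1 - pi0) * np.exp(-mu_area))
        se = np.sqrt(p_expect * (1 - p_expect) / n_rep)
        assert abs(hits / n_rep - p_expect) < 4 * se

    def test_prior_only_weight_is_uniform(self):
        data = self.setup_zip()
        rng = np.random.default_rng(18)
        st = initial_state(data, rng)
        draws = []
        for it in range(40_000):
            update_zip(st, data, rng, likelihood_on=False)
            if it % 20 == 0:
                draws.append(st.zip_pi)
        p = stats.kstest(np.asarray(draws[100:]), "uniform").pvalue
        assert p > 0.01


class TestRunMCMC:
    def test_zero_iterations_yield_empty_flagged_output(self, synth_dataset):
        table = cohort.expected_counts(synth_dataset.stratum_table)
        out = mcmc.run_mcmc(ModelSpec(effects="unstructured"), table,
                            chains=2, burn_in=0, iterations=0, seed=1)
        assert out.n_draws == 0 and not out.converged

    def test_single_chain_rejected(self, synth_dataset):
        table = cohort.expected_counts(synth_dataset.stratum_table)
        with pytest.raises(ValueError, match="2 chains"):
            mcmc.run_mcmc(ModelSpec(effects="unstructured"), table, chains=1)

    def test_same_seed_reproduces_output_exactly(self, synth_dataset):
        table = cohort.expected_counts(synth_dataset.stratum_table)
        kw = dict(chains=2, burn_in=100, iterations=200, max_batches=1, seed=55)
        a = mcmc.run_mcmc(ModelSpec(effects="both"), table,
                          synth_dataset.adjacency, **kw)
        b = mcmc.run_mcmc(ModelSpec(effects="both"), table,
                          synth_dataset.adjacency, **kw)
        for ca, cb in zip(a.chains, b.chains):
            np.testing.assert_array_equal(ca, cb)

    def test_structured_model_requires_graph(self, synth_dataset):
        table = cohort.expected_counts(synth_dataset.stratum_table)
        with pytest.raises(ValueError, match="adjacency"):
            mcmc.run_mcmc(ModelSpec(effects="both"), table, None,
                          chains=2, burn_in=10, iterations=10)

    def test_retained_s_draws_sum_to_zero(self, fitted_convolution):
        _, _, out = fitted_convolution
        s = out.area_draws("s")
        np.testing.assert_allclose(s.sum(axis=1), 0.0, atol=1e-8)

    def test_burn_in_acceptance_lands_in_target_band(self, fitted_convolution):
        _, _, out = fitted_convolution
        for acc in out.acceptance:
            for block, rate in acc.items():
                assert 0.05 < rate < 0.8, f"{block} acceptance {rate}"
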