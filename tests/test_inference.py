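import numpy as np
import pytest

import steppm as sp
from steppm.inference import _split_rhat, greedy_coloring


def tiny_fit(seed=1, iters=400, burn=150, family="model1a"):
    scen = sp.SimulationScenario(rows=5, cols=5, n_periods=4, seed=seed)
    res = sp.simulate_counts(scen)
    spec = scen.model_spec(family)
    cfg = sp.MCMCConfig(n_iterations=iters, n_burnin=burn, seed=seed)
    return sp.fit(spec, res.panel, res.weights, cfg=cfg), res, spec


class TestUpdatePrecision:
    def test_conjugacy_algebra(self):
        # prior (1, 5e-5), rank 3, quadratic form 2 -> Gamma(2.5, 1.00005)
        s = sp.iid_structure(3)
        field = np.array([1.0, 1.0, 0.0])   # q = 2
        rng = np.random.default_rng(0)
        draws = np.array([sp.update_precision(field, s, (1.0, 5e-5), rng)
                          for _ in range(10_000)])
        a_post, b_post = 2.5, 1.00005
        se_mean = np.sqrt(a_post / b_post ** 2 / len(draws))
        assert abs(draws.mean() - a_post / b_post) < 3 * se_mean

    def test_zero_field_posterior_is_prior_plus_rank(self):
        s = sp.rw2_structure(6)          # rank 4
        rng = np.random.default_rng(1)
        draws = np.array([sp.update_precision(np.zeros(6), s, (2.0, 1.0), rng)
                          for _ in range(20_000)])
        a_post, b_post = 2.0 + 2.0, 1.0
        assert draws.mean() == pytest.approx(a_post / b_post, rel=0.05)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            sp.update_precision(np.zeros(3), sp.iid_structure(3), (0.0, 1.0), 0)


class TestGreedyColoring:
    def test_classes_are_independent_sets(self):
        _, w = sp.make_lattice(6, 6)
        classes = greedy_coloring(w.neighbors)
        assert sorted(i for cls in classes for i in cls) == list(range(36))
        for cls in classes:
            s = set(cls)
            for i in cls:
                assert not (s & set(w.neighbors[i]))


class TestFit:
    def test_deterministic_given_seed(self):
        d1, _, _ = tiny_fit(seed=3)
        d2, _, _ = tiny_fit(seed=3)
        np.testing.assert_array_equal(d1.alpha, d2.alpha)
        np.testing.assert_array_equal(d1.u, d2.u)
        for k in d1.beta:
            np.testing.assert_array_equal(d1.beta[k], d2.beta[k])

    def test_constraints_hold_in_stored_draws(self):
        d, res, _ = tiny_fit(seed=4)
        np.testing.assert_allclose(d.delta.sum(axis=1), 0, atol=1e-8)
        np.testing.assert_allclose(d.u.sum(axis=1), 0, atol=1e-8)

    def test_dynamic_family_constraints(self):
        d, _, _ = tiny_fit(seed=5, family="model2")
        np.testing.assert_allclose(d.phi.sum(axis=1), 0, atol=1e-8)
        np.testing.assert_allclose(d.psi.sum(axis=1), 0, atol=1e-8)

    def test_model1b_f_constraints(self):
        scen = sp.SimulationScenario(rows=5, cols=5, n_periods=4, seed=6)
        res = sp.simulate_counts(scen)
        spec = scen.model_spec("model1b", rw2=("unemployment",), rw2_bins=8)
        d = sp.fit(spec, res.panel, res.weights,
                   cfg=sp.MCMCConfig(n_iterations=300, n_burnin=100, seed=6))
        np.testing.assert_allclose(d.f["unemployment"].sum(axis=1), 0, atol=1e-8)

    def test_dimension_mismatch_rejected(self):
        _, res, spec = tiny_fit(seed=7, iters=60, burn=10)
        _, w_other = sp.make_lattice(3, 3)
        with pytest.raises(ValueError, match="dimension"):
            sp.fit(spec, res.panel, w_other)

    def test_iid_marginals_match_independent_chain(self):
        # two chains with different seeds agree in distribution (KS < 0.05)
        from scipy.stats import ks_2samp
        scen = sp.SimulationScenario(rows=5, cols=5, n_periods=4, seed=8)
        res = sp.simulate_counts(scen)
        spec = scen.model_spec("null_parametric")
        cfg = dict(n_iterations=12_000, n_burnin=2_000)
        d1 = sp.fit(spec, res.panel, res.weights,
                    cfg=sp.MCMCConfig(seed=1, **cfg))
        d2 = sp.fit(spec, res.panel, res.weights,
                    cfg=sp.MCMCConfig(seed=2, **cfg))
        assert ks_2samp(d1.alpha, d2.alpha).statistic < 0.05


class TestDIC:
    def one_cell_draws(self, alphas):
        spec = sp.ModelSpec("null_parametric")
        S = len(alphas)
        return sp.PosteriorDraws(
            spec=spec, seed=0, area_ids=("A",), periods=(2007,),
            alpha=np.asarray(alphas, float), beta={}, gamma=np.zeros(S),
            delta=np.zeros((S, 1)), u=np.zeros((S, 1)), v=np.zeros((S, 1)),
            f={}, phi=np.zeros((S, 1)), psi=np.zeros((S, 1)), tau={},
            acceptance={}, rhat={})

    def test_hand_oracle_one_cell(self):
        # y=4, P chosen so E=y; deviance at alpha: -2*(y(logE+a)-E e^a - log y!)
        panel = sp.ArealPanel(("A",), (2007,), np.array([[4]]), np.array([[1.0]]))
        alphas = [0.0, 0.3, -0.2]
        draws = self.one_cell_draws(alphas)
        got = sp.dic(draws, panel)
        E = 4.0
        from scipy.special import gammaln
        dev = lambda a: -2 * (4 * (np.log(E) + a) - E * np.exp(a) - gammaln(5.0))
        Dbar = np.mean([dev(a) for a in alphas])
        Dhat = dev(np.mean(alphas))
        assert got.Dbar == pytest.approx(Dbar, rel=1e-12)
        assert got.D_hat == pytest.approx(Dhat, rel=1e-12)
        assert got.DIC == pytest.approx(Dbar + (Dbar - Dhat), rel=1e-12)

    def test_degenerate_posterior_has_zero_pd(self):
        panel = sp.ArealPanel(("A",), (2007,), np.array([[4]]), np.array([[1.0]]))
        got = sp.dic(self.one_cell_draws([0.25, 0.25, 0.25]), panel)
        assert got.pD == pytest.approx(0.0, abs=1e-10)
        assert got.DIC == pytest.approx(got.Dbar, abs=1e-10)

    def test_needs_two_draws(self):
        panel = sp.ArealPanel(("A",), (2007,), np.array([[4]]), np.array([[1.0]]))
        with pytest.raises(ValueError, match="2"):
            sp.dic(self.one_cell_draws([0.0]), panel)


class TestSummarize:
    def test_degenerate_coefficient_rr(self):
        spec = sp.ModelSpec("model1a", {"x": "linear"})
        S = 10
        draws = sp.PosteriorDraws(
            spec=spec, seed=0, area_ids=("A", "B"), periods=(2007, 2008),
            alpha=np.zeros(S), beta={"x": np.full(S, 0.008)},
            gamma=np.zeros(S), delta=np.zeros((S, 2)), u=np.zeros((S, 2)),
            v=np.zeros((S, 2)), f={}, phi=np.zeros((S, 2)), psi=np.zeros((S, 2)),
            tau={}, acceptance={}, rhat={})
        s = sp.summarize(draws)
        row = s.fixed.set_index("effect").loc["x"]
        rr = np.exp(0.008)          # prints as 1.008
        assert row["RR"] == pytest.approx(rr)
        assert row["ci_2.5"] == pytest.approx(rr)
        assert row["ci_97.5"] == pytest.approx(rr)
        assert round(row["RR"], 3) == 1.008
        # u=v=0 in all draws -> residual RR 1 everywhere
        np.testing.assert_allclose(s.area["rr_residual"], 1.0)

    def test_symmetric_draws_give_log_symmetric_ci(self):
        spec = sp.ModelSpec("model1a", {"x": "linear"})
        c = 0.1
        b = np.array([c, -c] * 50)
        draws = sp.PosteriorDraws(
            spec=spec, seed=0, area_ids=("A",), periods=(2007, 2008),
            alpha=np.zeros(100), beta={"x": b}, gamma=np.zeros(100),
            delta=np.zeros((100, 1)), u=np.zeros((100, 1)), v=np.zeros((100, 1)),
            f={}, phi=np.zeros((100, 2)), psi=np.zeros((100, 2)), tau={},
            acceptance={}, rhat={})
        row = sp.summarize(draws).fixed.set_index("effect").loc["x"]
        assert np.log(row["ci_2.5"]) == pytest.approx(-np.log(row["ci_97.5"]),
                                                      abs=1e-12)

    def test_ci_ordering_always_holds(self):
        d, _, _ = tiny_fit(seed=9)
        s = sp.summarize(d)
        assert (s.fixed["ci_2.5"] <= s.fixed["ci_97.5"]).all()
        assert (s.area["residual_ci_2.5"] <= s.area["residual_ci_97.5"]).all()


class TestSensitivity:
    def test_identical_priors_zero_shift(self):
        scen = sp.SimulationScenario(rows=4, cols=4, n_periods=3, seed=10)
        res = sp.simulate_counts(scen)
        spec = scen.model_spec("null_parametric")
        cfg = sp.MCMCConfig(n_iterations=150, n_burnin=50, seed=2)
        pr = sp.Hyperpriors()
        tab = sp.sensitivity_rerun(spec, res.panel, res.weights, [pr, pr], cfg)
        assert (tab["max_abs_logrr_shift"] == 0).all()

    def test_grid_of_one_rejected(self):
        scen = sp.SimulationScenario(rows=4, cols=4, n_periods=3, seed=10)
        res = sp.simulate_counts(scen)
        with pytest.raises(ValueError, match=">= 2"):
            sp.sensitivity_rerun(scen.model_spec("null_parametric"), res.panel,
                                 res.weights, [sp.Hyperpriors()],
                                 sp.MCMCConfig(n_iterations=100, n_burnin=10))


class TestDiagnostics:
    def test_split_rhat_near_one_for_iid(self):
        rng = np.random.default_rng(0)
        assert _split_rhat(rng.normal(size=4000)) == pytest.approx(1.0, abs=0.05)

    def test_split_rhat_detects_drift(self):
        x = np.concatenate([np.zeros(500), np.ones(500)])
        assert _split_rhat(x) > 1.5
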