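import numpy as np
import pytest

import steppm as sp
from steppm.model import time_index


def panel_2x3(**cov):
    return sp.ArealPanel(("A", "B"), (2008, 2009, 2010),
                         counts=np.array([[1, 2, 3], [4, 5, 6]]),
                         population=np.full((2, 3), 1e5), covariates=cov)


class TestModelSpec:
    def test_family_role_invariants(self):
        with pytest.raises(ValueError, match="no covariates"):
            sp.ModelSpec("null_parametric", {"x": "linear"})
        with pytest.raises(ValueError, match="linear"):
            sp.ModelSpec("model1a", {"x": "rw2"})
        with pytest.raises(ValueError, match="rw2"):
            sp.ModelSpec("model1b", {"x": "linear"})
        with pytest.raises(ValueError, match="unknown family"):
            sp.ModelSpec("model3", {})

    def test_trend_follows_family(self):
        assert sp.ModelSpec("model1a", {"x": "linear"}).trend == "linear_differential"
        assert sp.ModelSpec("model2", {"x": "linear"}).trend == "rw2_dynamic"

    def test_unknown_covariate_rejected_against_panel(self):
        spec = sp.ModelSpec("model1a", {"nope": "linear"})
        with pytest.raises(ValueError, match="nope"):
            spec.validate_against(panel_2x3(x=np.ones((2, 3))))


class TestExpectedCounts:
    def test_single_period_example(self):
        p = sp.ArealPanel(("A", "B"), (2007,), np.array([[10], [30]]),
                          np.array([[1e5], [3e5]]))
        np.testing.assert_allclose(sp.expected_counts(p), [[10], [30]])

    def test_conservation_and_population_invariance(self, small_sim):
        p = small_sim.panel
        E = sp.expected_counts(p)
        assert E.sum() == pytest.approx(p.counts.sum(), rel=1e-12)
        doubled = sp.ArealPanel(p.area_ids, p.periods, p.counts,
                                2 * p.population, p.covariates)
        np.testing.assert_allclose(sp.expected_counts(doubled), E, rtol=1e-12)

    def test_all_zero_counts_rejected(self):
        p = sp.ArealPanel(("A",), (2007,), np.array([[0]]), np.array([[1e5]]))
        with pytest.raises(ValueError, match="no events"):
            sp.expected_counts(p)


class TestLinearPredictor:
    def test_zero_state_gives_zero(self):
        p = panel_2x3(x=np.ones((2, 3)))
        spec = sp.ModelSpec("model1a", {"x": "linear"})
        st = sp.LatentState.zeros(spec, 2, 3)
        np.testing.assert_array_equal(sp.linear_predictor(spec, st, p), 0.0)

    def test_grand_slope_arithmetic(self):
        p = panel_2x3()
        spec = sp.ModelSpec("null_parametric", time_centering=2009)
        st = sp.LatentState.zeros(spec, 2, 3)
        st.gamma = 0.008
        eta = sp.linear_predictor(spec, st, p)
        np.testing.assert_allclose(eta[0], [-0.008, 0.0, 0.008], atol=1e-15)

    def test_coefficient_doubles_fitted_risk(self):
        p = panel_2x3(x=np.ones((2, 3)))
        spec = sp.ModelSpec("model1a", {"x": "linear"})
        st = sp.LatentState.zeros(spec, 2, 3)
        st.beta["x"] = np.log(2.0)
        np.testing.assert_allclose(np.exp(sp.linear_predictor(spec, st, p)), 2.0)

    def test_log_transform_applied(self):
        p = panel_2x3(dens=np.full((2, 3), np.e))
        spec = sp.ModelSpec("model1a", {"dens": "linear"},
                            log_covariates=frozenset({"dens"}))
        st = sp.LatentState.zeros(spec, 2, 3)
        st.beta["dens"] = 1.0
        np.testing.assert_allclose(sp.linear_predictor(spec, st, p), 1.0)

    def test_linearity_in_state(self):
        rng = np.random.default_rng(0)
        p = panel_2x3(x=rng.normal(size=(2, 3)))
        spec = sp.ModelSpec("model1a", {"x": "linear"})
        s1 = sp.LatentState.zeros(spec, 2, 3)
        s2 = sp.LatentState.zeros(spec, 2, 3)
        s1.alpha, s1.beta["x"], s1.u = 0.3, -0.2, rng.normal(size=2)
        s2.gamma, s2.v = 0.1, rng.normal(size=2)
        combined = sp.LatentState(alpha=s1.alpha + s2.alpha,
                                  beta={"x": s1.beta["x"] + s2.beta["x"]},
                                  gamma=s1.gamma + s2.gamma,
                                  delta=s1.delta + s2.delta, u=s1.u + s2.u,
                                  v=s1.v + s2.v, f={},
                                  phi=s1.phi + s2.phi, psi=s1.psi + s2.psi)
        np.testing.assert_allclose(
            sp.linear_predictor(spec, combined, p),
            sp.linear_predictor(spec, s1, p) + sp.linear_predictor(spec, s2, p),
            rtol=1e-12)

    def test_dynamic_trend_uses_period_effects(self):
        p = panel_2x3()
        spec = sp.ModelSpec("null_dynamic")
        st = sp.LatentState.zeros(spec, 2, 3)
        st.phi = np.array([0.1, 0.0, -0.1])
        st.psi = np.array([0.01, -0.02, 0.01])
        eta = sp.linear_predictor(spec, st, p)
        np.testing.assert_allclose(eta[1], st.phi + st.psi)

    def test_default_centering_is_middle_period(self):
        p = panel_2x3()
        spec = sp.ModelSpec("null_parametric")
        np.testing.assert_allclose(time_index(spec, p), [-1.0, 0.0, 1.0])


class TestBinning:
    def test_rw2_bins_partition_range(self, small_sim):
        spec = sp.ModelSpec("model1b", {"unemployment": "rw2"}, rw2_bins=10)
        binning = sp.CovariateBinning.from_panel(spec, small_sim.panel)
        x = small_sim.panel.covariates["unemployment"]
        idx = binning.bin_index("unemployment", x)
        assert idx.min() == 0 and idx.max() == 9

    def test_out_of_range_clamped_with_warning(self, small_sim):
        spec = sp.ModelSpec("model1b", {"unemployment": "rw2"}, rw2_bins=5)
        binning = sp.CovariateBinning.from_panel(spec, small_sim.panel)
        with pytest.warns(UserWarning, match="clamped"):
            idx = binning.bin_index("unemployment", np.array([1e9, -1e9]))
        assert list(idx) == [4, 0]


class TestPoissonLoglik:
    @pytest.mark.parametrize("y,expected", [(0.0, -1.0), (1.0, -1.0)])
    def test_unit_cell_values(self, y, expected):
        got = sp.poisson_loglik(np.array([[y]]), np.array([[1.0]]), np.array([[0.0]]))
        assert got == pytest.approx(expected)

    def test_additive_over_concatenated_panels(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(5.0, (4, 3)).astype(float)
        E = rng.uniform(1, 10, (4, 3))
        eta = rng.normal(0, 0.3, (4, 3))
        whole = sp.poisson_loglik(y, E, eta)
        parts = (sp.poisson_loglik(y[:2], E[:2], eta[:2])
                 + sp.poisson_loglik(y[2:], E[2:], eta[2:]))
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_concave_in_eta(self):
        y = np.array([[3.0]])
        E = np.array([[1.0]])
        h = 0.1
        vals = [sp.poisson_loglik(y, E, np.array([[e]])) for e in (-h, 0.0, h)]
        assert vals[0] + vals[2] - 2 * vals[1] < 0

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            sp.poisson_loglik(np.array([[1.0]]), np.array([[1.0]]),
                              np.array([[np.nan]]))
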