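import numpy as np
import pytest

import steppm as sp

from conftest import random_graph


def cycle_weights(n):
    nbrs = tuple(tuple(sorted(((i - 1) % n, (i + 1) % n))) for i in range(n))
    return sp.SpatialWeights(ids=tuple(range(n)), neighbors=nbrs,
                             weights=tuple(tuple(1.0 for _ in nb) for nb in nbrs),
                             style="binary", component_labels=(0,) * n)


class TestICAR:
    def test_two_node_path(self):
        _, w = sp.make_lattice(1, 2)
        s = sp.icar_structure(w)
        np.testing.assert_allclose(s.Q, [[1, -1], [-1, 1]])
        assert s.rank_deficiency == 1
        np.testing.assert_allclose(s.constraints, [[1, 1]])

    def test_row_sums_vanish_per_component(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            w = random_graph(30, 0.1, rng)
            s = sp.icar_structure(w)
            np.testing.assert_allclose(s.Q @ np.ones(30), 0, atol=1e-12)
            labels = np.asarray(w.component_labels)
            for c in set(w.component_labels):
                ind = (labels == c).astype(float)
                np.testing.assert_allclose(s.Q @ ind, 0, atol=1e-12)

    def test_disconnected_edges_have_two_constraints(self):
        w = sp.SpatialWeights(ids=("a", "b", "c", "d"),
                              neighbors=((1,), (0,), (3,), (2,)),
                              weights=((1.0,), (1.0,), (1.0,), (1.0,)),
                              style="binary", component_labels=(0, 0, 1, 1))
        s = sp.icar_structure(w)
        assert s.rank_deficiency == 2
        assert s.constraints.shape == (2, 4)

    def test_quadratic_form_equals_pairwise_sum(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            w = random_graph(25, 0.15, rng)
            s = sp.icar_structure(w)
            x = rng.normal(size=25)
            pairwise = sum((x[i] - x[j]) ** 2
                           for i, nbrs in enumerate(w.neighbors)
                           for j in nbrs if j > i)
            assert s.quad_form(x) == pytest.approx(pairwise, rel=1e-12)

    def test_island_gets_zero_diagonal_and_point_constraint(self):
        w = sp.SpatialWeights(ids=("a", "b", "c"),
                              neighbors=((1,), (0,), ()),
                              weights=((1.0,), (1.0,), ()),
                              style="binary", islands=frozenset({2}),
                              component_labels=(0, 0, 1))
        s = sp.icar_structure(w)
        assert s.Q[2, 2] == 0
        assert s.rank_deficiency == 2
        # the island's constraint row is the point constraint x_island = 0
        island_rows = [r for r in s.constraints if r[2] == 1 and r[:2].sum() == 0]
        assert len(island_rows) == 1


class TestRW2:
    def test_m3_matrix(self):
        s = sp.rw2_structure(3)
        np.testing.assert_allclose(s.Q, [[1, -2, 1], [-2, 4, -2], [1, -2, 1]])
        assert s.rank_deficiency == 2

    @pytest.mark.parametrize("m", [3, 5, 12])
    def test_null_space_constant_and_linear(self, m):
        s = sp.rw2_structure(m)
        np.testing.assert_allclose(s.Q @ np.ones(m), 0, atol=1e-10)
        np.testing.assert_allclose(s.Q @ np.arange(1.0, m + 1), 0, atol=1e-10)

    def test_interior_stencil(self):
        s = sp.rw2_structure(5)
        np.testing.assert_allclose(s.Q[2], [1, -4, 6, -4, 1])

    def test_quadratic_form_is_sum_of_second_differences(self):
        rng = np.random.default_rng(2)
        m = 9
        s = sp.rw2_structure(m)
        x = rng.normal(size=m)
        expected = np.sum((x[:-2] - 2 * x[1:-1] + x[2:]) ** 2)
        assert s.quad_form(x) == pytest.approx(expected, rel=1e-12)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            sp.rw2_structure(2)


class TestScaling:
    def test_idempotent(self):
        s = sp.scale_structure(sp.rw2_structure(20))
        s2 = sp.scale_structure(s)
        np.testing.assert_allclose(s2.Q, s.Q, rtol=1e-10)
        assert s2.scale_factor == pytest.approx(s.scale_factor, rel=1e-9)

    def test_iid_unchanged(self):
        s = sp.scale_structure(sp.iid_structure(5))
        np.testing.assert_allclose(s.Q, np.eye(5))
        assert s.scale_factor == 1.0

    def test_cycle_geometric_mean_is_one(self):
        # independent eigendecomposition oracle for the 4-cycle ICAR
        s0 = sp.icar_structure(cycle_weights(4))
        s = sp.scale_structure(s0)
        lam, V = np.linalg.eigh(s.Q)
        keep = lam > 1e-9
        var = (V[:, keep] ** 2 / lam[keep]).sum(axis=1)
        gm = np.exp(np.mean(np.log(var)))
        assert gm == pytest.approx(1.0, abs=1e-6)

    def test_scale_factor_matches_oracle(self):
        s0 = sp.icar_structure(cycle_weights(4))
        lam, V = np.linalg.eigh(s0.Q)
        keep = lam > 1e-9
        var = (V[:, keep] ** 2 / lam[keep]).sum(axis=1)
        expected = np.exp(np.mean(np.log(var)))
        s = sp.scale_structure(s0)
        assert s.scale_factor == pytest.approx(expected, rel=1e-9)


class TestSampling:
    def test_constraints_hold(self):
        s = sp.scale_structure(sp.icar_structure(cycle_weights(6)))
        x = sp.sample_constrained(s, tau=2.0, seed=0)
        assert abs(x.sum()) < 1e-10

    def test_rw2_draw_orthogonal_to_null_space(self):
        s = sp.scale_structure(sp.rw2_structure(15))
        x = sp.sample_constrained(s, tau=1.0, seed=3)
        assert abs(x.sum()) < 1e-10
        assert abs(x @ np.arange(15.0)) < 1e-8

    def test_deterministic_given_seed(self):
        s = sp.rw2_structure(10)
        np.testing.assert_array_equal(sp.sample_constrained(s, 1.0, seed=5),
                                      sp.sample_constrained(s, 1.0, seed=5))

    def test_invalid_precision_rejected(self):
        with pytest.raises(ValueError):
            sp.sample_constrained(sp.iid_structure(3), tau=0.0, seed=0)

    def test_monte_carlo_covariance_matches_generalized_inverse(self):
        # 4-cycle ICAR: empirical covariance of many draws vs the
        # eigendecomposition pseudo-inverse, within 5% on leading entries
        s = sp.icar_structure(cycle_weights(4))
        tau = 2.0
        rng = np.random.default_rng(17)
        draws = np.stack([sp.sample_constrained(s, tau, rng) for _ in range(10_000)])
        emp = np.cov(draws.T)
        lam, V = np.linalg.eigh(s.Q)
        keep = lam > 1e-9
        Sigma = (V[:, keep] / lam[keep]) @ V[:, keep].T / tau
        big = np.abs(Sigma) > 0.05
        np.testing.assert_allclose(emp[big], Sigma[big], rtol=0.05)


class TestSemiDefiniteness:
    @pytest.mark.parametrize("maker", [lambda: sp.rw2_structure(8),
                                       lambda: sp.iid_structure(6)])
    def test_nonnegative_quadratic_form(self, maker):
        rng = np.random.default_rng(4)
        s = maker()
        for _ in range(20):
            x = rng.normal(size=s.m)
            assert s.quad_form(x) >= -1e-10

    def test_declared_deficiency_checked(self):
        s = sp.GMRFStructure(Q=np.eye(3), rank_deficiency=1,
                             constraints=np.zeros((0, 3)), kind="iid")
        with pytest.raises(ValueError, match="rank deficiency"):
            s.marginal_variances()
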