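"""Copula transform, Gaussian information quantities and graph metrics."""

import itertools

import numpy as np
import pytest
from scipy import stats

import neurodyn as nd
from neurodyn.connectivity import (MI_MAX, copula_transform, mi_matrix,
                                   cmi_matrix, o_information,
                                   o_information_matrix, graph_metrics,
                                   connectivity_graph, _global_efficiency)


class TestCopulaTransform:
    def test_output_margins_standard_normal(self, rng):
        z = copula_transform(rng.exponential(size=(3, 1000)))
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=0.01)
        np.testing.assert_allclose(z.var(axis=1), 1.0, atol=0.01)

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal((1, 500))
        np.testing.assert_array_equal(copula_transform(x),
                                      copula_transform(np.exp(x)))

    def test_ks_against_standard_normal(self, rng):
        z = copula_transform(rng.uniform(size=(1, 1000)))[0]
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError):
            copula_transform(np.tile([1.0, 2.0], (1, 50)))

    def test_heavy_ties_warn(self, rng):
        x = rng.standard_normal(400)
        x[:300] = np.round(x[:300] * 2) / 2  # many duplicates
        with pytest.warns(UserWarning, match="heavy ties"):
            copula_transform(x[None, :])


class TestMiMatrix:
    def test_closed_form_at_rho_grid(self, rng):
        n = 4096
        for rho in (0.0, 0.3, 0.6, 0.9):
            x = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
            w = mi_matrix(copula_transform(np.vstack([x, y])))
            assert w[0, 1] == pytest.approx(-0.5 * np.log1p(-rho ** 2), abs=0.02)

    def test_independent_rows_near_zero(self, rng):
        w = mi_matrix(copula_transform(rng.standard_normal((2, 4096))))
        assert w[0, 1] < 0.01

    def test_duplicated_row_capped(self, rng):
        x = rng.standard_normal(256)
        w = mi_matrix(copula_transform(np.vstack([x, x])))
        assert w[0, 1] == pytest.approx(MI_MAX)

    def test_symmetry_zero_diagonal(self, rng):
        w = mi_matrix(copula_transform(rng.standard_normal((5, 512))))
        np.testing.assert_allclose(w, w.T)
        assert np.all(np.diag(w) == 0) and np.all(w >= 0)


class TestCmiMatrix:
    def test_gaussian_chain_conditional_independence(self, rng):
        n = 8192
        a = rng.standard_normal(n)
        b = 0.8 * a + 0.6 * rng.standard_normal(n)
        c = 0.8 * b + 0.6 * rng.standard_normal(n)
        w = cmi_matrix(copula_transform(np.vstack([a, b, c])))
        assert w[0, 2] < 0.01          # X indep Z given Y
        assert w[0, 1] > 0.1 and w[1, 2] > 0.1

    def test_two_rois_equals_mi(self, rng):
        z = copula_transform(rng.standard_normal((2, 1024)))
        np.testing.assert_array_equal(cmi_matrix(z), mi_matrix(z))

    def test_independent_rois_near_zero(self, rng):
        w = cmi_matrix(copula_transform(rng.standard_normal((4, 8192))))
        assert w[np.triu_indices(4, 1)].max() < 0.01

    def test_sample_size_precondition(self, rng):
        with pytest.raises(ValueError):
            cmi_matrix(rng.standard_normal((10, 40)))


class TestOInformation:
    def test_independent_triplet_near_zero(self, rng):
        z = copula_transform(rng.standard_normal((3, 8192)))
        assert abs(o_information(z)) < 0.01

    def test_redundant_triplet_positive(self, rng):
        lat = rng.standard_normal(8192)
        x = np.vstack([0.9 * lat + np.sqrt(1 - 0.81) * rng.standard_normal(8192)
                       for _ in range(3)])
        assert o_information(copula_transform(x)) > 0

    def test_analytic_correlation_matrix(self):
        """Closed-form check: Omega from log-determinants of an explicit
        trivariate correlation matrix."""
        r = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])
        def h(m):
            return 0.5 * (m.shape[0] * np.log(2 * np.pi * np.e)
                          + np.linalg.slogdet(m)[1])
        h1 = 0.5 * np.log(2 * np.pi * np.e)
        expected = 1.0 * h(r)
        for i in range(3):
            rest = [j for j in range(3) if j != i]
            expected += h1 - h(r[np.ix_(rest, rest)])
        assert o_information(r, is_correlation=True) == pytest.approx(
            expected, abs=1e-9)

    def test_subset_size_validation(self, rng):
        with pytest.raises(ValueError):
            o_information(rng.standard_normal((2, 100)))

    def test_edge_matrix_triplet_average(self, rng):
        z = copula_transform(rng.standard_normal((4, 2048)))
        total, edge = o_information_matrix(z)
        corr = np.corrcoef(z)
        # entry (0,1) = mean over triplets {0,1,2} and {0,1,3}
        o012 = o_information(corr[np.ix_([0, 1, 2], [0, 1, 2])], is_correlation=True)
        o013 = o_information(corr[np.ix_([0, 1, 3], [0, 1, 3])], is_correlation=True)
        assert edge[0, 1] == pytest.approx((o012 + o013) / 2, abs=1e-12)
        assert total == pytest.approx(
            o_information(corr, is_correlation=True), abs=1e-12)


class TestGraphMetrics:
    def test_complete_triangle(self):
        w = np.ones((3, 3)) - np.eye(3)
        gm = graph_metrics(w, seed=0)
        assert gm.global_efficiency == pytest.approx(1.0)
        assert gm.transitivity == pytest.approx(1.0)
        assert gm.density == pytest.approx(1.0)

    def test_three_node_path_efficiency(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        gm = graph_metrics(w, seed=0)
        assert gm.global_efficiency == pytest.approx((1 + 1 + 0.5) / 3)

    def test_efficiency_matches_brute_force_small_graphs(self, rng):
        """Dijkstra efficiency equals exhaustive path enumeration on all
        random weighted graphs with <= 6 nodes."""
        for n in (3, 4, 5, 6):
            for _ in range(3):
                w = rng.uniform(0.1, 1.0, (n, n))
                w = (w + w.T) / 2
                np.fill_diagonal(w, 0)
                w /= w.max()
                # brute force: min path length over all simple paths
                nodes = range(n)
                eff = 0.0
                for i, j in itertools.combinations(nodes, 2):
                    best = np.inf
                    for k in range(0, n - 1):
                        for mid in itertools.permutations(
                                [m for m in nodes if m not in (i, j)], k):
                            path = (i, *mid, j)
                            d = sum(1.0 / w[a, b] for a, b in zip(path, path[1:]))
                            best = min(best, d)
                    eff += 1.0 / best
                eff /= n * (n - 1) / 2
                assert _global_efficiency(w) == pytest.approx(eff, abs=1e-9)

    def test_small_world_lattice_vs_random(self, rng):
        import networkx as nx
        ws = nx.connected_watts_strogatz_graph(30, 4, 0.1, seed=4)
        w_ws = nx.to_numpy_array(ws)
        sigma_ws = graph_metrics(w_ws, seed=1).small_worldness
        er = nx.gnm_random_graph(30, ws.number_of_edges(), seed=5)
        w_er = nx.to_numpy_array(er)
        sigma_er = graph_metrics(w_er, seed=1).small_worldness
        assert sigma_ws > 1.0
        assert sigma_er == pytest.approx(1.0, abs=0.3)

    def test_all_zero_matrix_degenerate(self):
        with pytest.raises(ValueError):
            graph_metrics(np.zeros((4, 4)))

    def test_validation(self):
        with pytest.raises(ValueError):
            graph_metrics(np.array([[0, 1], [2, 0]], float))  # asymmetric
        with pytest.raises(ValueError):
            graph_metrics(np.array([[0, -1], [-1, 0]], float))


class TestPermutationEquivariance:
    def test_all_outputs_relabel_consistently(self, rng):
        data = rng.standard_normal((5, 600))
        perm = [3, 1, 4, 0, 2]
        z = copula_transform(data)
        zp = copula_transform(data[perm])
        for fn in (mi_matrix, cmi_matrix):
            w, wp = fn(z), fn(zp)
            np.testing.assert_allclose(wp, w[np.ix_(perm, perm)], atol=1e-10)
        t, e = o_information_matrix(z)
        tp, ep = o_information_matrix(zp)
        assert tp == pytest.approx(t, abs=1e-10)
        np.testing.assert_allclose(ep, e[np.ix_(perm, perm)], atol=1e-10)


class TestConnectivityGraph:
    def test_stack_on_synthetic_recording(self, standardized_recording):
        rec = standardized_recording
        cg = connectivity_graph(rec.data, rec.labels)
        assert cg.w_mi.shape == (10, 10)
        assert np.all(cg.w_cmi >= 0) and np.all(cg.w_oinfo >= 0)
        # ring-coupled generator: neighbours carry direct links
        gm = graph_metrics(cg.w_cmi, seed=0)
        assert 0 < gm.global_efficiency <= 1
        assert 0 <= gm.density <= 1
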