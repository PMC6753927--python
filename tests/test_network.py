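import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from biofilmnet.config import AnalysisConfig
from biofilmnet.network import (build_network, characteristic_path_length,
                                clustering_coefficient, correlation_pvalue,
                                network_density, network_heterogeneity,
                                permutation_pvalue, pvalue_matrix,
                                spearman_matrix, topology_summary)
from tests.oracles import (oracle_clustering, oracle_cpl, oracle_density,
                           oracle_heterogeneity)
from tests.test_preprocess import table_from


class TestSpearmanMatrix:
    def test_monotone_and_reversed(self):
        t = table_from([[1, 2, 3, 4], [10, 20, 25, 30], [8, 6, 4, 2]])
        rho = spearman_matrix(t)
        assert rho.loc["o0", "o1"] == pytest.approx(1.0)
        assert rho.loc["o0", "o2"] == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self, rng):
        # independent midrank oracle: Pearson of scipy average ranks
        x = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 4.0])
        y = np.array([5.0, 5.0, 7.0, 6.0, 9.0, 9.0])
        rho = spearman_matrix(table_from(np.vstack([x, y])))
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho.loc["o0", "o1"] == pytest.approx(expected)
        # and against scipy's own implementation
        assert rho.loc["o0", "o1"] == pytest.approx(stats.spearmanr(x, y)[0])

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.uniform(0.1, 5.0, (3, 8))
        rho1 = spearman_matrix(table_from(x)).to_numpy()
        rho2 = spearman_matrix(table_from(np.exp(2 * x))).to_numpy()
        np.testing.assert_allclose(rho1, rho2, atol=1e-12)

    def test_constant_otu_is_nan_with_warning(self):
        t = table_from([[1, 1, 1, 1], [1, 2, 3, 4]])
        with pytest.warns(UserWarning, match="constant"):
            rho = spearman_matrix(t)
        assert np.isnan(rho.loc["o0", "o1"])

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="4 samples"):
            spearman_matrix(table_from([[1, 2, 3], [3, 2, 1]]))


class TestCorrelationPvalue:
    def test_null_center(self):
        assert correlation_pvalue(0.0, 11) == pytest.approx(1.0)

    def test_perfect_correlation(self):
        assert correlation_pvalue(1.0, 8) == 0.0
        assert correlation_pvalue(-1.0, 8) == 0.0

    def test_exact_enumeration_n5(self, rng):
        # full 120-permutation enumeration, checked against an in-test oracle
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        p = permutation_pvalue(x, y)
        obs = abs(stats.spearmanr(x, y)[0])
        count = sum(
            abs(stats.spearmanr(x, np.array(y)[list(perm)])[0]) >= obs - 1e-12
            for perm in itertools.permutations(range(5)))
        assert p == pytest.approx(count / 120)

    def test_t_approx_agrees_with_sampled_permutation(self):
        # n = 11, rho = 0.75: significant at 0.01 and consistent with a
        # large sampled permutation null
        rng = np.random.default_rng(7)
        x = np.arange(11.0)
        # construct y with spearman rho close to 0.75
        y = x + rng.normal(0, 3.2, 11)
        rho = stats.spearmanr(x, y)[0]
        p_t = correlation_pvalue(rho, 11)
        p_perm = permutation_pvalue(x, y, n_perm=100_000, seed=1)
        se = np.sqrt(p_perm * (1 - p_perm) / 100_000)
        assert abs(p_t - p_perm) < 4 * se + 0.003

    def test_pvalue_matrix_t_matches_scalar(self, rng):
        t = table_from(rng.uniform(0, 10, (4, 9)))
        rho = spearman_matrix(t)
        p = pvalue_matrix(t, rho=rho)
        for i, j in itertools.combinations(range(4), 2):
            assert p.iloc[i, j] == pytest.approx(
                correlation_pvalue(rho.iloc[i, j], 9))


class TestBuildNetwork:
    def grid(self, entries):
        ids = sorted({a for a, *_ in entries} | {b for _, b, *_ in entries})
        rho = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
        p = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
        for a, b, r, pv in entries:
            rho.loc[a, b] = rho.loc[b, a] = r
            p.loc[a, b] = p.loc[b, a] = pv
        return rho, p

    def test_thresholds_are_strict(self):
        rho, p = self.grid([("a", "b", 0.7, 0.001),    # rho not > 0.7
                            ("c", "d", 0.9, 0.02),     # p not < 0.01
                            ("a", "c", 0.71, 0.009)])  # passes both
        net = build_network(rho, p)
        assert set(map(frozenset, net.edges)) == {frozenset(("a", "c"))}
        # isolated nodes are excluded entirely
        assert set(net.nodes) == {"a", "c"}

    def test_hand_enumerated_grid(self):
        entries = [("a", "b", 0.95, 1e-5), ("a", "c", -0.8, 0.005),
                   ("a", "d", 0.75, 0.5), ("b", "c", 0.2, 0.6),
                   ("b", "d", -0.9, 0.009), ("c", "d", 0.69, 1e-6)]
        rho, p = self.grid(entries)
        net = build_network(rho, p)
        expected = {frozenset(e[:2]) for e in entries
                    if abs(e[2]) > 0.7 and e[3] < 0.01}
        assert set(map(frozenset, net.edges)) == expected
        assert net["a"]["c"]["sign"] == "negative"
        assert net["a"]["b"]["sign"] == "positive"

    def test_monotone_in_thresholds(self, rng):
        t = table_from(rng.uniform(0, 10, (8, 7)))
        rho = spearman_matrix(t)
        p = pvalue_matrix(t, rho=rho)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            loose = build_network(rho, p, AnalysisConfig(
                rho_threshold=0.5, p_threshold=0.2))
            tight = build_network(rho, p, AnalysisConfig(
                rho_threshold=0.7, p_threshold=0.05))
        assert set(map(frozenset, tight.edges)) <= set(map(frozenset, loose.edges))

    def test_empty_result_warns(self):
        rho, p = self.grid([("a", "b", 0.1, 0.9)])
        with pytest.warns(UserWarning, match="no edge"):
            net = build_network(rho, p)
        assert net.number_of_edges() == 0


class TestTopologyMetrics:
    def test_clustering_closed_forms(self):
        assert clustering_coefficient(nx.complete_graph(3)) == 1.0
        assert clustering_coefficient(nx.star_graph(3)) == 0.0
        k4_minus = nx.complete_graph(4)
        k4_minus.remove_edge(0, 1)
        assert clustering_coefficient(k4_minus) == pytest.approx(5 / 6)

    def test_cpl_closed_forms(self):
        assert characteristic_path_length(nx.complete_graph(3)) == 1.0
        assert characteristic_path_length(nx.path_graph(3)) == 1.5
        two_k3 = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        assert characteristic_path_length(two_k3) == 1.0

    def test_cpl_all_isolated_is_error(self):
        g = nx.empty_graph(3)
        with pytest.raises(ValueError, match="isolated"):
            characteristic_path_length(g)

    def test_density(self):
        assert network_density(nx.complete_graph(3)) == 1.0
        g = nx.gnm_random_graph(10, 13, seed=1)
        assert network_density(g) == pytest.approx(2 * 13 / (10 * 9))

    def test_heterogeneity_closed_forms(self):
        assert network_heterogeneity(nx.cycle_graph(6)) == 0.0
        assert network_heterogeneity(nx.star_graph(4)) == pytest.approx(0.75)

    def test_heterogeneity_leaf_edge_does_not_increase(self):
        star = nx.star_graph(4)
        before = network_heterogeneity(star)
        star.add_edge(1, 2)  # connect two minimum-degree leaves
        assert network_heterogeneity(star) <= before

    def test_metrics_match_bruteforce_on_random_graphs(self, rng):
        # 40 random graphs here; the full 200-graph sweep runs in the
        # acceptance suite
        for k in range(40):
            n = int(rng.integers(4, 13))
            m = int(rng.integers(1, n * (n - 1) // 2 + 1))
            g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
            nodes, edges = list(g.nodes), list(g.edges)
            assert clustering_coefficient(g) == pytest.approx(
                oracle_clustering(nodes, edges))
            assert network_density(g) == pytest.approx(
                oracle_density(nodes, edges))
            if any(d for _, d in g.degree()):
                assert network_heterogeneity(g) == pytest.approx(
                    oracle_heterogeneity(nodes, edges))
                if sum(1 for _, d in g.degree() if d == 0) < n:
                    assert characteristic_path_length(g) == pytest.approx(
                        oracle_cpl(nodes, edges))

    def test_summary_two_k3s_hand_check(self):
        from biofilmnet.modules import detect_modules
        g = nx.Graph()
        for base in (0, 3):
            for i, j in itertools.combinations(range(base, base + 3), 2):
                g.add_edge(f"n{i}", f"n{j}", rho=0.9, p=0.001, sign="positive")
        part = detect_modules(g)
        ts = topology_summary(g, part)
        assert ts.n_nodes == 6
        assert ts.n_edges_total == 6 == ts.n_edges_positive
        assert ts.clustering_coefficient == 1.0
        assert ts.characteristic_path_length == 1.0
        assert ts.density == pytest.approx(6 / 15)
        assert ts.heterogeneity == 0.0
        assert ts.modularity == pytest.approx(0.5)

    def test_summary_empty_network(self):
        ts = topology_summary(nx.Graph())
        assert ts.n_nodes == 0 and ts.n_edges_total == 0
        assert ts.clustering_coefficient is None
        assert ts.density is None
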