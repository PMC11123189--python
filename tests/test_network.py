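import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import soilroot as sr


def rank_then_pearson(x, y):
    """Independent Spearman oracle: mid-rank ties, then Pearson."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_matches_rank_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(21)
        X = rng.integers(0, 6, size=(12, 8)).astype(float)  # heavy ties
        rho, _ = sr.spearman_matrix(pd.DataFrame(X, columns=list("abcdefgh")))
        for i, j in itertools.combinations(range(8), 2):
            assert rho.iloc[i, j] == pytest.approx(
                rank_then_pearson(X[:, i], X[:, j]), abs=1e-12
            )

    def test_too_few_samples_rejected(self):
        with pytest.raises(sr.ValidationError):
            sr.spearman_matrix(pd.DataFrame(np.eye(3)))


class TestBuildNetwork:
    def test_concordant_pair_connected_no_self_loops(self):
        rng = np.random.default_rng(22)
        base = np.sort(rng.uniform(size=8))
        X = pd.DataFrame({"t1": base, "t2": base * 2 + 1, "t3": rng.uniform(size=8)})
        net = sr.build_network(X, r_threshold=0.6, p_threshold=0.05, prevalence_min=0)
        assert net.has_edge("t1", "t2")
        assert net.edges["t1", "t2"]["rho"] == pytest.approx(1.0)
        assert not any(u == v for u, v in net.edges)

    def test_null_retention_rate_bounded(self):
        # independent taxa: essentially nothing should pass |rho|>0.6, q<0.01
        retained = total = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.uniform(size=(10, 21)))
            X.columns = [f"t{i}" for i in range(21)]
            net = sr.build_network(X, prevalence_min=0, drop_isolated=False)
            retained += net.number_of_edges()
            total += 21 * 20 // 2
        assert retained / total <= 0.01

    def test_sample_order_invariance(self, gradient_ra):
        ra, md, _ = gradient_ra
        members = sr.flow.resolve_group(md, "rhizosphere:XLZ61")
        X = ra.data.loc[members].iloc[:, :60]
        a = sr.build_network(X, p_threshold=0.05)
        b = sr.build_network(X.iloc[::-1], p_threshold=0.05)
        assert set(a.edges) == set(b.edges)


class TestNodeTopology:
    def test_star_graph(self):
        g = nx.star_graph(4)  # centre 0, leaves 1..4
        t = sr.node_topology(g)
        assert t.loc[0, "degree"] == 4
        assert t.loc[1, "degree"] == 1
        assert t.loc[0, "betweenness"] == pytest.approx(1.0)
        assert t.loc[1, "betweenness"] == 0.0

    def test_complete_graph_no_intermediaries(self):
        t = sr.node_topology(nx.complete_graph(4))
        assert (t["betweenness"] == 0).all()
        assert (t["clustering"] == 1.0).all()

    def test_path_centre_closest(self):
        t = sr.node_topology(nx.path_graph(3))  # a-b-c
        assert t.loc[1, "closeness"] > t.loc[0, "closeness"]

    def test_eigenvector_restricted_to_giant_component(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y")])
        t = sr.node_topology(g)
        assert t.loc["a", "eigenvector"] > 0
        assert t.loc["x", "eigenvector"] == 0.0


def brute_force_modularity(g: nx.Graph) -> float:
    """Best modularity over all bipartitions, computed from first principles."""
    nodes = list(g.nodes)
    m = g.number_of_edges()
    deg = dict(g.degree())
    best = -1.0
    for mask in range(2 ** (len(nodes) - 1)):
        side = [(mask >> i) & 1 for i in range(len(nodes) - 1)] + [0]
        comms = [
            {n for n, s in zip(nodes, side) if s == 0},
            {n for n, s in zip(nodes, side) if s == 1},
        ]
        q = 0.0
        for c in comms:
            if not c:
                continue
            lc = sum(1 for u, v in g.edges if u in c and v in c)
            dc = sum(deg[n] for n in c)
            q += lc / m - (dc / (2 * m)) ** 2
        best = max(best, q)
    return best


class TestNetworkTopology:
    def test_complete_graph_closed_forms(self):
        m = sr.network_topology(nx.complete_graph(4))
        assert m["edge_density"] == 1.0
        assert m["average_degree"] == 3.0
        assert m["average_clustering"] == 1.0
        assert m["diameter"] == 1

    def test_path_graph_enumeration(self):
        m = sr.network_topology(nx.path_graph(4))
        assert m["diameter"] == 3
        assert m["average_path_length"] == pytest.approx(10 / 6)

    def test_modularity_two_triangles_vs_exhaustive(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        m = sr.network_topology(g)
        assert m["modularity"] == pytest.approx(brute_force_modularity(g), abs=1e-12)
        assert m["modularity"] == pytest.approx(0.5)
        assert m["n_communities"] == 2

    def test_centralizations_star_vs_complete(self):
        star = sr.network_topology(nx.star_graph(5))
        comp = sr.network_topology(nx.complete_graph(6))
        assert star["degree_centralization"] == pytest.approx(1.0)
        assert comp["degree_centralization"] == 0.0
        assert 0 <= star["betweenness_centralization"] <= 1


class TestNaturalConnectivity:
    def test_edgeless_graph_zero(self):
        g = nx.empty_graph(7)
        assert sr.natural_connectivity(g) == pytest.approx(0.0, abs=1e-12)

    def test_triangle_closed_form(self):
        nc = sr.natural_connectivity(nx.complete_graph(3))
        expected = math.log((math.e ** 2 + 2 / math.e) / 3)
        assert nc == pytest.approx(expected, abs=1e-9)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1e6)))
            A = nx.to_numpy_array(g)
            lam = np.linalg.eigvalsh(A)
            oracle = math.log(np.exp(lam).mean())
            assert sr.natural_connectivity(g) == pytest.approx(oracle, abs=1e-9)

    def test_adding_edges_never_decreases(self):
        rng = np.random.default_rng(24)
        for _ in range(5):
            g = nx.gnp_random_graph(10, 0.25, seed=int(rng.integers(1e6)))
            nc0 = sr.natural_connectivity(g)
            non_edges = list(nx.non_edges(g))
            if not non_edges:
                continue
            u, v = non_edges[rng.integers(len(non_edges))]
            g.add_edge(u, v)
            assert sr.natural_connectivity(g) >= nc0 - 1e-12


class TestRobustness:
    def test_zero_fraction_identity(self):
        g = nx.complete_graph(5)
        curve = sr.robustness_curve(g, "random", fractions=[0.0], n_repeats=3, seed=0)
        assert curve.table.loc[0, "natural_connectivity"] == pytest.approx(
            sr.natural_connectivity(g)
        )

    def test_k5_random_removal_decreasing(self):
        g = nx.complete_graph(5)
        curve = sr.robustness_curve(
            g, "random", fractions=[0.0, 0.2, 0.4], n_repeats=50, seed=1
        )
        nc = curve.table["natural_connectivity"].to_numpy()
        assert np.all(np.diff(nc) < 0)

    def test_targeted_beats_random_on_star(self):
        g = nx.star_graph(9)  # hub + 9 leaves
        targeted = sr.robustness_curve(g, "degree", fractions=[0.2], seed=2)
        random = sr.robustness_curve(g, "random", fractions=[0.2], n_repeats=100, seed=2)
        assert (
            targeted.table.loc[0, "natural_connectivity"]
            < random.table.loc[0, "natural_connectivity"]
        )

    def test_truncation_flag(self):
        g = nx.complete_graph(4)
        curve = sr.robustness_curve(g, "degree", fractions=[0.0, 0.3, 0.6, 0.9])
        assert curve.truncated
        assert curve.table["fraction"].max() < 0.9
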