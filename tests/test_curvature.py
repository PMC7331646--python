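import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braincurv import (
    CurvatureError,
    all_edge_curvatures,
    compute_graph_metric,
    curvature_tables,
    edge_curvature,
    node_measure,
    scalar_curvature,
    wasserstein1,
)
from conftest import (
    complete_network,
    make_network,
    path_network,
    random_connected_network,
)
from oracles import (
    exact_node_measure,
    mcf_wasserstein1,
    oracle_edge_curvature,
    polytope_vertex_w1,
)


class TestGraphMetric:
    def test_hop_counts_edges(self):
        net = path_network(3)
        metric = compute_graph_metric(net, "hop")
        assert metric.distances[0, 2] == 2.0
        assert metric.distances[0, 1] == 1.0

    def test_single_edge_distance_one_regardless_of_weight(self):
        net = make_network([[0, 7.3], [7.3, 0]])
        assert compute_graph_metric(net, "hop").distances[0, 1] == 1.0

    def test_matches_bfs_oracle(self, rng):
        net = random_connected_network(rng, 10, p=0.35)
        metric = compute_graph_metric(net, "hop")
        graph = nx.from_numpy_array(net.weights)
        for a, lengths in nx.all_pairs_shortest_path_length(graph):
            for b, d in lengths.items():
                assert metric.distances[a, b] == d

    def test_weighted_mode_matches_dijkstra_on_inverse_weights(self, rng):
        net = random_connected_network(rng, 8, p=0.4)
        metric = compute_graph_metric(net, "weighted")
        graph = nx.Graph()
        for i, j in net.edges():
            graph.add_edge(i, j, length=1.0 / net.weights[i, j])
        expect = dict(nx.all_pairs_dijkstra_path_length(graph, weight="length"))
        for a in range(net.n_nodes):
            for b in range(net.n_nodes):
                assert metric.distances[a, b] == pytest.approx(
                    expect[a][b], abs=1e-12
                )

    def test_unreachable_flagged_and_triangle_inequality(self, rng):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0  # node 4 isolated, two components
        metric = compute_graph_metric(make_network(w), "hop")
        assert not metric.is_reachable(0, 2)
        assert metric.is_reachable(0, 1)
        net = random_connected_network(rng, 9, p=0.4)
        d = compute_graph_metric(net, "hop").distances
        for _ in range(200):
            a, b, c = rng.integers(0, 9, size=3)
            assert d[a, c] <= d[a, b] + d[b, c]
        assert np.array_equal(d, d.T)
        assert np.all(np.diag(d) == 0)


class TestNodeMeasure:
    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=1e4, allow_nan=False),
            min_size=1,
            max_size=8,
        )
    )
    def test_measure_normalized_for_arbitrary_positive_weights(self, weights):
        n = len(weights) + 1
        w = np.zeros((n, n))
        w[0, 1:] = weights
        w[1:, 0] = weights
        mu = node_measure(make_network(w), 0)
        assert abs(mu.masses.sum() - 1.0) < 1e-12
        assert mu.weighted_degree == pytest.approx(sum(weights), rel=1e-12)

    def test_masses_proportional_to_weights(self):
        net = make_network([[0, 2, 6], [2, 0, 0], [6, 0, 0]])
        mu = node_measure(net, 0)
        assert mu.weighted_degree == 8.0
        assert dict(zip(mu.support.tolist(), mu.masses)) == {1: 0.25, 2: 0.75}

    def test_single_neighbor_is_point_mass(self):
        net = make_network([[0, 5], [5, 0]])
        mu = node_measure(net, 1)
        assert mu.support.tolist() == [0] and mu.masses[0] == 1.0

    def test_isolated_node_error(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        with pytest.raises(CurvatureError, match="isolated"):
            node_measure(make_network(w), 2)

    def test_masses_sum_to_one(self, rng):
        for _ in range(20):
            net = random_connected_network(rng, 7, p=0.5)
            for x in range(net.n_nodes):
                mu = node_measure(net, x)
                assert abs(mu.masses.sum() - 1.0) < 1e-12
                assert mu.base_node not in mu.support
                assert (mu.masses > 0).all()


class TestWasserstein1:
    def test_identical_measures_cost_zero(self, k3):
        metric = compute_graph_metric(k3)
        mu = node_measure(k3, 0)
        assert wasserstein1(mu, mu, metric).cost == pytest.approx(0.0, abs=1e-12)

    def test_point_masses_cost_ground_distance(self):
        net = path_network(4)
        metric = compute_graph_metric(net)
        mu = node_measure(net, 0)  # point mass at node 1
        nu = node_measure(net, 3)  # point mass at node 2
        assert wasserstein1(mu, nu, metric).cost == pytest.approx(1.0, abs=1e-12)
        # endpoints further apart: delta_0 to delta_3 via measures of an edge
        net2 = make_network([[0, 1], [1, 0]])
        metric2 = compute_graph_metric(net2)
        plan = wasserstein1(node_measure(net2, 0), node_measure(net2, 1), metric2)
        assert plan.cost == pytest.approx(1.0, abs=1e-12)

    def test_matches_vertex_enumeration_oracle(self, rng):
        for _ in range(25):
            m, n = rng.integers(2, 5, size=2)
            size = int(m) + int(n)
            ground_nodes = rng.integers(0, 6, size=size)
            dist = rng.integers(0, 4, size=(6, 6)).astype(float)
            dist = np.triu(dist, 1)
            dist = dist + dist.T
            ground = dist[np.ix_(ground_nodes[:m], ground_nodes[m:])]
            mu_mass = rng.dirichlet(np.ones(m))
            nu_mass = rng.dirichlet(np.ones(n))

            class FakeMeasure:
                pass

            mu = FakeMeasure()
            mu.support = np.arange(m)
            mu.masses = mu_mass
            nu = FakeMeasure()
            nu.support = np.arange(m, size)
            nu.masses = nu_mass

            class FakeMetric:
                distances = np.full((size, size), np.inf)

            FakeMetric.distances[np.ix_(np.arange(m), np.arange(m, size))] = ground
            got = wasserstein1(mu, nu, FakeMetric).cost
            expect = polytope_vertex_w1(mu_mass, nu_mass, ground)
            assert got == pytest.approx(expect, abs=1e-9)

    def test_plan_marginals_and_cost_consistent(self, rng):
        net = random_connected_network(rng, 8, p=0.5)
        metric = compute_graph_metric(net)
        i, j = net.edges()[0]
        mu, nu = node_measure(net, i), node_measure(net, j)
        plan = wasserstein1(mu, nu, metric)
        assert np.abs(plan.plan.sum(axis=1) - mu.masses).max() < 1e-9
        assert np.abs(plan.plan.sum(axis=0) - nu.masses).max() < 1e-9
        assert plan.plan.min() > -1e-12
        ground = metric.distances[np.ix_(plan.sources, plan.targets)]
        assert plan.cost == pytest.approx((plan.plan * ground).sum(), abs=1e-9)

    def test_unreachable_supports_raise(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        net = make_network(w)
        metric = compute_graph_metric(net)
        with pytest.raises(CurvatureError, match="different components"):
            wasserstein1(node_measure(net, 0), node_measure(net, 2), metric)

    def test_w1_is_a_metric_on_sampled_triples(self, rng):
        net = random_connected_network(rng, 7, p=0.6)
        metric = compute_graph_metric(net)
        measures = [node_measure(net, x) for x in range(net.n_nodes)]
        for _ in range(15):
            a, b, c = rng.choice(net.n_nodes, size=3, replace=False)
            ab = wasserstein1(measures[a], measures[b], metric).cost
            ba = wasserstein1(measures[b], measures[a], metric).cost
            bc = wasserstein1(measures[b], measures[c], metric).cost
            ac = wasserstein1(measures[a], measures[c], metric).cost
            assert ab >= -1e-12
            assert ab == pytest.approx(ba, abs=1e-8)
            assert ac <= ab + bc + 1e-8


class TestEdgeCurvature:
    def test_two_node_graph_is_flat(self):
        net = make_network([[0, 2.5], [2.5, 0]])
        metric = compute_graph_metric(net)
        assert edge_curvature(net, 0, 1, metric) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_complete_graph_closed_form(self, n):
        net = complete_network(n)
        result = all_edge_curvatures(net)
        for (i, j), k in result.edge_curvature.items():
            assert k == pytest.approx((n - 2) / (n - 1), abs=1e-9)
            if n <= 5:  # closed form confirmed independently
                assert oracle_edge_curvature(net, i, j) == pytest.approx(
                    (n - 2) / (n - 1), abs=1e-12
                )

    def test_path_interior_edge_flat(self):
        net = path_network(5)
        metric = compute_graph_metric(net)
        assert edge_curvature(net, 1, 2, metric) == pytest.approx(0.0, abs=1e-9)
        assert oracle_edge_curvature(net, 1, 2) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        net = random_connected_network(rng, 8, p=0.45)
        metric = compute_graph_metric(net)
        for i, j in net.edges():
            assert edge_curvature(net, i, j, metric) == pytest.approx(
                edge_curvature(net, j, i, metric), abs=1e-9
            )

    def test_matches_exact_flow_oracle_on_random_graphs(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            net = random_connected_network(rng, n, p=0.5)
            result = all_edge_curvatures(net)
            for (i, j), k in result.edge_curvature.items():
                assert k == pytest.approx(
                    oracle_edge_curvature(net, i, j), abs=1e-9
                )

    def test_missing_edge_rejected(self, rng):
        net = path_network(4)
        metric = compute_graph_metric(net)
        with pytest.raises(CurvatureError, match="no edge"):
            edge_curvature(net, 0, 3, metric)

    def test_scale_invariance_of_hop_curvature(self, rng):
        net = random_connected_network(rng, 7, p=0.5)
        scaled = net.with_weights(net.weights * 37.5)
        base = all_edge_curvatures(net)
        other = all_edge_curvatures(scaled)
        for key in base.edge_curvature:
            assert base.edge_curvature[key] == pytest.approx(
                other.edge_curvature[key], abs=1e-12
            )
        for x in base.scalar_curvature:
            assert base.scalar_curvature[x] == pytest.approx(
                other.scalar_curvature[x], abs=1e-12
            )


class TestCurvatureResult:
    def test_empty_network_gives_empty_result(self):
        result = all_edge_curvatures(make_network(np.zeros((4, 4))))
        assert result.edge_curvature == {} and result.scalar_curvature == {}

    def test_keys_match_edge_set_and_bounds(self, rng):
        for _ in range(10):
            net = random_connected_network(rng, 8, p=0.4)
            result = all_edge_curvatures(net)
            assert set(result.edge_curvature) == set(net.edges())
            for k in result.edge_curvature.values():
                assert -2.0 - 1e-9 <= k <= 1.0 + 1e-9

    def test_scalar_is_convex_combination_of_incident(self, rng):
        net = random_connected_network(rng, 9, p=0.4)
        result = all_edge_curvatures(net)
        for x in range(net.n_nodes):
            incident = [
                k for (i, j), k in result.edge_curvature.items() if x in (i, j)
            ]
            s = result.scalar_curvature[x]
            assert min(incident) - 1e-9 <= s <= max(incident) + 1e-9
            assert s == pytest.approx(
                scalar_curvature(net, result, x), abs=1e-12
            )

    def test_k3_scalar_curvature(self, k3):
        result = all_edge_curvatures(k3)
        for s in result.scalar_curvature.values():
            assert s == pytest.approx(0.5, abs=1e-9)

    def test_tables_deterministic_order(self, rng):
        net = random_connected_network(rng, 7, p=0.5)
        edges, nodes = curvature_tables(net, all_edge_curvatures(net))
        assert list(edges.columns) == ["node_a", "node_b", "weight", "curvature"]
        assert edges["node_a"].is_monotonic_increasing or len(edges) <= 1
        assert len(nodes) == net.n_nodes
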