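import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mapperflow.core import ContractError
from mapperflow.mapper import (
    Cover,
    MapperParams,
    PCAFiltration,
    assign_new_points,
    build_cover,
    build_mapper_graph,
    compute_numeric_ranges,
    gower_distance,
    gower_matrix,
    graph_edit_distance,
    graph_to_dot,
    graph_to_edgelist_tsv,
    k_medoids,
    to_networkx,
)
from mapperflow.synthetic import generate_noisy_circle


SPEC_MIXED = [
    {"name": "x", "kind": "continuous"},
    {"name": "c", "kind": "categorical"},
]


class TestGower:
    def test_identical_points_zero(self):
        r = {"x": 10.0}
        assert gower_distance({"x": 1.0, "c": "a"}, {"x": 1.0, "c": "a"},
                              SPEC_MIXED, r) == 0.0

    def test_all_categorical_mismatch_is_one(self):
        spec = [{"name": "c1", "kind": "categorical"},
                {"name": "c2", "kind": "categorical"}]
        d = gower_distance({"c1": "a", "c2": "x"}, {"c1": "b", "c2": "y"},
                           spec, {})
        assert d == 1.0

    def test_mixed_hand_value(self):
        # numeric diff 5 over range 10 -> 0.5; categorical mismatch -> 1.
        d = gower_distance({"x": 0.0, "c": "a"}, {"x": 5.0, "c": "b"},
                           SPEC_MIXED, {"x": 10.0})
        assert np.isclose(d, 0.75)

    def test_zero_range_column_excluded(self):
        df = pd.DataFrame({"x": [1.0, 1.0], "c": ["a", "b"]})
        with pytest.warns(UserWarning, match="zero range"):
            ranges = compute_numeric_ranges(df, SPEC_MIXED)
        D = gower_matrix(df, df, SPEC_MIXED, ranges)
        assert np.isclose(D[0, 1], 1.0)  # only the categorical column counts

    def test_matrix_symmetric_unit_interval(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20),
                           "c": rng.choice(list("ab"), 20)})
        ranges = compute_numeric_ranges(df, SPEC_MIXED)
        D = gower_matrix(df, df, SPEC_MIXED, ranges)
        assert np.allclose(D, D.T)
        assert D.min() >= 0.0 and D.max() <= 1.0
        assert np.allclose(np.diag(D), 0.0)


class TestFiltration:
    def test_line_data_affine_in_position(self):
        t = np.linspace(0, 1, 50)
        X = np.column_stack([2 * t + 1, -3 * t + 4])
        f = PCAFiltration().fit(X)
        v = f.apply(X)
        corr = np.corrcoef(v, t)[0, 1]
        assert abs(abs(corr) - 1.0) < 1e-10

    def test_filter_variance_equals_top_eigenvalue(self, rng):
        X = rng.normal(size=(100, 4)) @ np.diag([3.0, 1.0, 0.5, 0.2])
        f = PCAFiltration().fit(X)
        v = f.apply(X)
        from mapperflow.morphisms import apply_standardize, fit_standardize

        Z = apply_standardize(X, fit_standardize(X))
        top = np.linalg.eigvalsh(np.cov(Z, rowvar=False, ddof=1)).max()
        assert np.isclose(v.var(ddof=1), top, atol=1e-10)
        assert np.isclose(f.top_eigenvalue_, top)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(50, 3))
        v1 = PCAFiltration().fit(X).apply(X)
        v2 = PCAFiltration().fit(-X).apply(-X)
        # the fixed-sign rule maps the flipped cloud onto the negated values
        assert np.allclose(v1, -v2, atol=1e-10)

    def test_constant_data_errors(self):
        with pytest.raises(ContractError):
            PCAFiltration().fit(np.ones((10, 2)))


class TestCover:
    def test_hand_solved_two_interval_overlap(self):
        c = build_cover(np.array([0.0, 1.0]), k=2, o=0.5)
        (a0, b0), (a1, b1) = c.intervals
        assert np.allclose([a0, b0], [0.0, 2.0 / 3.0])
        assert np.allclose([a1, b1], [1.0 / 3.0, 1.0])
        assert np.isclose(b0 - a1, 0.5 * (b0 - a0))  # overlap = o * length

    def test_k1_single_full_interval(self):
        c = build_cover(np.array([2.0, 5.0]), k=1, o=0.3)
        assert c.intervals == ((2.0, 5.0),)

    def test_zero_overlap_disjoint_bins(self):
        c = build_cover(np.array([0.0, 3.0]), k=3, o=0.0)
        assert np.allclose(c.intervals, [(0, 1), (1, 2), (2, 3)])

    def test_degenerate_constant_values(self):
        c = build_cover(np.array([1.0, 1.0]), k=4, o=0.2)
        assert c.intervals == ((1.0, 1.0),)
        assert c.containing(1.0) == [0]

    def test_membership_inclusive_and_clamped(self):
        c = build_cover(np.array([0.0, 1.0]), k=2, o=0.5)
        assert c.containing(0.5) == [0, 1]
        assert c.containing(2.0) == []
        assert c.containing(2.0, clamp=True) == [1]

    def test_invalid_params(self):
        with pytest.raises(ContractError):
            build_cover(np.array([0.0, 1.0]), k=0, o=0.2)
        with pytest.raises(ContractError):
            build_cover(np.array([0.0, 1.0]), k=2, o=1.0)


class TestKMedoids:
    def test_two_blobs_split(self):
        x = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
        D = np.abs(x[:, None] - x[None, :])
        labels = k_medoids(D, 2)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_deterministic(self, rng):
        X = rng.normal(size=(30, 2))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        assert np.array_equal(k_medoids(D, 3), k_medoids(D, 3))

    def test_b_larger_than_n(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        labels = k_medoids(D, 5)
        assert len(np.unique(labels)) == 2


class TestBuildGraph:
    def test_two_blobs_two_nodes_no_edges(self, blobs_table):
        params = MapperParams(k=2, o=0.0, b=1, min_node_size=1)
        graph, _ = build_mapper_graph(
            blobs_table, blobs_table.to_numpy(float), params)
        assert len(graph.nodes) == 2
        assert graph.edges == []

    def test_uniform_line_path_graph(self, uniform_line_table):
        params = MapperParams(k=3, o=0.5, b=1, min_node_size=1)
        graph, _ = build_mapper_graph(
            uniform_line_table, uniform_line_table.to_numpy(float), params)
        g = to_networkx(graph)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2
        assert nx.is_connected(g)
        assert max(dict(g.degree).values()) == 2  # a path, not a triangle

    def test_noisy_circle_contains_cycle(self):
        pts = generate_noisy_circle(500, noise_sd=0.05, seed=11)
        df = pd.DataFrame(pts, columns=["x", "y"])
        params = MapperParams(k=6, o=0.4, b=2, min_node_size=5,
                              filtration=lambda X: X[:, 1],  # height
                              distance="euclidean")
        graph, _ = build_mapper_graph(df, pts, params)
        g = to_networkx(graph)
        assert len(nx.cycle_basis(g)) >= 1

    def test_pre_pruning_membership_covers_all_samples(self, blobs_table):
        params = MapperParams(k=4, o=0.3, b=2, min_node_size=1)
        graph, _ = build_mapper_graph(
            blobs_table, blobs_table.to_numpy(float), params)
        covered = set()
        for node in graph.nodes:
            covered |= set(node.members.tolist())
        assert covered == set(range(len(blobs_table)))

    def test_edges_have_shared_members_no_self_edges(self, uniform_line_table):
        params = MapperParams(k=4, o=0.5, b=2, min_node_size=1)
        graph, _ = build_mapper_graph(
            uniform_line_table, uniform_line_table.to_numpy(float), params)
        members = {n.id: set(n.members.tolist()) for n in graph.nodes}
        for i, j, w in graph.edges:
            assert i != j
            assert len(members[i] & members[j]) == w >= 1

    def test_members_lie_in_interval_preimage(self, uniform_line_table):
        params = MapperParams(k=3, o=0.4, b=2, min_node_size=1)
        Xe = uniform_line_table.to_numpy(float)
        graph, filtration = build_mapper_graph(uniform_line_table, Xe, params)
        fv = filtration.apply(Xe)
        for node in graph.nodes:
            lo, hi = graph.cover.intervals[node.interval_index]
            assert np.all((fv[node.members] >= lo) & (fv[node.members] <= hi))

    def test_overlap_monotonicity_in_edges(self, uniform_line_table):
        Xe = uniform_line_table.to_numpy(float)
        edge_counts = []
        for o in (0.0, 0.2, 0.4, 0.6):
            params = MapperParams(k=4, o=o, b=1, min_node_size=1)
            graph, _ = build_mapper_graph(uniform_line_table, Xe, params)
            edge_counts.append(len(graph.edges))
        assert all(a <= b for a, b in zip(edge_counts, edge_counts[1:]))

    def test_all_pruned_errors(self, blobs_table):
        params = MapperParams(k=2, o=0.0, b=2, min_node_size=60)
        with pytest.raises(ContractError, match="min_node_size"):
            build_mapper_graph(blobs_table, blobs_table.to_numpy(float), params)

    def test_gower_mode_on_mixed_table(self, flipped_cohort, flipped_colspec):
        from mapperflow.morphisms import encode, fit_encoder

        X, y, groups, spec = flipped_cohort
        enc = fit_encoder(X, flipped_colspec)
        params = MapperParams(k=4, o=0.4, b=2, min_node_size=40)
        graph, _ = build_mapper_graph(X, encode(enc, X), params, flipped_colspec)
        assert len(graph.nodes) >= 2
        # PC1 separates the planted groups: most nodes are group-pure
        purity = [
            max(np.mean(groups[n.members] == g) for g in (0, 1))
            for n in graph.nodes
        ]
        assert np.mean(np.array(purity) > 0.9) >= 0.5


class TestAssign:
    @pytest.fixture
    def line_graph(self, uniform_line_table):
        Xe = uniform_line_table.to_numpy(float)
        params = MapperParams(k=3, o=0.5, b=1, min_node_size=1)
        graph, filtration = build_mapper_graph(uniform_line_table, Xe, params)
        return uniform_line_table, Xe, graph, filtration

    def test_training_medoid_assigned_to_own_node_distance_zero(self, line_graph):
        df, Xe, graph, filt = line_graph
        node = graph.nodes[0]
        row = df.iloc[[node.medoid]].reset_index(drop=True)
        out = assign_new_points(graph, filt, graph.cover, row,
                                Xe[[node.medoid]], max_nodes=1)
        assert out[0][0][1] == 0.0

    def test_overlap_region_gives_two_nodes(self, line_graph):
        df, Xe, graph, filt = line_graph
        fv = filt.apply(Xe)
        in_two = [i for i in range(len(df))
                  if len(graph.cover.containing(float(fv[i]))) == 2]
        assert in_two
        i = in_two[0]
        out = assign_new_points(graph, filt, graph.cover, df.iloc[[i]],
                                Xe[[i]], max_nodes=2)
        assert len(out[0]) == 2

    def test_out_of_range_clamped_to_last_interval(self, line_graph):
        df, Xe, graph, filt = line_graph
        far = pd.DataFrame({"x0": [10.0], "x1": [0.0]})
        out = assign_new_points(graph, filt, graph.cover, far,
                                far.to_numpy(float), max_nodes=1)
        last_interval_nodes = {n.id for n in graph.nodes
                               if n.interval_index == len(graph.cover.intervals) - 1}
        assert out[0][0][0] in last_interval_nodes

    def test_max_nodes_validated(self, line_graph):
        df, Xe, graph, filt = line_graph
        with pytest.raises(ContractError):
            assign_new_points(graph, filt, graph.cover, df.iloc[[0]],
                              Xe[[0]], max_nodes=3)


def _nx_graph(n, edges):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return g


class TestGED:
    def test_identical_graph_zero(self):
        g = _nx_graph(3, [(0, 1), (1, 2)])
        assert graph_edit_distance(g, g) == 0.0

    def test_one_extra_edge_costs_one(self):
        g1 = _nx_graph(3, [(0, 1)])
        g2 = _nx_graph(3, [(0, 1), (1, 2)])
        assert graph_edit_distance(g1, g2) == 1.0

    def test_triangle_vs_path(self):
        tri = _nx_graph(3, [(0, 1), (1, 2), (0, 2)])
        path = _nx_graph(3, [(0, 1), (1, 2)])
        assert graph_edit_distance(tri, path) == 1.0

    def test_symmetric_under_symmetric_costs(self, rng):
        for _ in range(10):
            n1, n2 = rng.integers(1, 5, size=2)
            e1 = [(i, j) for i, j in itertools.combinations(range(n1), 2)
                  if rng.random() < 0.5]
            e2 = [(i, j) for i, j in itertools.combinations(range(n2), 2)
                  if rng.random() < 0.5]
            g1, g2 = _nx_graph(n1, e1), _nx_graph(n2, e2)
            assert graph_edit_distance(g1, g2) == graph_edit_distance(g2, g1)

    def test_matches_networkx_oracle_on_random_graphs(self, rng):
        for _ in range(15):
            n1, n2 = rng.integers(1, 5, size=2)
            e1 = [(i, j) for i, j in itertools.combinations(range(n1), 2)
                  if rng.random() < 0.5]
            e2 = [(i, j) for i, j in itertools.combinations(range(n2), 2)
                  if rng.random() < 0.5]
            g1, g2 = _nx_graph(n1, e1), _nx_graph(n2, e2)
            expected = nx.graph_edit_distance(g1, g2)
            assert graph_edit_distance(g1, g2) == expected

    def test_negative_costs_error(self):
        g = _nx_graph(2, [(0, 1)])
        with pytest.raises(ContractError):
            graph_edit_distance(g, g, costs={"edge_delete": -1.0})

    def test_large_graph_errors_towards_approximate(self):
        g = _nx_graph(9, [])
        with pytest.raises(ContractError, match="exact solver"):
            graph_edit_distance(g, g)


class TestExports:
    def test_edgelist_and_dot(self, uniform_line_table):
        params = MapperParams(k=3, o=0.5, b=1, min_node_size=1)
        graph, _ = build_mapper_graph(
            uniform_line_table, uniform_line_table.to_numpy(float), params)
        tsv = graph_to_edgelist_tsv(graph)
        assert tsv.startswith("node_i\tnode_j\tshared")
        assert len(tsv.strip().splitlines()) == 1 + len(graph.edges)
        y = np.zeros(len(uniform_line_table), dtype=int)
        y[:10] = 1
        dot = graph_to_dot(graph, outcome=y)
        assert dot.startswith("graph mapper {")
        assert "--" in dot
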