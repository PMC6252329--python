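import itertools

import numpy as np
import pytest

from ggmine import (
    HubSelection,
    PointSet2D,
    delaunay,
    emst,
    gabriel_graph,
    global_efficiency,
    hub_variability_ge,
    rng_graph,
    select_hubs,
)
from ggmine.graphs import EmptySelectionError, ProximityGraph

from conftest import brute_gabriel_edges, brute_rng_edges


def pts(*coords):
    return PointSet2D(np.array(coords, dtype=float))


class TestGabriel:
    def test_two_points_always_adjacent(self):
        assert gabriel_graph(pts((0, 0), (1, 0))).edges == frozenset({(0, 1)})

    def test_collinear_middle_blocks_long_edge(self):
        g = gabriel_graph(pts((0, 0), (1, 0), (3, 0)))
        assert g.edges == frozenset({(0, 1), (1, 2)})

    def test_open_triangle_is_complete(self):
        g = gabriel_graph(pts((0, 0), (4, 0), (1, 2)))
        assert g.edges == frozenset({(0, 1), (0, 2), (1, 2)})

    def test_right_angle_boundary_tie_keeps_edge(self):
        # (0,1) lies exactly on the diametral circle of (0,0)-(1,... wait:
        # unit-square corner: C((0,0),(0,2)) has radius 1 centered (0,1);
        # point (1,1) is exactly on that circle -> must NOT block.
        g = gabriel_graph(pts((0, 0), (0, 2), (1, 1)))
        assert (0, 1) in g.edges

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_oracle(self, seed):
        r = np.random.default_rng(seed)
        coords = r.uniform(size=(60, 2))
        g = gabriel_graph(PointSet2D(coords))
        assert g.edges == frozenset(brute_gabriel_edges(coords))

    def test_duplicates_collapsed(self):
        with pytest.warns(UserWarning, match="duplicate"):
            g = gabriel_graph(pts((0, 0), (0, 0), (1, 0)))
        assert g.n_nodes == 2
        assert g.n_points == 3


class TestRNGAndChain:
    def test_collinear_same_as_gg(self):
        g = rng_graph(pts((0, 0), (1, 0), (3, 0)))
        assert g.edges == frozenset({(0, 1), (1, 2)})

    @pytest.mark.parametrize("seed", range(5))
    def test_rng_agrees_with_brute_oracle(self, seed):
        r = np.random.default_rng(seed + 100)
        coords = r.uniform(size=(60, 2))
        assert rng_graph(PointSet2D(coords)).edges == frozenset(brute_rng_edges(coords))

    @pytest.mark.parametrize("seed", range(10))
    def test_containment_chain(self, seed):
        r = np.random.default_rng(seed + 7)
        p = PointSet2D(r.uniform(size=(100, 2)))
        e_mst = emst(p).edges
        e_rng = rng_graph(p).edges
        e_gg = gabriel_graph(p).edges
        e_dt = delaunay(p).edges
        assert e_mst <= e_rng <= e_gg <= e_dt


class TestEMSTandDT:
    def test_emst_minimal_over_spanning_trees(self):
        coords = np.array([[0.0, 0.0], [4.0, 0.0], [1.0, 2.0]])
        g = emst(PointSet2D(coords))
        assert len(g.edges) == 2

        def tree_len(edges):
            return sum(np.linalg.norm(coords[a] - coords[b]) for a, b in edges)

        all_trees = [
            {(0, 1), (0, 2)}, {(0, 1), (1, 2)}, {(0, 2), (1, 2)},
        ]
        assert tree_len(g.edges) == pytest.approx(min(tree_len(t) for t in all_trees))

    @pytest.mark.parametrize("n", [2, 10, 50])
    def test_emst_edge_count(self, n):
        r = np.random.default_rng(n)
        g = emst(PointSet2D(r.uniform(size=(n, 2))))
        assert len(g.edges) == n - 1

    def test_collinear_delaunay_falls_back_to_path(self):
        with pytest.warns(UserWarning, match="degenerate"):
            g = delaunay(pts((0, 0), (1, 0), (3, 0), (2, 0)))
        assert len(g.edges) == 3
        deg = g.degrees
        assert sorted(deg) == [1, 1, 2, 2]


class TestHubs:
    def test_path_graph_middle_node(self):
        g = ProximityGraph(3, frozenset({(0, 1), (1, 2)}), "gg", np.arange(3))
        sel = select_hubs(g, 2)
        assert list(sel.selected) == [1]

    def test_k1_selects_everything_on_connected_graph(self, rng):
        p = PointSet2D(rng.uniform(size=(50, 2)))
        sel = select_hubs(gabriel_graph(p), 1)
        assert sel.n_selected == 50

    def test_selection_shrinks_with_k(self, rng):
        p = PointSet2D(rng.uniform(size=(128, 2)))
        g = gabriel_graph(p)
        sizes = [select_hubs(g, k).n_selected for k in (1, 2, 3, 4)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[3] < sizes[2]

    def test_empty_selection_suggests_lower_k(self):
        g = ProximityGraph(2, frozenset({(0, 1)}), "gg", np.arange(2))
        with pytest.raises(EmptySelectionError, match="k = 7"):
            select_hubs(g, 8)

    def test_duplicates_inherit_hub_status(self):
        with pytest.warns(UserWarning, match="duplicate"):
            g = gabriel_graph(pts((0, 0), (0, 0), (1, 0), (2, 0)))
        sel = select_hubs(g, 2)
        # middle unique point is the hub; duplicates of (0,0) are not
        assert list(sel.selected) == [2]


class TestGlobalEfficiency:
    def test_three_node_unit_path(self):
        g = ProximityGraph(3, frozenset({(0, 1), (1, 2)}), "custom", np.arange(3))
        assert global_efficiency(g) == pytest.approx(5.0 / 6.0, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_complete_unit_graph_is_one(self, n):
        edges = frozenset((i, j) for i in range(n) for j in range(i + 1, n))
        g = ProximityGraph(n, edges, "custom", np.arange(n))
        assert global_efficiency(g) == pytest.approx(1.0, abs=1e-12)

    def test_disconnected_pair_is_zero(self):
        g = ProximityGraph(2, frozenset(), "custom", np.arange(2))
        assert global_efficiency(g) == 0.0

    def test_monotone_in_edge_length(self):
        e = {(0, 1): 1.0, (1, 2): 1.0}
        from ggmine.graphs import _ge_from_lengths

        base = _ge_from_lengths(3, e)
        worse = _ge_from_lengths(3, {(0, 1): 2.0, (1, 2): 1.0})
        assert worse < base


class TestHubVariability:
    def hubs(self, n):
        return HubSelection(1, np.arange(n), np.zeros(n, dtype=int))

    def test_worked_collinear_case(self):
        p = pts((0, 0), (1, 0), (2, 0))
        assert hub_variability_ge(p, self.hubs(3)) == pytest.approx(
            0.41666666666666663, abs=1e-12
        )

    def test_two_hubs_forced_zero(self):
        p = pts((0, 0), (1, 0))
        assert hub_variability_ge(p, self.hubs(2)) == 0.0

    @pytest.mark.parametrize("c", [0.1, 3.0, 250.0])
    def test_scale_invariance(self, rng, c):
        coords = rng.uniform(size=(8, 2))
        a = hub_variability_ge(PointSet2D(coords), self.hubs(8))
        b = hub_variability_ge(PointSet2D(coords * c), self.hubs(8))
        assert a == pytest.approx(b, rel=1e-9)

    def test_coincident_hubs_maximal(self):
        p = pts((1, 1), (1, 1), (1, 1))
        with pytest.warns(UserWarning, match="coincident"):
            assert hub_variability_ge(p, self.hubs(3)) == 1.0
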