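"""Neighborhood graphs and the MRF-like filter against its loop oracle."""

import numpy as np
import pytest

from conftest import toy_bank
from pupilmark.graph import build_graph, default_graph, local_neighborhood
from pupilmark.heatmaps import HeatmapStack
from pupilmark.schema import DEFAULT_SCHEMA
from pupilmark.spatial import (
    SpatialModelParams,
    build_edge_set,
    filter_heatmaps,
    filter_oracle,
)


class TestLocalNeighborhood:
    COORDS = np.array([[0.0, 0.0], [3.0, 0.0], [10.0, 0.0]])

    def test_small_radius_empty(self):
        assert local_neighborhood(self.COORDS, 0, 1.0) == set()

    def test_hand_distance_check(self):
        assert local_neighborhood(self.COORDS, 0, 5.0) == {1}

    def test_radius_covering_diameter_gives_all_others(self, rng):
        coords = rng.uniform(0, 10, (17, 2))
        diam = max(
            np.linalg.norm(a - b) for a in coords for b in coords
        )
        assert local_neighborhood(coords, 3, diam) == set(range(17)) - {3}

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            local_neighborhood(self.COORDS, 0, 0.0)


class TestBuildGraph:
    def test_complete_star_with_diameter_radius(self, rng):
        ids = tuple("abcdefghijklmnopq")
        coords = rng.uniform(0, 5, (17, 2))
        g = build_graph(ids, coords, r=100.0, global_set=())
        assert all(len(g.union_sets[i]) == 16 for i in ids)
        assert g.n_edges == 17 * 16

    def test_central_landmark_not_its_own_neighbor(self):
        g = default_graph()
        for lid in g.global_set:
            assert lid not in g.union_sets[lid]

    def test_toy_five_landmark_hand_enumeration(self):
        ids = ("p", "q", "r", "s", "t")
        coords = np.array(
            [[0.0, 0.0], [1.0, 0.0], [4.0, 0.0], [4.0, 1.0], [10.0, 0.0]]
        )
        g = build_graph(ids, coords, r=1.5, global_set={"p", "t"})
        assert g.union_sets["p"] == frozenset({"q", "t"})
        assert g.union_sets["q"] == frozenset({"p", "t"})
        assert g.union_sets["r"] == frozenset({"s", "p", "t"})
        assert g.union_sets["s"] == frozenset({"r", "p", "t"})
        assert g.union_sets["t"] == frozenset({"p"})
        expected_edges = sorted(
            [(i, j) for i in ids for j in g.union_sets[i]]
        )
        assert list(g.edges) == expected_edges

    def test_empty_neighborhood_raises(self):
        ids = ("a", "b")
        coords = np.array([[0.0, 0.0], [50.0, 0.0]])
        with pytest.raises(ValueError, match="radius"):
            build_graph(ids, coords, r=1.0, global_set=())

    def test_edges_deterministically_sorted(self):
        g = default_graph()
        assert list(g.edges) == sorted(g.edges)

    def test_default_graph_nonempty_unions(self):
        g = default_graph()
        assert all(g.union_sets[i] for i in g.ids)
        assert g.global_set == DEFAULT_SCHEMA.global_set


class TestFilterOracleEquivalence:
    def _random_instance(self, seed, h=8, w=8):
        rng = np.random.default_rng(seed)
        ids = ("A", "B", "C")
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        g = build_graph(ids, coords, r=5.0, global_set=())
        bank = toy_bank(
            g, (2 * h, 2 * w), lambda e: rng.random((2 * h, 2 * w)) * 0.05 + 1e-9
        )
        hm = HeatmapStack(rng.random((3, h, w)), 4.0)
        return hm, bank, g

    def test_matches_oracle_on_random_instances(self):
        worst = 0.0
        for seed in range(10):
            hm, bank, g = self._random_instance(seed)
            fast = filter_heatmaps(hm, bank, g)
            slow = filter_oracle(hm, bank, g)
            rel = np.abs(fast.maps - slow.maps) / np.abs(slow.maps)
            worst = max(worst, rel.max())
        assert worst < 1e-6

    def test_oracle_refuses_large_grids(self):
        hm, bank, g = self._random_instance(0)
        big = HeatmapStack(np.zeros((3, 20, 20)), 4.0)
        with pytest.raises(ValueError, match="oracle"):
            filter_oracle(big, bank, g)


class TestFilterProperties:
    def _uniform_setup(self, h=8, w=8, bias=-40.0):
        ids = ("A", "B", "C")
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        g = build_graph(ids, coords, r=5.0, global_set=())
        val = 1.0 / (4 * h * w)
        bank = toy_bank(g, (2 * h, 2 * w), lambda e: np.full((2 * h, 2 * w), val))
        params = SpatialModelParams(bias_init=bias)
        return g, bank, params

    def test_uniform_priors_preserve_argmax(self, rng):
        """With uniform priors the neighbor field is constant, so the
        filtered argmax equals the unary argmax for every landmark."""
        g, bank, params = self._uniform_setup()
        for _ in range(5):
            hm = HeatmapStack(rng.random((3, 8, 8)), 4.0)
            out = filter_heatmaps(hm, bank, g, params)
            for k in range(3):
                assert hm.maps[k].argmax() == out.maps[k].argmax()

    def test_positivity_for_nonnegative_input(self, rng):
        g, bank, params = self._uniform_setup()
        hm = HeatmapStack(np.zeros((3, 8, 8)), 4.0)
        out = filter_heatmaps(hm, bank, g, params)
        assert np.all(out.maps > 0)

    def test_zero_heatmaps_uniform_priors_give_constant_maps(self):
        g, bank, params = self._uniform_setup()
        hm = HeatmapStack(np.zeros((3, 8, 8)), 4.0)
        out = filter_heatmaps(hm, bank, g, params)
        for k in range(3):
            assert np.ptp(out.maps[k]) < 1e-12

    def test_monotone_consolidation(self, rng):
        """Raising p_i at a cell strictly raises filtered p̂_i there."""
        g, bank, params = self._uniform_setup()
        hm = HeatmapStack(rng.random((3, 8, 8)), 4.0)
        out1 = filter_heatmaps(hm, bank, g, params)
        hm2 = hm.copy()
        hm2.maps[0, 4, 4] += 0.5
        out2 = filter_heatmaps(hm2, bank, g, params)
        assert out2.maps[0, 4, 4] > out1.maps[0, 4, 4]

    def test_delta_prior_delta_neighbor_peaks_at_neighbor_location(self):
        """One neighbor, delta prior at the kernel anchor, delta p_j:
        p̂_i is maximal exactly at p_j's location when p_i is uniform."""
        h = w = 8
        ids = ("A", "B")
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        g = build_graph(ids, coords, r=5.0, global_set=())

        def maker(e):
            grid = np.full((2 * h, 2 * w), 1e-9)
            a0, b0 = h // 2, w // 2
            grid[2 * a0 : 2 * a0 + 2, 2 * b0 : 2 * b0 + 2] = 5.0
            return grid

        bank = toy_bank(g, (2 * h, 2 * w), maker)
        maps = np.full((2, h, w), 0.1)
        maps[1] = 0.0
        maps[1, 2, 5] = 1.0  # neighbor's delta at (r=2, c=5)
        out = filter_heatmaps(HeatmapStack(maps, 4.0), bank, g)
        r, c = np.unravel_index(out.maps[0].argmax(), (h, w))
        assert (r, c) == (2, 5)

    def test_negative_heatmaps_rejected(self):
        g, bank, params = self._uniform_setup()
        with pytest.raises(ValueError, match="non-negative"):
            filter_heatmaps(HeatmapStack(-np.ones((3, 8, 8)), 4.0), bank, g, params)

    def test_runtime_scales_with_edge_count(self, rng):
        """Work is proportional to the number of edges (structural check)."""
        ids = tuple("abcde")
        coords = rng.uniform(0, 3, (5, 2))
        g_small = build_graph(ids, coords, r=100.0, global_set=())
        edge_ops = g_small.n_edges
        assert edge_ops == 5 * 4
        bank = toy_bank(g_small, (16, 16), lambda e: np.full((16, 16), 0.01))
        es = build_edge_set(bank, g_small, SpatialModelParams(), (8, 8))
        assert es.kernels.shape[0] == edge_ops


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SpatialModelParams(eps=0.0)
    with pytest.raises(ValueError):
        SpatialModelParams(softplus_beta=-1.0)
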