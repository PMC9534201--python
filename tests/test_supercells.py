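"""Local-graph construction, supercell extraction, descriptor geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from supercellgraph import (
    CellTable, build_local_graph, extract_supercells, supercell_descriptor,
)

from conftest import random_table


def edge_set(graph):
    return {tuple(e) for e in graph.edges}


def brute_force_components(xy, d_max, min_size):
    """Independent oracle: union-find over the <= d_max pairwise relation."""
    n = len(xy)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(xy[i] - xy[j])) <= d_max:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    comps = [tuple(sorted(g)) for g in groups.values() if len(g) >= min_size]
    return sorted(comps)


class TestBuildLocalGraph:
    def test_matches_exhaustive_pairwise_oracle_tight_threshold(self, line_table):
        g = build_local_graph(line_table, np.zeros(3, int), d_max=2.0, k_nn=2)
        assert edge_set(g) == {(0, 1)}
        np.testing.assert_allclose(g.lengths, [1.0])

    def test_matches_exhaustive_pairwise_oracle_loose_threshold(self, line_table):
        g = build_local_graph(line_table, np.zeros(3, int), d_max=20.0, k_nn=2)
        assert edge_set(g) == {(0, 1), (0, 2), (1, 2)}

    def test_stratified_mode_drops_cross_phenotype_edges(self):
        t = CellTable("i", [1, 2], [(0, 0), (1, 0)], np.zeros((2, 1)), ["f0"])
        g = build_local_graph(t, np.array([0, 1]), d_max=5.0, k_nn=1, mode="stratified")
        assert g.n_edges == 0
        g2 = build_local_graph(t, np.array([0, 0]), d_max=5.0, k_nn=1, mode="stratified")
        assert edge_set(g2) == {(0, 1)}

    def test_single_cell_image_gives_one_node_no_edges(self):
        t = CellTable("i", [1], [(3, 4)], np.zeros((1, 1)), ["f0"])
        g = build_local_graph(t, np.zeros(1, int), d_max=5.0, k_nn=3)
        assert g.n_nodes == 1 and g.n_edges == 0

    def test_knn_at_least_n_is_clamped_with_warning(self, line_table):
        with pytest.warns(UserWarning, match="clamping"):
            g = build_local_graph(line_table, np.zeros(3, int), d_max=20.0, k_nn=10)
        assert edge_set(g) == {(0, 1), (0, 2), (1, 2)}

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 40))
    def test_full_knn_edges_equal_distance_relation(self, seed, n):
        """With k_nn >= n-1, edges are exactly the <= d_max pairs."""
        rng = np.random.default_rng(seed)
        t = random_table(rng, n, extent=20.0)
        d_max = 5.0
        g = build_local_graph(t, np.zeros(n, int), d_max=d_max, k_nn=n - 1)
        expected = {
            (i, j)
            for i in range(n) for j in range(i + 1, n)
            if np.hypot(*(t.xy[i] - t.xy[j])) <= d_max
        }
        assert edge_set(g) == expected


class TestExtractSupercells:
    def test_small_components_are_discarded_and_counted(self, line_table):
        g = build_local_graph(line_table, np.zeros(3, int), d_max=2.0, k_nn=2)
        scs, report = extract_supercells(g, line_table, min_supercell_size=2)
        assert len(scs) == 1
        assert scs[0].member_cells.tolist() == [0, 1]
        assert report.n_components_discarded == 1 and report.n_cells_discarded == 1

    def test_complete_graph_centroid_is_mean_of_members(self, line_table):
        g = build_local_graph(line_table, np.zeros(3, int), d_max=20.0, k_nn=2)
        scs, _ = extract_supercells(g, line_table, min_supercell_size=1)
        assert len(scs) == 1 and len(scs[0].member_cells) == 3
        np.testing.assert_allclose(scs[0].centroid, [(0 + 1 + 10) / 3, 0.0])

    def test_empty_edges_min_size_one_gives_singletons(self):
        rng = np.random.default_rng(0)
        t = random_table(rng, 6, extent=1000.0)
        g = build_local_graph(t, np.zeros(6, int), d_max=1e-6, k_nn=5)
        scs, _ = extract_supercells(g, t, min_supercell_size=1)
        assert [len(s.member_cells) for s in scs] == [1] * 6

    @pytest.mark.parametrize("seed", range(10))
    def test_components_match_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 120))
        t = random_table(rng, n, extent=40.0)
        g = build_local_graph(t, np.zeros(n, int), d_max=6.0, k_nn=n - 1)
        scs, _ = extract_supercells(g, t, min_supercell_size=2)
        got = sorted(tuple(s.member_cells.tolist()) for s in scs)
        assert got == brute_force_components(t.xy, 6.0, 2)

    def test_invariant_to_row_permutation_up_to_relabeling(self):
        rng = np.random.default_rng(42)
        t = random_table(rng, 60, extent=30.0)
        perm = rng.permutation(60)
        tp = CellTable(t.image_id, t.cell_ids[perm], t.xy[perm], t.features[perm], t.feature_names)
        partition = lambda table: {
            frozenset(table.cell_ids[s.member_cells].tolist())
            for s in extract_supercells(
                build_local_graph(table, np.zeros(60, int), 8.0, 59), table, 1)[0]
        }
        assert partition(t) == partition(tp)

    def test_increasing_d_max_never_increases_supercell_count(self):
        rng = np.random.default_rng(9)
        t = random_table(rng, 80, extent=50.0)
        counts = []
        for d_max in (2.0, 5.0, 10.0, 25.0, 80.0):
            g = build_local_graph(t, np.zeros(80, int), d_max, k_nn=79)
            counts.append(len(extract_supercells(g, t, 1)[0]))
        assert counts == sorted(counts, reverse=True)


class TestSupercellDescriptor:
    def _descriptor(self, xy, phen, k_cells=2, F=1):
        n = len(xy)
        t = CellTable("i", np.arange(n), xy, np.zeros((n, F)), [f"f{j}" for j in range(F)])
        g = build_local_graph(t, np.asarray(phen), d_max=1e6, k_nn=max(n - 1, 1))
        scs, _ = extract_supercells(g, t, 1)
        assert len(scs) == 1
        return supercell_descriptor(scs[0], t, np.asarray(phen), k_cells, np.zeros((n, F)))

    def test_two_member_degenerate_hull(self):
        d = self._descriptor([(0, 0), (1, 0)], [0, 0])
        assert d[0] == 2
        np.testing.assert_allclose(d[1:3], [1.0, 0.0])  # composition (1, 0)
        assert d[3] == 0.0 and d[4] == 0.0              # hull area 0, density 0

    def test_unit_square_geometry(self):
        d = self._descriptor([(0, 0), (1, 0), (1, 1), (0, 1)], [0, 0, 0, 0])
        assert d[3] == pytest.approx(1.0)   # hull area
        assert d[4] == pytest.approx(4.0)   # density = 4 cells / unit area
        assert d[5] == pytest.approx(1.0)   # mean NN distance

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_composition_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        k = int(rng.integers(2, 6))
        d = self._descriptor(rng.uniform(0, 10, (n, 2)), rng.integers(0, k, n), k_cells=k)
        assert abs(d[1:1 + k].sum() - 1.0) <= 1e-12

    def test_descriptor_length_is_k_plus_f_plus_4(self):
        d = self._descriptor([(0, 0), (2, 0), (1, 2)], [0, 1, 1], k_cells=3, F=5)
        assert len(d) == 3 + 5 + 4
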