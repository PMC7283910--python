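"""Minimum spanning arborescences: solver, oracle equivalence, profiles."""

import networkx as nx
import numpy as np
import pytest

from brainfingerprint.channels import generic_channel_map
from brainfingerprint.dmst import (
    Arborescence,
    WeightedDigraph,
    from_ste,
    minimum_arborescence,
    out_degree_profile,
    select_root,
)
from brainfingerprint.ste import STEMatrix
from .conftest import brute_force_min_arborescence


def _check_structure(arb: Arborescence, n: int, root: int) -> None:
    assert arb.root == root
    assert len(arb.parent) == n - 1
    assert root not in arb.parent
    # reachability of every node from the root
    for v in arb.parent:
        node, hops = v, 0
        while node != root:
            node = arb.parent[node]
            hops += 1
            assert hops <= n


class TestFromSte:
    def test_modes(self, rng):
        vals = rng.random((5, 5))
        np.fill_diagonal(vals, 0)
        m = STEMatrix(vals)
        lit = from_ste(m, "literal").weights
        neg = from_ste(m, "negate").weights
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_array_equal(lit[off], vals[off])
        np.testing.assert_array_equal(neg[off], -vals[off])
        assert np.all(np.isnan(np.diag(lit)))
        with pytest.raises(ValueError, match="mode"):
            from_ste(m, "maximize")

    def test_both_modes_span_all_nodes(self, rng):
        vals = rng.random((8, 8))
        np.fill_diagonal(vals, 0)
        m = STEMatrix(vals)
        for mode in ("literal", "negate"):
            arb = minimum_arborescence(from_ste(m, mode), 0, mode=mode)
            assert set(arb.parent) | {0} == set(range(8))


class TestMinimumArborescence:
    def test_star_graph(self):
        n = 6
        w = np.full((n, n), np.nan)
        w[0, 1:] = 1.0
        arb = minimum_arborescence(WeightedDigraph(w), 0)
        assert arb.total_weight == n - 1
        assert all(arb.parent[v] == 0 for v in range(1, n))

    def test_two_cycle_requires_contraction(self):
        # cheapest entering edges of a and b form the ring a<->b
        w = np.full((3, 3), np.nan)
        w[0, 1] = 5.0
        w[0, 2] = 5.0
        w[1, 2] = 1.0
        w[2, 1] = 1.0
        arb = minimum_arborescence(WeightedDigraph(w), 0)
        assert arb.total_weight == 6.0
        _check_structure(arb, 3, 0)

    @pytest.mark.parametrize("trial_block", range(4))
    def test_enumeration_oracle_on_random_digraphs(self, trial_block):
        rng = np.random.default_rng(1000 + trial_block)
        for _ in range(50):
            n = int(rng.integers(2, 6))
            w = rng.integers(1, 10, size=(n, n)).astype(float)
            np.fill_diagonal(w, np.nan)
            if rng.random() < 0.4:  # sparse variant
                w[rng.random((n, n)) < 0.3] = np.nan
                np.fill_diagonal(w, np.nan)
            root = int(rng.integers(n))
            expected = brute_force_min_arborescence(w, root)
            if expected is None:
                with pytest.raises(ValueError, match="unreachable"):
                    minimum_arborescence(WeightedDigraph(w), root)
                continue
            arb = minimum_arborescence(WeightedDigraph(w), root)
            assert arb.total_weight == pytest.approx(expected)
            _check_structure(arb, n, root)

    def test_agrees_with_networkx_edmonds(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 8))
            w = rng.integers(1, 20, size=(n, n)).astype(float)
            np.fill_diagonal(w, np.nan)
            root = int(rng.integers(n))
            g = nx.DiGraph()
            for u in range(n):
                for v in range(n):
                    if u != v and v != root:  # forcing the root
                        g.add_edge(u, v, weight=w[u, v])
            expected = nx.algorithms.tree.branchings.minimum_spanning_arborescence(
                g, attr="weight"
            )
            arb = minimum_arborescence(WeightedDigraph(w), root)
            assert arb.total_weight == pytest.approx(
                expected.size(weight="weight")
            )

    def test_weight_shift_moves_total_by_n_minus_1_c(self, rng):
        n = 5
        w = rng.random((n, n)) * 10
        np.fill_diagonal(w, np.nan)
        arb = minimum_arborescence(WeightedDigraph(w), 0)
        shifted = minimum_arborescence(WeightedDigraph(w + 3.0), 0)
        assert shifted.total_weight == pytest.approx(arb.total_weight + (n - 1) * 3.0)
        assert shifted.parent == arb.parent

    def test_unreachable_node_named(self):
        w = np.full((3, 3), np.nan)
        w[0, 1] = 1.0  # node 2 has no entering edge
        with pytest.raises(ValueError, match="2"):
            minimum_arborescence(WeightedDigraph(w), 0)

    def test_deterministic_tie_break(self):
        w = np.full((3, 3), np.nan)
        w[0, 1] = 1.0
        w[0, 2] = 1.0
        w[1, 2] = 1.0
        arb = minimum_arborescence(WeightedDigraph(w), 0)
        assert arb.parent[2] == 0  # lowest source index wins the tie


class TestProfilesAndExport:
    def test_star_profile(self):
        arb = Arborescence(root=0, parent={1: 0, 2: 0, 3: 0},
                           weights={1: 1.0, 2: 1.0, 3: 1.0})
        table, key = out_degree_profile(arb, generic_channel_map(4))
        assert table.loc[0, "out_degree"] == 3
        assert key == {"ch1"}

    def test_chain_profile_reports_tied_key_nodes(self):
        arb = Arborescence(root=0, parent={1: 0, 2: 1, 3: 2},
                           weights={1: 1.0, 2: 1.0, 3: 1.0})
        _, key = out_degree_profile(arb, generic_channel_map(4))
        assert key == {"ch1", "ch2", "ch3"}

    def test_out_degrees_sum_to_n_minus_1(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 9))
            w = rng.random((n, n))
            np.fill_diagonal(w, np.nan)
            arb = minimum_arborescence(WeightedDigraph(w), 0)
            assert arb.out_degrees().sum() == n - 1

    def test_cycle_in_parent_map_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            Arborescence(root=0, parent={1: 2, 2: 1}, weights={1: 1.0, 2: 1.0})

    def test_edge_tsv_and_dot(self, tmp_path):
        arb = Arborescence(root=0, parent={1: 0, 2: 1}, weights={1: 0.5, 2: 0.25})
        path = tmp_path / "tree.tsv"
        arb.to_edge_tsv(path)
        assert path.read_text().splitlines()[0] == "source\ttarget\tweight"
        dot = arb.to_dot(["A", "B", "C"])
        assert '"A" -> "B"' in dot and dot.startswith("digraph")


class TestRootSelection:
    def test_policies(self, rng):
        vals = rng.random((64, 64))
        np.fill_diagonal(vals, 0)
        m = STEMatrix(vals)
        assert select_root(m, 5) == 5
        assert select_root(m, "max-out-strength") == int(np.argmax(vals.sum(axis=1)))
        assert select_root(m, "random", seed=3) == select_root(m, "random", seed=3)
        assert select_root(m, "FC5") == 0
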