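import networkx as nx
import numpy as np
import pandas as pd
import pytest

from nigraspace.io import PPINetwork
from nigraspace.netprop import (
    PropagationConfig,
    betweenness,
    build_seed_vector,
    column_normalize,
    propagate_degs,
    rwr,
    select_key_genes,
)


def de_table(rows):
    """rows: list of (gene, log2FC, padj)."""
    return pd.DataFrame(
        {
            "gene": [r[0] for r in rows],
            "log2FC": [r[1] for r in rows],
            "padj": [r[2] for r in rows],
        }
    )


def direct_solve(W, p0, r):
    """Closed-form stationary vector: p = r (I - (1-r) W)^-1 p0."""
    n = W.shape[0]
    return r * np.linalg.solve(np.eye(n) - (1 - r) * W, p0)


def random_connected_graph(rng, n_max=50, n_min=4):
    n = int(rng.integers(n_min, n_max + 1))
    while True:
        g = nx.gnp_random_graph(n, min(1.0, 2.5 / n), seed=int(rng.integers(2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            return PPINetwork(nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes}))


class TestColumnNormalize:
    def test_path_graph_middle_column(self):
        W, nodes = column_normalize(PPINetwork(nx.path_graph(3)))
        j = nodes.index(1)
        np.testing.assert_allclose(W[:, j], [0.5, 0.0, 0.5])

    def test_regular_graph_unchanged(self):
        g = nx.cycle_graph(6)  # 2-regular: A/deg already column-stochastic
        W, _ = column_normalize(PPINetwork(g))
        A = nx.to_numpy_array(g, nodelist=sorted(g.nodes)) / 2.0
        np.testing.assert_allclose(W, A)

    def test_isolated_node_identity_column(self):
        g = nx.Graph([("A", "B")])
        g.add_node("C")
        W, nodes = column_normalize(PPINetwork(g))
        j = nodes.index("C")
        expected = np.zeros(3)
        expected[j] = 1.0
        np.testing.assert_allclose(W[:, j], expected)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            W, _ = column_normalize(random_connected_graph(rng, 20))
            np.testing.assert_allclose(W.sum(axis=0), 1.0, atol=1e-12)


class TestSeedVector:
    def test_single_deg_unit_mass(self):
        net = PPINetwork(nx.path_graph(["A", "B", "C"]))
        p0 = build_seed_vector(de_table([("A", -3.0, 0.01), ("B", 1.0, 0.9)]), net)
        assert p0["A"] == 1.0 and p0.sum() == 1.0

    def test_abs_transform_splits_mass(self):
        net = PPINetwork(nx.path_graph(["A", "B", "C"]))
        p0 = build_seed_vector(de_table([("A", 1.0, 0.01), ("C", -1.0, 0.01)]), net)
        np.testing.assert_allclose([p0["A"], p0["C"]], [0.5, 0.5])

    def test_unmapped_deg_warns(self):
        net = PPINetwork(nx.path_graph(["A", "B", "C"]))
        with pytest.warns(UserWarning, match="absent from network"):
            p0 = build_seed_vector(de_table([("A", 2.0, 0.01), ("ZZZ", 3.0, 0.01)]), net)
        assert p0["A"] == 1.0

    def test_no_mappable_deg_is_error(self):
        net = PPINetwork(nx.path_graph(["A", "B", "C"]))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="ZZZ"):
                build_seed_vector(de_table([("ZZZ", 2.0, 0.01)]), net)

    def test_positive_part_drops_downregulated(self):
        net = PPINetwork(nx.path_graph(["A", "B", "C"]))
        p0 = build_seed_vector(
            de_table([("A", 2.0, 0.01), ("C", -5.0, 0.01)]), net, "positive-part"
        )
        assert p0["A"] == 1.0 and p0["C"] == 0.0


class TestRWR:
    def test_two_node_closed_form(self):
        W, _ = column_normalize(PPINetwork(nx.path_graph(["A", "B"])))
        p = rwr(W, np.array([1.0, 0.0]), PropagationConfig(restart_rate=0.5))
        np.testing.assert_allclose(p, [2 / 3, 1 / 3], atol=1e-7)

    def test_restart_dominant_limit(self):
        rng = np.random.default_rng(1)
        net = random_connected_graph(rng, 20)
        W, nodes = column_normalize(net)
        p0 = np.zeros(len(nodes))
        p0[0] = 1.0
        p = rwr(W, p0, PropagationConfig(restart_rate=0.999))
        assert np.abs(p - p0).sum() < 0.01

    def test_matches_direct_linear_solve(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            net = random_connected_graph(rng)
            W, nodes = column_normalize(net)
            p0 = rng.random(len(nodes))
            p0 /= p0.sum()
            p_iter = rwr(W, p0, PropagationConfig(restart_rate=0.7, tolerance=1e-12))
            p_direct = direct_solve(W, p0, 0.7)
            assert np.abs(p_iter - p_direct).max() <= 1e-8

    def test_mass_conserved_and_fixed_point(self):
        rng = np.random.default_rng(3)
        net = random_connected_graph(rng, 30)
        W, nodes = column_normalize(net)
        p0 = np.full(len(nodes), 1.0 / len(nodes))
        cfg = PropagationConfig(restart_rate=0.7, tolerance=1e-10)
        p = rwr(W, p0, cfg)
        assert abs(p.sum() - 1.0) < 1e-9
        residual = np.abs(p - 0.3 * (W @ p) - 0.7 * p0).sum()
        assert residual < 10 * cfg.tolerance

    def test_seed_mass_monotonicity(self):
        """Adding seed mass to a node never decreases its stationary value."""
        rng = np.random.default_rng(4)
        net = random_connected_graph(rng, 25)
        W, nodes = column_normalize(net)
        n = len(nodes)
        base = np.full(n, 1.0 / n)
        boosted = base.copy()
        boosted[0] += 1.0
        boosted /= boosted.sum()
        cfg = PropagationConfig(tolerance=1e-12)
        assert rwr(W, boosted, cfg)[0] >= rwr(W, base, cfg)[0]

    def test_invalid_inputs_rejected(self):
        W, _ = column_normalize(PPINetwork(nx.path_graph(["A", "B"])))
        with pytest.raises(ValueError, match="sum to 1"):
            rwr(W, np.array([0.6, 0.6]))
        with pytest.raises(ValueError):
            PropagationConfig(restart_rate=1.0)


class TestBetweenness:
    def test_path_and_star_closed_forms(self):
        path = betweenness(PPINetwork(nx.path_graph(3)), normalized=False)
        assert path[1] == 1.0 and path[0] == 0.0
        star = betweenness(PPINetwork(nx.star_graph(3)), normalized=False)
        assert star[0] == 3.0

    def test_brute_force_enumeration_oracle(self):
        """Exact agreement with all-shortest-paths enumeration on small graphs."""
        rng = np.random.default_rng(5)
        for _ in range(40):
            net = random_connected_graph(rng, n_max=7, n_min=3)
            got = betweenness(net, normalized=False)
            expected = dict.fromkeys(net.nodes, 0.0)
            nodes = net.nodes
            for i, s in enumerate(nodes):
                for t in nodes[i + 1:]:
                    paths = list(nx.all_shortest_paths(net.graph, s, t))
                    for v in nodes:
                        if v in (s, t):
                            continue
                        expected[v] += sum(v in p for p in paths) / len(paths)
            for v in nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-12)

    def test_matches_networkx(self):
        rng = np.random.default_rng(6)
        net = random_connected_graph(rng, 30)
        got = betweenness(net, normalized=True)
        ref = nx.betweenness_centrality(net.graph, normalized=True)
        for v in net.nodes:
            assert got[v] == pytest.approx(ref[v], abs=1e-10)

    def test_disconnected_pairs_contribute_zero(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("X", "Y")])
        bc = betweenness(PPINetwork(g), normalized=False)
        assert bc["B"] == 1.0 and bc["X"] == 0.0


class TestKeyGenes:
    def _result(self):
        return pd.DataFrame(
            {
                "gene": list("ABCDE"),
                "log2FC": [2, -1, 1, 0.5, 0],
                "seed": [0.4, 0.3, 0.2, 0.1, 0],
                "probability": [0.4, 0.3, 0.2, 0.08, 0.02],
                "betweenness": [10.0, 0.0, 5.0, 1.0, 8.0],
                "is_deg": [True, True, True, True, False],
            }
        )

    def test_top_on_both_criteria_is_key(self):
        with pytest.warns(UserWarning, match="DEG nodes"):
            out = select_key_genes(self._result(), 0.75, 0.75)
        assert out.set_index("gene").loc["A", "key"]

    def test_leaf_with_top_probability_not_key(self):
        # B: highest-but-one probability, zero betweenness -> fails BC criterion
        with pytest.warns(UserWarning):
            out = select_key_genes(self._result(), 0.5, 0.5)
        assert not out.set_index("gene").loc["B", "key"]

    def test_zero_quantiles_flag_every_deg(self):
        with pytest.warns(UserWarning):
            out = select_key_genes(self._result(), 0.0, 0.0)
        assert out["key"].sum() == 4
        assert not out.set_index("gene").loc["E", "key"]  # not a DEG

    def test_sorted_by_probability_then_bc(self):
        with pytest.warns(UserWarning):
            out = select_key_genes(self._result(), 0.9, 0.9)
        assert list(out["gene"])[:3] == ["A", "B", "C"]


class TestPropagateDEGs:
    def test_end_to_end_columns_and_conservation(self):
        net = PPINetwork(nx.path_graph(["A", "B", "C", "D"]))
        de = de_table([("A", 2.0, 0.01), ("D", -1.0, 0.02), ("B", 0.1, 0.8)])
        res = propagate_degs(de, net)
        assert abs(res["probability"].sum() - 1.0) < 1e-9
        assert res.loc[res["gene"] == "B", "is_deg"].item() is False

    def test_signed_split_averages_two_walks(self):
        net = PPINetwork(nx.path_graph(["A", "B", "C", "D"]))
        de = de_table([("A", 2.0, 0.01), ("D", -1.0, 0.02)])
        cfg = PropagationConfig(seed_transform="signed-split")
        res = propagate_degs(de, net, cfg)
        assert abs(res["probability"].sum() - 1.0) < 1e-9
        up = propagate_degs(de_table([("A", 2.0, 0.01)]), net)
        down = propagate_degs(de_table([("D", -1.0, 0.02)]), net)
        np.testing.assert_allclose(
            res["probability"], (up["probability"] + down["probability"]) / 2, atol=1e-9
        )
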