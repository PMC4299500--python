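"""Tests of the spectral clustering tree, modularity parsing, module graph."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dcnet.modules import (
    ModulePartition,
    annotate_direction,
    build_clustering_tree,
    cluster_score,
    module_enrichment,
    module_graph,
    parse_modules,
    partition_modularity,
    shared_overrep,
)
from dcnet.network import DCNetwork
from dcnet.simulate import planted_partition_network


def two_cliques(bridge=True):
    g = nx.Graph()
    for base in (0, 5):
        for i, j in itertools.combinations(range(5), 2):
            g.add_edge(base + i, base + j)
    if bridge:
        g.add_edge(0, 5)
    return g


def enumerate_tree_cuts(node, min_size, max_size):
    """All tree-consistent module selections (exhaustive oracle)."""
    options = []
    if min_size <= len(node.genes) <= max_size:
        options.append([tuple(sorted(node.genes))])
    if node.is_leaf:
        options.append([])
        return options
    for left in enumerate_tree_cuts(node.left, min_size, max_size):
        for right in enumerate_tree_cuts(node.right, min_size, max_size):
            options.append(left + right)
    return options


class TestClusteringTree:
    def test_two_cliques_first_split(self):
        tree = build_clustering_tree(two_cliques())
        sides = {frozenset(tree.left.genes), frozenset(tree.right.genes)}
        assert sides == {frozenset(range(5)), frozenset(range(5, 10))}

    def test_complete_graph_tree_valid(self):
        g = nx.complete_graph(8)
        tree = build_clustering_tree(g)
        leaves = sorted(leaf.genes[0] for leaf in tree.leaves())
        assert leaves == list(range(8))

    def test_disconnected_components_split_first(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("x", "y"), ("y", "z"), ("z", "w")])
        tree = build_clustering_tree(g)
        sides = {frozenset(tree.left.genes), frozenset(tree.right.genes)}
        assert sides == {frozenset("abc"), frozenset("xyzw")}

    def test_deterministic(self):
        net, _ = planted_partition_network([12, 15], seed=4)
        t1 = build_clustering_tree(net)
        t2 = build_clustering_tree(net)

        def shape(n):
            if n.is_leaf:
                return n.genes
            return (shape(n.left), shape(n.right))

        assert shape(t1) == shape(t2)


class TestParseModules:
    def test_two_cliques_exact_modularity(self):
        g = two_cliques()
        tree = build_clustering_tree(g)
        part = parse_modules(tree, g, min_size=2, max_size=100)
        assert set(part.modules.values()) == {
            frozenset(range(5)), frozenset(range(5, 10)),
        }
        # Newman modularity of the two-clique split: 2 * (10/21 - 0.25)
        assert sum(part.module_scores.values()) == pytest.approx(0.45238, abs=1e-5)

    def test_cliques_below_min_size_unassigned(self):
        g = two_cliques()
        tree = build_clustering_tree(g)
        with pytest.warns(UserWarning, match="size bounds"):
            part = parse_modules(tree, g, min_size=10, max_size=100)
        assert part.modules == {}

    def test_planted_modules_recovered(self):
        net, truth_modules = planted_partition_network(
            [20, 20], p_in=0.5, p_out=0.01, seed=7
        )
        tree = build_clustering_tree(net)
        part = parse_modules(tree, net, min_size=10, max_size=100)
        assert len(part.modules) == 2
        # best-match agreement with the planted assignment >= 90%
        agree = 0
        for found in part.modules.values():
            agree += max(len(found & t) for t in truth_modules)
        assert agree / sum(len(t) for t in truth_modules) >= 0.9

    def test_oversized_cluster_resplit(self):
        net, _ = planted_partition_network([30, 35], p_in=0.4, p_out=0.02, seed=8)
        tree = build_clustering_tree(net)
        part = parse_modules(tree, net, min_size=10, max_size=32)
        assert all(10 <= s <= 32 for s in part.sizes().values())

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_tree_cut_optimum(self, seed):
        """On graphs <= 12 nodes the DP equals brute-force enumeration."""
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(rng.integers(6, 13), 0.35, seed=int(seed))
        if g.number_of_edges() == 0:
            return
        g = nx.relabel_nodes(g, {n: f"n{n}" for n in g.nodes})
        tree = build_clustering_tree(g)
        part = parse_modules(tree, g, min_size=2, max_size=100)
        best = max(
            partition_modularity(sel, g)
            for sel in enumerate_tree_cuts(tree, 2, 100)
        )
        got = partition_modularity(part.modules.values(), g)
        assert got == pytest.approx(max(best, 0.0), abs=1e-12)

    def test_numbering_by_score(self):
        net, _ = planted_partition_network([15, 25, 20], p_in=0.5, p_out=0.01, seed=9)
        tree = build_clustering_tree(net)
        part = parse_modules(tree, net, min_size=10, max_size=100)
        scores = [part.module_scores[f"M{k + 1}"] for k in range(len(part.modules))]
        assert scores == sorted(scores, reverse=True)


def _toy_partition():
    assignment = {f"a{k}": "M1" for k in range(6)}
    assignment.update({f"b{k}": "M2" for k in range(6)})
    modules = {
        "M1": frozenset(f"a{k}" for k in range(6)),
        "M2": frozenset(f"b{k}" for k in range(6)),
    }
    return ModulePartition(assignment, {"M1": 0.2, "M2": 0.1}, modules)


def _pairs_frame(rows):
    return DCNetwork(pd.DataFrame(
        [{"gene_i": a, "gene_j": b, "direction": d, "q": 9.0} for a, b, d in rows]
    ))


class TestModuleGraph:
    def test_single_module_self_loop(self):
        part = _toy_partition()
        dc = _pairs_frame([("a0", "a1", "GOC"), ("a2", "a3", "GOC")])
        mg = module_graph(part, dc, shared=None, min_edge_pairs=1)
        self_loops = mg.edges[mg.edges["module_a"] == mg.edges["module_b"]]
        assert len(self_loops) == 1
        assert int(self_loops["weight"].iloc[0]) == 2

    def test_inter_module_weight_and_shared_fraction(self):
        part = _toy_partition()
        inter = [(f"a{k}", f"b{k % 6}", "GOC") for k in range(6)] + [
            (f"a{(k + 1) % 6}", f"b{k}", "LOC") for k in range(6)
        ]
        dc = _pairs_frame(inter)
        shared = _pairs_frame(inter[:3])
        mg = module_graph(part, dc, shared, min_edge_pairs=20)
        edge = mg.edges.iloc[0]
        assert edge["weight"] == 12
        assert edge["shared_fraction"] == pytest.approx(3 / 12)
        assert not edge["exported"]  # 12 < 20 suppressed from the export view

    def test_weight_conservation(self):
        net, _ = planted_partition_network([15, 20], p_in=0.5, p_out=0.05, seed=10)
        tree = build_clustering_tree(net)
        part = parse_modules(tree, net, min_size=10, max_size=100)
        mg = module_graph(part, net, shared=None, min_edge_pairs=5)
        assigned = sum(
            1 for row in net.pairs.itertuples(index=False)
            if row.gene_i in part.assignment and row.gene_j in part.assignment
        )
        assert mg.total_weight() == assigned


class TestAnnotateDirection:
    def test_majority_and_tie(self):
        part = _toy_partition()
        dc = _pairs_frame(
            [("a0", "a1", "GOC"), ("a2", "a3", "GOC"),
             ("b0", "b1", "LOC"), ("b2", "b3", "LOC"), ("b4", "b5", "GOC")]
        )
        labels = annotate_direction(part, dc)
        assert labels["M1"] == "GOC" and labels["M2"] == "LOC"
        tie = _pairs_frame([("a0", "a1", "GOC"), ("a2", "a3", "LOC")])
        with pytest.warns(UserWarning, match="tie"):
            labels = annotate_direction(part, tie)
        assert labels["M1"] == "LOC"


class TestSharedOverrep:
    def test_exact_tail_sum(self):
        """All shared pairs in one module: p matches direct summation."""
        import math

        part = _toy_partition()
        intra = [("a0", "a1", "GOC"), ("a1", "a2", "GOC"), ("a3", "a4", "GOC"),
                 ("b0", "b1", "LOC"), ("b1", "b2", "LOC")]
        dc = _pairs_frame(intra)
        shared = _pairs_frame(intra[:2])  # both shared pairs inside M1
        out = shared_overrep(part, dc, shared)
        # universe 5 intra pairs, 2 shared, module M1 holds 3 pairs
        expected = sum(
            math.comb(2, k) * math.comb(3, 3 - k) for k in (2,)
        ) / math.comb(5, 3)
        assert out["M1"][0] == pytest.approx(expected, rel=1e-12)

    def test_single_module_bh_identity(self):
        part = ModulePartition(
            {f"a{k}": "M1" for k in range(6)}, {"M1": 0.2},
            {"M1": frozenset(f"a{k}" for k in range(6))},
        )
        dc = _pairs_frame([("a0", "a1", "GOC"), ("a2", "a3", "GOC")])
        shared = _pairs_frame([("a0", "a1", "GOC")])
        out = shared_overrep(part, dc, shared)
        raw, adj = out["M1"]
        assert raw == adj

    def test_proportional_distribution_not_significant(self):
        part = _toy_partition()
        intra = [(f"a{k}", f"a{(k + 1) % 6}", "GOC") for k in range(6)] + [
            (f"b{k}", f"b{(k + 1) % 6}", "LOC") for k in range(6)
        ]
        dc = _pairs_frame(intra)
        shared = _pairs_frame([intra[0], intra[6]])  # one shared pair per module
        out = shared_overrep(part, dc, shared)
        assert all(adj > 0.05 for _, adj in out.values())


class TestModuleEnrichment:
    def test_module_equals_set_minimal_p(self):
        import math

        part = _toy_partition()
        universe = set(part.assignment) | {f"u{k}" for k in range(8)}
        sets = {"hit": set(part.modules["M1"]), "misc": {"u0", "u1"}}
        table = module_enrichment(part, sets, universe)
        row = table[(table["module"] == "M1") & (table["gene_set"] == "hit")].iloc[0]
        expected = 1.0 / math.comb(20, 6)  # draw the set exactly
        assert row["p"] == pytest.approx(expected, rel=1e-9)
        assert row["p_bonferroni"] == pytest.approx(min(1.0, expected * 2), rel=1e-9)

    def test_empty_set_skipped_with_warning(self):
        part = _toy_partition()
        universe = set(part.assignment)
        with pytest.warns(UserWarning, match="skipped"):
            table = module_enrichment(part, {"outside": {"zz1", "zz2"}}, universe)
        assert len(table) == 0

    def test_universe_restriction(self):
        part = _toy_partition()
        universe = set(part.assignment)
        sets = {"mixed": {"a0", "a1", "zz9"}}
        table = module_enrichment(part, sets, universe)
        assert int(table["set_size"].iloc[0]) == 2  # unmeasured gene excluded
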