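import itertools

import networkx as nx
import numpy as np
import pytest

from odorcascade.communities import (
    OdorGraph,
    OdorPartition,
    assign_molecule_communities,
    build_odor_graph,
    greedy_modularity_partition,
    modularity,
)
from odorcascade.io import MoleculeRecord


def graph_from_edges(edges, extra_nodes=()):
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    return OdorGraph(g)


TWO_TRIANGLES = graph_from_edges(
    [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]
)
TRIANGLE = graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")])


def exhaustive_best_partition(graph):
    """Brute-force modularity maximum over all set partitions of the nodes."""
    nodes = graph.nodes

    def partitions(collection):
        if len(collection) == 1:
            yield [collection]
            return
        first, rest = collection[0], collection[1:]
        for smaller in partitions(rest):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
            yield [[first]] + smaller

    best_q, best = -np.inf, None
    for part in partitions(list(nodes)):
        assignment = {n: i for i, block in enumerate(part) for n in block}
        q = modularity(graph, OdorPartition(assignment))
        if q > best_q:
            best_q, best = q, assignment
    return best_q, best


class TestBuildOdorGraph:
    def test_single_pair(self):
        g = build_odor_graph([MoleculeRecord("m1", "C", {"sweet", "caramel"})])
        assert set(g.graph.edges) == {("caramel", "sweet")} or set(
            g.graph.edges
        ) == {("sweet", "caramel")}
        assert g.graph["sweet"]["caramel"]["weight"] == 1

    def test_shared_label_no_transitive_edge(self):
        g = build_odor_graph(
            [
                MoleculeRecord("m1", "C", {"a", "b"}),
                MoleculeRecord("m2", "C", {"b", "c"}),
            ]
        )
        assert g.graph.has_edge("a", "b") and g.graph.has_edge("b", "c")
        assert not g.graph.has_edge("a", "c")

    def test_isolated_labels(self):
        g = build_odor_graph(
            [MoleculeRecord("m1", "C", {"a"}), MoleculeRecord("m2", "C", {"b"})]
        )
        assert g.m == 0 and set(g.graph.nodes) == {"a", "b"}

    def test_requires_some_labels(self):
        with pytest.raises(ValueError, match="odor label"):
            build_odor_graph([MoleculeRecord("m1", "C", set())])

    def test_co_annotation_counts_accumulate(self):
        g = build_odor_graph(
            [
                MoleculeRecord("m1", "C", {"a", "b"}),
                MoleculeRecord("m2", "C", {"a", "b"}),
            ]
        )
        assert g.graph["a"]["b"]["weight"] == 2


class TestModularity:
    def test_one_community_is_zero(self):
        part = OdorPartition({n: 1 for n in TWO_TRIANGLES.nodes})
        assert modularity(TWO_TRIANGLES, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles_natural_split(self):
        part = OdorPartition({n: (1 if n in "abc" else 2) for n in "abcdef"})
        assert modularity(TWO_TRIANGLES, part) == pytest.approx(0.5)

    def test_triangle_singletons(self):
        part = OdorPartition({"a": 1, "b": 2, "c": 3})
        assert modularity(TRIANGLE, part) == pytest.approx(-1 / 3)

    def test_edgeless_graph_undefined(self):
        g = graph_from_edges([], extra_nodes=["a", "b"])
        with pytest.raises(ValueError, match="edgeless"):
            modularity(g, OdorPartition({"a": 1, "b": 1}))

    def test_uncovered_node_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            modularity(TRIANGLE, OdorPartition({"a": 1, "b": 1}))

    def test_weighted_reduces_to_unweighted_on_unit_weights(self):
        part = OdorPartition({n: (1 if n in "abc" else 2) for n in "abcdef"})
        assert modularity(TWO_TRIANGLES, part, weighted=True) == pytest.approx(
            modularity(TWO_TRIANGLES, part)
        )

    def test_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            og = OdorGraph(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
            assignment = {n: int(rng.integers(3)) for n in og.nodes}
            blocks = {}
            for n, c in assignment.items():
                blocks.setdefault(c, set()).add(n)
            expected = nx.community.modularity(og.graph, blocks.values())
            assert modularity(og, OdorPartition(assignment)) == pytest.approx(
                expected, abs=1e-12
            )


class TestGreedyPartition:
    def test_two_triangles_recovered(self):
        part = greedy_modularity_partition(TWO_TRIANGLES)
        assert part.n_communities == 2
        assert len({part.community_of[n] for n in "abc"}) == 1
        assert len({part.community_of[n] for n in "def"}) == 1
        assert part.q == pytest.approx(0.5)

    def test_single_edge_merges_over_singletons(self):
        g = graph_from_edges([("a", "b")])
        part = greedy_modularity_partition(g)
        assert part.n_communities == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError, match="edgeless"):
            greedy_modularity_partition(graph_from_edges([], extra_nodes=["a"]))

    def test_isolated_nodes_stay_singletons(self):
        g = graph_from_edges([("a", "b"), ("b", "c"), ("a", "c")],
                             extra_nodes=["z"])
        part = greedy_modularity_partition(g)
        assert part.community_of["z"] not in {
            part.community_of["a"], part.community_of["b"], part.community_of["c"]
        }

    def test_community_indices_ordered_by_size(self):
        g = graph_from_edges(
            list(itertools.combinations("abcd", 2))
            + [("x", "y"), ("y", "z"), ("x", "z")]
        )
        part = greedy_modularity_partition(g)
        assert {part.community_of[n] for n in "abcd"} == {1}
        assert {part.community_of[n] for n in "xyz"} == {2}

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(12, 0.3, seed=7)
        og = OdorGraph(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
        a = greedy_modularity_partition(og)
        b = greedy_modularity_partition(og)
        assert a.community_of == b.community_of and a.q == b.q

    def test_incremental_q_matches_recomputation(self):
        """The dQ bookkeeping agrees with the direct double sum after every merge."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 21))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            og = OdorGraph(nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes}))
            trace = []
            greedy_modularity_partition(og, trace=trace)
            state = {n: n for n in og.nodes}
            for (u, v), q_incr in trace:
                for node, rep in state.items():
                    if rep == v:
                        state[node] = u
                q_direct = modularity(
                    og, OdorPartition({n: hash(r) for n, r in state.items()})
                )
                assert q_incr == pytest.approx(q_direct, abs=1e-9)

    def test_matches_networkx_cnm_quality(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = nx.gnp_random_graph(10, 0.35, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            og = OdorGraph(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
            ours = greedy_modularity_partition(og)
            nx_comms = nx.community.greedy_modularity_communities(og.graph)
            nx_q = nx.community.modularity(og.graph, nx_comms)
            assert ours.q >= nx_q - 1e-9

    def test_monotone_q_across_merges(self):
        g = nx.gnp_random_graph(15, 0.25, seed=5)
        og = OdorGraph(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
        trace = []
        greedy_modularity_partition(og, trace=trace)
        qs = [q for _, q in trace]
        assert all(b > a for a, b in zip(qs, qs[1:]))


class TestGreedyVsExhaustive:
    def test_two_node_path_enumeration(self):
        g = graph_from_edges([("a", "b")])
        best_q, _ = exhaustive_best_partition(g)
        assert best_q == pytest.approx(0.0, abs=1e-12)
        assert greedy_modularity_partition(g).q == pytest.approx(best_q, abs=1e-12)

    def test_exact_on_disjoint_cliques(self):
        for sizes in [(3, 3), (3, 4), (4, 4)]:
            edges, offset = [], 0
            truth = {}
            for ci, s in enumerate(sizes):
                names = [f"c{ci}n{j}" for j in range(s)]
                edges += list(itertools.combinations(names, 2))
                truth.update({n: ci for n in names})
            og = graph_from_edges(edges)
            part = greedy_modularity_partition(og)
            mapped = {}
            for n, c in part.community_of.items():
                mapped.setdefault(truth[n], set()).add(c)
            assert all(len(v) == 1 for v in mapped.values())
            assert len({next(iter(v)) for v in mapped.values()}) == len(sizes)


class TestAssignment:
    def make_partition(self):
        return OdorPartition(
            {f"o{i}": 1 for i in range(9)} | {"p0": 2}
            | {f"q{i}": c for i, c in zip(range(5), [3, 4, 5, 6, 7])}
        )

    def test_majority_rule_drops_minor_community(self):
        part = self.make_partition()
        mol = MoleculeRecord("m", "C", {f"o{i}" for i in range(9)} | {"p0"})
        assert assign_molecule_communities(mol, part) == {1}

    def test_even_split_keeps_both(self):
        part = OdorPartition({"a": 1, "b": 2})
        mol = MoleculeRecord("m", "C", {"a", "b"})
        assert assign_molecule_communities(mol, part) == {1, 2}

    def test_five_way_tie_falls_back_to_argmax(self):
        part = OdorPartition({f"q{i}": i + 1 for i in range(5)})
        mol = MoleculeRecord("m", "C", {f"q{i}" for i in range(5)})
        assert assign_molecule_communities(mol, part) == {1}

    def test_unknown_labels_skipped(self):
        part = OdorPartition({"a": 1, "b": 1})
        mol = MoleculeRecord("m", "C", {"a", "b", "mystery"})
        assert assign_molecule_communities(mol, part) == {1}

    def test_no_recognized_labels_empty(self):
        part = OdorPartition({"a": 1})
        mol = MoleculeRecord("m", "C", {"mystery"})
        assert assign_molecule_communities(mol, part) == set()
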