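"""Odor-label co-annotation graph and greedy-modularity community extraction.

Free-text odor notes are noisy and redundant: different annotators describe
the same smell with different words. Instead of string-level synonym merging,
related notes are grouped structurally — two notes are connected whenever at
least one molecule carries both, and communities of the resulting graph are
extracted by agglomerative (Clauset–Newman–Moore style) modularity
maximization. Modularity of a partition is

    Q = (1/2m) * sum_ij [ A_ij - k_i k_j / (2m) ] * delta(C_i, C_j)

with m the total number of edges, A the adjacency matrix, k_i the degrees and
delta the same-community indicator. The default is the unweighted (0/1
adjacency) form; a ``weighted`` flag switches every quantity to the
co-annotation-count weighted generalization.

Molecules are then mapped to communities of their own labels with a majority
rule: only communities holding strictly more than 20% of a molecule's labels
are kept, so a molecule with nine labels in one community and one stray label
elsewhere is treated as having a single odor community.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class OdorGraph:
    """Odor-label co-annotation graph backed by a networkx Graph.

    Nodes are odor labels; an edge's integer weight counts the molecules
    annotated with both endpoint labels. No self-loops.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("odor graph must not contain self-loops")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def m(self) -> int:
        """Total number of edges (unweighted)."""
        return self.graph.number_of_edges()

    @property
    def total_weight(self) -> float:
        return sum(d.get("weight", 1) for _, _, d in self.graph.edges(data=True))

    def adjacency(self, weighted: bool = False) -> tuple[list[str], np.ndarray]:
        nodes = self.nodes
        a = nx.to_numpy_array(
            self.graph, nodelist=nodes, weight="weight" if weighted else None
        )
        return nodes, a


@dataclass
class OdorPartition:
    """A community assignment over the odor-label vocabulary."""

    community_of: dict[str, int]
    q: float = float("nan")

    @property
    def n_communities(self) -> int:
        return len(set(self.community_of.values()))

    def members(self, community: int) -> set[str]:
        return {n for n, c in self.community_of.items() if c == community}

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for n, c in self.community_of.items():
            out.setdefault(c, set()).add(n)
        return out

    def to_csv(self, path) -> None:
        pd.DataFrame(
            sorted(self.community_of.items()),
            columns=["odor_label", "community_index"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OdorPartition":
        df = pd.read_csv(path, dtype={"odor_label": str, "community_index": int})
        return cls({r.odor_label: int(r.community_index) for r in df.itertuples()})


def build_odor_graph(molecules: Sequence) -> OdorGraph:
    """Build the co-annotation graph from molecules carrying odor-label sets.

    A node per distinct label; an edge between two labels iff at least one
    molecule carries both, weighted by the number of such molecules.
    """
    g = nx.Graph()
    any_labeled = False
    for m in molecules:
        labels = sorted(m.odor_labels)
        if labels:
            any_labeled = True
        g.add_nodes_from(labels)
        for u, v in itertools.combinations(labels, 2):
            if g.has_edge(u, v):
                g[u][v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    if not any_labeled:
        raise ValueError("no molecule carries any odor label")
    return OdorGraph(g)


def modularity(
    graph: OdorGraph, partition: OdorPartition, weighted: bool = False
) -> float:
    """Modularity Q of a partition, evaluated by the direct double sum.

    Unweighted by default (0/1 adjacency, degree = edge count); with
    ``weighted=True`` the adjacency carries co-annotation counts and degrees
    are strength sums.
    """
    nodes, a = graph.adjacency(weighted=weighted)
    uncovered = [n for n in nodes if n not in partition.community_of]
    if uncovered:
        raise ValueError(f"partition does not cover nodes: {uncovered[:5]}")
    two_m = a.sum()
    if two_m == 0:
        raise ValueError("modularity is undefined on an edgeless graph (m = 0)")
    k = a.sum(axis=1)
    comm = np.array([partition.community_of[n] for n in nodes])
    delta = comm[:, None] == comm[None, :]
    return float(((a - np.outer(k, k) / two_m) * delta).sum() / two_m)


def greedy_modularity_partition(
    graph: OdorGraph,
    weighted: bool = False,
    trace: Optional[list] = None,
) -> OdorPartition:
    """Agglomerative greedy modularity maximization.

    Starts from singleton communities and repeatedly merges the community
    pair with the largest modularity gain dQ, stopping when no merge has
    dQ > 0. Equal-gain merges are broken by the lexicographically smallest
    (community representative) label pair, making the result deterministic.
    Community indices in the returned partition are renumbered 1..n by
    descending community size (ties by smallest member label). Isolated
    labels end as singleton communities.

    If ``trace`` is a list, a (merged_pair, Q_after_merge) tuple is appended
    after every accepted merge, supporting incremental-vs-recomputed
    cross-checks.
    """
    nodes, a = graph.adjacency(weighted=weighted)
    two_m = a.sum()
    if two_m == 0:
        raise ValueError("cannot partition an edgeless graph (m = 0)")
    k = a.sum(axis=1)

    # community state: representative label -> member indices, degree sum,
    # and pairwise inter-community weights
    members: dict[str, list[int]] = {n: [i] for i, n in enumerate(nodes)}
    tot: dict[str, float] = {n: float(k[i]) for i, n in enumerate(nodes)}
    between: dict[frozenset, float] = {}
    for i, j in zip(*np.nonzero(np.triu(a, 1))):
        between[frozenset((nodes[i], nodes[j]))] = float(a[i, j])

    # Q relative to the singleton start; absolute Q tracked for the trace
    q = -float(np.sum(k**2)) / two_m**2

    while True:
        best_gain = 0.0
        best_pair: Optional[tuple[str, str]] = None
        for pair, w in between.items():
            u, v = sorted(pair)
            gain = 2.0 * (w / two_m - tot[u] * tot[v] / two_m**2)
            if gain > best_gain + 1e-15 or (
                best_pair is not None
                and abs(gain - best_gain) <= 1e-15
                and (u, v) < best_pair
            ):
                best_gain = gain
                best_pair = (u, v)
        if best_pair is None or best_gain <= 0.0:
            break
        u, v = best_pair
        # merge v into u
        members[u].extend(members.pop(v))
        tot[u] += tot.pop(v)
        q += best_gain
        merged_between: dict[frozenset, float] = {}
        for pair, w in between.items():
            repl = frozenset(u if x == v else x for x in pair)
            if len(repl) == 1:
                continue  # the merged pair's internal edge
            merged_between[repl] = merged_between.get(repl, 0.0) + w
        between = merged_between
        if trace is not None:
            trace.append(((u, v), q))

    # renumber by descending size, ties by smallest member label
    ordered = sorted(
        members.items(), key=lambda kv: (-len(kv[1]), min(nodes[i] for i in kv[1]))
    )
    community_of = {
        nodes[i]: idx for idx, (_, idxs) in enumerate(ordered, start=1) for i in idxs
    }
    part = OdorPartition(community_of)
    part.q = q
    return part


def assign_molecule_communities(
    molecule,
    partition: OdorPartition,
    threshold: float = 0.20,
) -> set[int]:
    """Map a molecule's odor labels to its majority odor communities.

    The molecule's recognized labels are tallied per community; communities
    holding a share strictly greater than ``threshold`` (default 20%) of the
    labels are kept. If no community clears the threshold (a degenerate
    many-way tie), the single largest community is kept, ties broken by the
    smallest community index. Labels absent from the partition are skipped
    with a log message; a molecule with no recognized labels yields the empty
    set with a warning.
    """
    counts: dict[int, int] = {}
    n_recognized = 0
    for label in sorted(molecule.odor_labels):
        c = partition.community_of.get(label)
        if c is None:
            logger.info(
                "%s: odor label %r not in partition; skipped",
                molecule.molecule_id, label,
            )
            continue
        counts[c] = counts.get(c, 0) + 1
        n_recognized += 1
    if n_recognized == 0:
        logger.warning("%s: no recognized odor labels", molecule.molecule_id)
        return set()
    kept = {c for c, n in counts.items() if n / n_recognized > threshold}
    if not kept:
        best = min(counts, key=lambda c: (-counts[c], c))
        kept = {best}
    return kept


def export_edge_list(graph: OdorGraph, path) -> None:
    rows = [
        (u, v, d.get("weight", 1))
        for u, v, d in sorted(graph.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["label_a", "label_b", "weight"]).to_csv(
        path, index=False
    )
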