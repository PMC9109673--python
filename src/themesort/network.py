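"""Weighted quote co-occurrence network.

The edge weight w_ij between quotes i and j counts the raters who placed
both quotes in the same group, so 0 <= w_ij <= R. Every corpus quote is a
node, including quotes no rater paired with anything (they must surface
downstream as singleton themes rather than silently vanish). Quotes a rater
left unassigned simply contribute no pairs for that rater.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx

from .corpus import SortStudy
from .errors import ConfigError


@dataclass
class CooccurrenceNetwork:
    """Symmetric integer-weighted graph over quote ids.

    Backed by a ``networkx.Graph`` storing only positive-weight edges;
    zero-weight pairs are implicit.
    """

    graph: nx.Graph
    n_raters: int

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def weight(self, i: int, j: int) -> int:
        if i == j:
            raise ConfigError("self-weights are undefined (no self-loops)")
        if self.graph.has_edge(i, j):
            return int(self.graph[i][j]["weight"])
        return 0

    def strength(self, i: int) -> int:
        """Weighted degree s_i = sum_j w_ij."""
        return int(sum(d["weight"] for _, _, d in self.graph.edges(i, data=True)))

    @property
    def total_weight(self) -> int:
        """m = half the sum of strengths = sum of edge weights."""
        return int(self.graph.size(weight="weight"))


def build_network(study: SortStudy) -> CooccurrenceNetwork:
    """Count, for every unordered quote pair, the raters grouping them together.

    An empty study yields an empty network with a warning. Nodes come from
    the corpus, so isolated quotes are retained.
    """
    graph = nx.Graph()
    graph.add_nodes_from(sorted(study.corpus.quote_ids))
    if study.corpus.n_quotes == 0 or study.n_raters == 0:
        warnings.warn("building co-occurrence network from an empty study", stacklevel=2)
    for sort in study.sorts:
        for members in sort.groups.values():
            for i, j in combinations(sorted(members), 2):
                if graph.has_edge(i, j):
                    graph[i][j]["weight"] += 1
                else:
                    graph.add_edge(i, j, weight=1)
    return CooccurrenceNetwork(graph=graph, n_raters=study.n_raters)


def from_weights(weights: dict[tuple[int, int], int], nodes=None, n_raters: int = 0) -> CooccurrenceNetwork:
    """Build a network directly from a pair->weight mapping (for tests/tools)."""
    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(sorted(nodes))
    for (i, j), w in sorted(weights.items()):
        if i == j:
            raise ConfigError("self-loops are not allowed")
        if w < 0:
            raise ConfigError("weights must be non-negative")
        graph.add_node(i)
        graph.add_node(j)
        if w > 0:
            graph.add_edge(i, j, weight=int(w))
    return CooccurrenceNetwork(graph=graph, n_raters=n_raters)


def export_network(
    net: CooccurrenceNetwork,
    fmt: str,
    path: str | Path,
    partition=None,
) -> None:
    """Write the network as ``graphml`` or ``edge-tsv``.

    GraphML carries the integer ``weight`` edge attribute and, when a
    partition is given, a ``community`` node attribute. The TSV edge list
    has header ``source\\ttarget\\tweight`` with zero-weight pairs omitted
    and rows sorted, so output is byte-stable across runs.
    """
    path = Path(path)
    if fmt == "graphml":
        graph = nx.Graph()
        graph.add_nodes_from(sorted(net.graph.nodes))
        for i, j in sorted((min(u, v), max(u, v)) for u, v in net.graph.edges):
            graph.add_edge(i, j, weight=int(net.graph[i][j]["weight"]))
        if partition is not None:
            assignment = getattr(partition, "assignment", partition)
            for node in graph.nodes:
                if node in assignment:
                    graph.nodes[node]["community"] = str(assignment[node])
        nx.write_graphml(graph, path)
    elif fmt == "edge-tsv":
        if net.n_nodes == 0:
            raise ConfigError("cannot write an edge list for an empty network")
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["source", "target", "weight"])
            for i, j in sorted((min(u, v), max(u, v)) for u, v in net.graph.edges):
                writer.writerow([i, j, int(net.graph[i][j]["weight"])])
    else:
        raise ConfigError(f"unknown network export format {fmt!r} (use graphml or edge-tsv)")
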