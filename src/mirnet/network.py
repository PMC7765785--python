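"""Tissue-filtered target-gene network construction and components.

Nodes are upper-case gene symbols; edges carry the STRING combined score.
Only genes with at least one retained interaction become network nodes;
isolated candidates are reported separately, mirroring the reduction from
"targets expressed in the tissue" to "targets with at least one connection".
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .exceptions import EmptyNetworkError, NoExpressedTargetsError
from .io_sources import EdgeTable, ExpressedGeneSet, TargetGeneSet


@dataclass
class NetworkBuild:
    """A constructed gene network plus the candidates it excluded."""

    graph: nx.Graph
    candidates: frozenset[str]
    isolated: tuple[str, ...]  # sorted candidates with no retained edge

    @property
    def n_isolated(self) -> int:
        return len(self.isolated)


def build_network(
    targets: TargetGeneSet, expressed: ExpressedGeneSet, edges: EdgeTable
) -> NetworkBuild:
    """Interaction network of the miRNA targets expressed in the tissue.

    Candidate nodes are ``targets & expressed``; an edge is retained when
    both endpoints are candidates; candidates left with degree zero are
    excluded from the graph but listed in the result.  An empty candidate
    intersection is an error; an all-isolated candidate set is not.
    """
    candidates = frozenset(targets.genes) & frozenset(expressed.genes)
    if not candidates:
        raise NoExpressedTargetsError(
            f"no targets of {targets.mirna_id} are expressed in {expressed.tissue!r}"
        )
    graph = nx.Graph()
    for a, b, score in edges.records():
        if a in candidates and b in candidates:
            graph.add_edge(a, b, score=int(score))
    # deterministic node order for downstream serialization
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(graph.nodes))
    ordered.add_edges_from(
        sorted((min(a, b), max(a, b)) for a, b in graph.edges)
    )
    for a, b in ordered.edges:
        ordered.edges[a, b]["score"] = graph.edges[a, b]["score"]
    isolated = tuple(sorted(candidates - set(ordered.nodes)))
    return NetworkBuild(graph=ordered, candidates=candidates, isolated=isolated)


@dataclass
class ComponentSummary:
    """Connected components in deterministic order.

    Components are sorted by size (descending), ties broken by the
    lexicographically smallest member; the LCC is component 0.
    """

    components: tuple[tuple[str, ...], ...]
    n_isolated: int = 0

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.components)

    @property
    def lcc_index(self) -> int:
        return 0

    @property
    def lcc_size(self) -> int:
        return len(self.components[0]) if self.components else 0


def connected_components(graph: nx.Graph) -> ComponentSummary:
    """Standard undirected components with deterministic ordering."""
    comps = [tuple(sorted(c)) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    n_isolated = sum(1 for n in graph.nodes if graph.degree[n] == 0)
    return ComponentSummary(components=tuple(comps), n_isolated=n_isolated)


def largest_connected_component(graph: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component (ties broken as above)."""
    if graph.number_of_nodes() == 0:
        raise EmptyNetworkError("cannot extract the LCC of an empty network")
    summary = connected_components(graph)
    members = summary.components[0]
    sub = graph.subgraph(members)
    out = nx.Graph()
    out.add_nodes_from(sorted(sub.nodes))
    out.add_edges_from(sorted((min(a, b), max(a, b)) for a, b in sub.edges))
    for a, b in out.edges:
        out.edges[a, b].update(sub.edges[a, b])
    return out
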