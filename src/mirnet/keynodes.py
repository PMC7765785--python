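"""Combined-centrality ranking and plateau-based key-node selection.

The centrality of a node is the additive sum of its normalized shortest-path
betweenness and its degree centrality (both on [0, 1], so the sum lies on
[0, 2]).  Nodes of the intact LCC are ranked once by this combined score;
the disintegration curve f(n) records the LCC cardinality after removing
the top-n ranked nodes, and the key nodes are the minimal prefix at which
f plateaus (forward difference zero) below half the original LCC size.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .exceptions import DisconnectedGraphError, EmptyNetworkError, MirnetError


@dataclass
class CentralityTable:
    """Per-gene centralities on one connected component.

    ``table`` is indexed by gene with columns ``betweenness``,
    ``degree_centrality``, ``combined`` and ``rank`` (0-based position in
    the removal ordering); ``ordering`` lists genes by combined centrality
    descending, ties broken lexicographically.
    """

    table: pd.DataFrame
    ordering: tuple[str, ...]

    def combined(self, gene: str) -> float:
        return float(self.table.at[gene, "combined"])


def node_centrality(lcc: nx.Graph) -> CentralityTable:
    """Betweenness + degree centrality of every node of a connected graph.

    Betweenness uses the standard undirected normalization
    2/((N-1)(N-2)) (defined as 0 when N <= 2); degree centrality is
    degree/(N-1).
    """
    n = lcc.number_of_nodes()
    if n < 2:
        raise EmptyNetworkError("centrality needs a graph with >= 2 nodes")
    if not nx.is_connected(lcc):
        raise DisconnectedGraphError(
            "graph is disconnected; pass the largest connected component"
        )
    betweenness = nx.betweenness_centrality(lcc, normalized=True)
    degree = nx.degree_centrality(lcc)
    genes = sorted(lcc.nodes)
    table = pd.DataFrame(
        {
            "betweenness": [betweenness[g] for g in genes],
            "degree_centrality": [degree[g] for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    table["combined"] = table["betweenness"] + table["degree_centrality"]
    ordering = tuple(
        sorted(genes, key=lambda g: (-table.at[g, "combined"], g))
    )
    table["rank"] = [ordering.index(g) for g in genes]
    table = table.loc[list(ordering)]
    return CentralityTable(table=table, ordering=ordering)


@dataclass
class DisintegrationCurve:
    """f(n) = |LCC_n| for n = 0..N, removing top-ranked nodes from the intact LCC."""

    n_lcc: int
    f: tuple[int, ...]
    ordering: tuple[str, ...]

    def __post_init__(self):
        if len(self.f) != self.n_lcc + 1:
            raise ValueError("curve must have N_LCC + 1 points")


def _lcc_size(graph: nx.Graph) -> int:
    if graph.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(graph))


def disintegration_curve(lcc: nx.Graph, ordering) -> DisintegrationCurve:
    """LCC cardinality after each successive removal of the ranked nodes.

    Removal is always from the *intact* graph: f(n) is the largest
    component of ``lcc`` minus the first n nodes of ``ordering``.
    """
    ordering = tuple(ordering)
    if sorted(ordering) != sorted(lcc.nodes):
        raise MirnetError("ordering must be a permutation of the graph's nodes")
    n = lcc.number_of_nodes()
    work = lcc.copy()
    # f(0) is the intact largest-component size; for a connected input
    # (the intended LCC) it equals the node count.
    f = [_lcc_size(work)]
    for node in ordering:
        work.remove_node(node)
        f.append(_lcc_size(work))
    return DisintegrationCurve(n_lcc=n, f=tuple(f), ordering=ordering)


@dataclass
class KeyNodeResult:
    """Outcome of plateau-based key-node selection."""

    n_min: int
    key_genes: tuple[str, ...]
    curve: DisintegrationCurve
    plateau_candidates: tuple[int, ...]  # every plateau point examined


def select_key_nodes(curve: DisintegrationCurve, ordering=None) -> KeyNodeResult:
    """Minimal removal prefix at which the curve plateaus below N_LCC/2.

    Scans n = 1, 2, ...: n is a plateau point when the forward difference
    f(n+1) - f(n) is zero (f is extended with zeros beyond N_LCC, where the
    graph is exhausted).  The selected n_min is the smallest plateau point
    with f(n_min) < N_LCC/2; plateau points failing the half-size condition
    are skipped and the scan continues.  The comparison is exact integer
    arithmetic (2*f(n) < N_LCC), never floating point.
    """
    ordering = tuple(ordering) if ordering is not None else curve.ordering
    n_lcc = curve.n_lcc
    if n_lcc < 3:
        raise MirnetError("LCC too small for key-node selection (need >= 3 nodes)")
    f = curve.f
    examined = []
    for n in range(1, n_lcc + 1):
        f_next = f[n + 1] if n + 1 <= n_lcc else 0
        if f_next - f[n] == 0:
            examined.append(n)
            if 2 * f[n] < n_lcc:
                return KeyNodeResult(
                    n_min=n,
                    key_genes=tuple(ordering[:n]),
                    curve=curve,
                    plateau_candidates=tuple(examined),
                )
    raise MirnetError("no qualifying plateau found (malformed curve)")  # pragma: no cover


def find_key_nodes(lcc: nx.Graph, adaptive: bool = False):
    """Centrality -> disintegration curve -> plateau selection, in one call.

    With ``adaptive=True`` the ranking is recomputed on the shrinking graph
    after every removal (off by default: the standard procedure ranks the
    intact LCC once).  Returns ``(KeyNodeResult, CentralityTable)``; the
    table always describes the intact LCC.
    """
    centrality = node_centrality(lcc)
    if not adaptive:
        curve = disintegration_curve(lcc, centrality.ordering)
        return select_key_nodes(curve), centrality

    work = lcc.copy()
    ordering = []
    f = [lcc.number_of_nodes()]
    while work.number_of_nodes() > 0:
        comps = sorted(
            (tuple(sorted(c)) for c in nx.connected_components(work)),
            key=lambda c: (-len(c), c[0]),
        )
        current_lcc = work.subgraph(comps[0])
        if current_lcc.number_of_nodes() >= 2:
            bet = nx.betweenness_centrality(current_lcc, normalized=True)
            deg = nx.degree_centrality(current_lcc)
            pick = min(current_lcc.nodes, key=lambda g: (-(bet[g] + deg[g]), g))
        else:
            pick = min(work.nodes)
        ordering.append(pick)
        work.remove_node(pick)
        f.append(_lcc_size(work))
    curve = DisintegrationCurve(
        n_lcc=lcc.number_of_nodes(), f=tuple(f), ordering=tuple(ordering)
    )
    return select_key_nodes(curve), centrality
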