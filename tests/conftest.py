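"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the code paths they check: components
come from a hand-rolled union-find, betweenness from explicit BFS path
counting, and the hypergeometric tail from subset enumeration.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from mirnet.fixtures import make_toy_databases

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def uf_components(nodes, edges):
    """Union-find connected components; returns list of frozensets."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return [frozenset(g) for g in groups.values()]


def uf_lcc_size(nodes, edges):
    comps = uf_components(nodes, edges)
    return max((len(c) for c in comps), default=0)


def brute_betweenness(graph: nx.Graph) -> dict:
    """Normalized betweenness via explicit BFS shortest-path enumeration."""
    nodes = list(graph.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        # enumerate all shortest s-t paths by BFS layering
        try:
            length = nx.shortest_path_length(graph, s, t)
        except nx.NetworkXNoPath:
            continue
        paths = [
            p for p in nx.all_shortest_paths(graph, s, t)
        ]
        assert all(len(p) - 1 == length for p in paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    if n > 2:
        norm = 2.0 / ((n - 1) * (n - 2))
    else:
        norm = 0.0
    return {v: score[v] * norm for v in nodes}


def enumerate_hypergeom_tail(k, universe_size, set_size, draws) -> Fraction:
    """P(overlap >= k) by enumerating every possible draw of the universe."""
    universe = list(range(universe_size))
    members = set(universe[:set_size])
    hits = 0
    total = 0
    for combo in itertools.combinations(universe, draws):
        total += 1
        if len(members.intersection(combo)) >= k:
            hits += 1
    return Fraction(hits, total)


def random_curve(rng, n_max=40):
    """Random valid disintegration curve: non-increasing, f(0)=N, f(N)=0,
    f(i) <= N - i, with frequent plateaus.  Returns (f, N)."""
    n = int(rng.integers(3, n_max + 1))
    f = [n]
    for i in range(1, n + 1):
        drop = int(rng.integers(0, 3))
        f.append(max(0, min(f[-1] - drop, n - i)))
    return f, n


def reference_select(f, n_lcc):
    """One-line restatement of the plateau rule used as the selection oracle."""
    extended = list(f) + [0]
    candidates = [
        n
        for n in range(1, n_lcc + 1)
        if extended[n + 1] - extended[n] == 0 and Fraction(extended[n]) < Fraction(n_lcc, 2)
    ]
    return min(candidates)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def toy_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("toy_db")
    return make_toy_databases(out, seed=42)


@pytest.fixture(scope="session")
def toy_run(toy_paths, tmp_path_factory):
    """One full pipeline run on the seed-42 toy databases."""
    from mirnet.pipeline import RunConfig, run_pipeline

    out_dir = tmp_path_factory.mktemp("toy_run")
    config = RunConfig(
        mirna_id="hsa-miR-375",
        tissue="heart muscle",
        expression=toy_paths["expression"],
        targets=toy_paths["targets"],
        links=toy_paths["links"],
        aliases=toy_paths["aliases"],
        gmt=toy_paths["gmt"],
        out_dir=str(out_dir),
        n_perm=500,
        seed=42,
    )
    return config, run_pipeline(config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_gene_graph(rng, n_nodes, edge_prob):
    genes = [f"N{i:03d}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            if rng.random() < edge_prob:
                g.add_edge(a, b)
    return g
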