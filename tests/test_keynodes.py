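"""Centrality, disintegration curves, and plateau-based key-node selection."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_betweenness, random_curve, random_gene_graph, reference_select
from mirnet import keynodes as kn
from mirnet.exceptions import DisconnectedGraphError, MirnetError
from mirnet.fixtures import PlantedGraphSpec, make_planted_graph


def path3():
    return nx.Graph([("a", "b"), ("b", "c")])


def star(n_leaves, center="hub"):
    return nx.Graph((center, f"leaf{i}") for i in range(n_leaves))


# ---------------------------------------------------------------------------
# centrality
# ---------------------------------------------------------------------------


def test_path_closed_form():
    table = kn.node_centrality(path3()).table
    assert table.at["b", "combined"] == pytest.approx(2.0)
    assert table.at["b", "betweenness"] == pytest.approx(1.0)
    assert table.at["a", "combined"] == pytest.approx(0.5)


def test_star_closed_form():
    table = kn.node_centrality(star(4)).table
    assert table.at["hub", "combined"] == pytest.approx(2.0)
    for leaf in ("leaf0", "leaf1", "leaf2", "leaf3"):
        assert table.at[leaf, "combined"] == pytest.approx(0.25)


def test_centrality_matches_brute_force_oracle(rng):
    for _ in range(5):
        g = random_gene_graph(rng, 10, 0.35)
        if not nx.is_connected(g):
            continue
        result = kn.node_centrality(g)
        oracle_b = brute_betweenness(g)
        n = g.number_of_nodes()
        for gene in g.nodes:
            expected = oracle_b[gene] + g.degree[gene] / (n - 1)
            assert result.combined(gene) == pytest.approx(expected)


def test_centrality_requires_connected_graph():
    g = nx.Graph([("a", "b"), ("c", "d")])
    with pytest.raises(DisconnectedGraphError):
        kn.node_centrality(g)


def test_ordering_sorted_by_combined_then_symbol(rng):
    g = random_gene_graph(rng, 15, 0.3)
    g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    result = kn.node_centrality(g)
    keys = [(-result.combined(gene), gene) for gene in result.ordering]
    assert keys == sorted(keys)


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_combined_centrality_in_0_2(seed):
    rng = np.random.default_rng(seed)
    g = random_gene_graph(rng, int(rng.integers(2, 25)), 0.25)
    g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    if g.number_of_nodes() < 2:
        return
    table = kn.node_centrality(g).table
    assert ((table["combined"] >= 0) & (table["combined"] <= 2)).all()


# ---------------------------------------------------------------------------
# disintegration curve
# ---------------------------------------------------------------------------


def test_curve_star_removes_center_first():
    g = star(5, center="aaa")
    ordering = ["aaa"] + sorted(n for n in g.nodes if n != "aaa")
    curve = kn.disintegration_curve(g, ordering)
    assert curve.f == (6, 1, 1, 1, 1, 1, 0)


def test_curve_triangle_any_ordering():
    g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
    curve = kn.disintegration_curve(g, ["b", "a", "c"])
    assert curve.f == (3, 2, 1, 0)


def test_curve_bridged_triangles():
    g = nx.Graph(
        [("a", "b"), ("b", "c"), ("a", "c"),
         ("d", "e"), ("e", "f"), ("d", "f"),
         ("h", "a"), ("h", "d")]
    )
    ordering = kn.node_centrality(g).ordering
    # the triangle attachment points a and d carry the most combined
    # centrality (degree 3 plus bridge traffic); the degree-2 hub is third
    assert ordering[:3] == ("a", "d", "h")
    curve = kn.disintegration_curve(g, ordering)
    assert curve.f[:3] == (7, 4, 2)
    # brute-force recomputation after each removal
    for n in range(8):
        h = g.copy()
        h.remove_nodes_from(ordering[:n])
        sizes = [len(c) for c in nx.connected_components(h)]
        assert curve.f[n] == max(sizes, default=0)


def test_curve_rejects_non_permutation():
    g = path3()
    with pytest.raises(MirnetError):
        kn.disintegration_curve(g, ["a", "b"])
    with pytest.raises(MirnetError):
        kn.disintegration_curve(g, ["a", "b", "b"])


@settings(max_examples=40, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_curve_non_increasing_property(seed):
    """Removing nodes can never grow the largest component."""
    rng = np.random.default_rng(seed)
    g = random_gene_graph(rng, int(rng.integers(2, 25)), rng.uniform(0.05, 0.4))
    ordering = list(g.nodes)
    rng.shuffle(ordering)
    curve = kn.disintegration_curve(g, ordering)
    assert curve.f[0] == g.number_of_nodes() if nx.is_connected(g) else True
    assert curve.f[-1] == 0
    assert all(a >= b for a, b in zip(curve.f, curve.f[1:]))


# ---------------------------------------------------------------------------
# key-node selection
# ---------------------------------------------------------------------------


def test_select_star_takes_center():
    curve = kn.DisintegrationCurve(
        n_lcc=6, f=(6, 1, 1, 1, 1, 1, 0),
        ordering=("hub", "l1", "l2", "l3", "l4", "l5"),
    )
    result = kn.select_key_nodes(curve)
    assert result.n_min == 1
    assert result.key_genes == ("hub",)


def test_select_skips_plateau_above_half_size():
    # plateau at n=1 fails f < N/2 (4 >= 3.5); next plateau at n=3 qualifies
    curve = kn.DisintegrationCurve(
        n_lcc=7, f=(7, 4, 4, 2, 2, 1, 1, 0),
        ordering=tuple("abcdefg"),
    )
    result = kn.select_key_nodes(curve)
    assert result.n_min == 3
    assert result.plateau_candidates == (1, 3)
    assert result.key_genes == ("a", "b", "c")


def test_select_strictly_decreasing_curve_takes_terminal_plateau():
    curve = kn.DisintegrationCurve(n_lcc=3, f=(3, 2, 1, 0), ordering=("a", "b", "c"))
    assert kn.select_key_nodes(curve).n_min == 3


def test_select_small_lcc_rejected():
    curve = kn.DisintegrationCurve(n_lcc=2, f=(2, 1, 0), ordering=("a", "b"))
    with pytest.raises(MirnetError, match="too small"):
        kn.select_key_nodes(curve)


def test_select_agrees_with_exhaustive_oracle():
    rng = np.random.default_rng(4242)
    for _ in range(500):
        f, n = random_curve(rng)
        curve = kn.DisintegrationCurve(
            n_lcc=n, f=tuple(f), ordering=tuple(f"g{i:02d}" for i in range(n))
        )
        result = kn.select_key_nodes(curve)
        assert result.n_min == reference_select(f, n)
        assert len(result.key_genes) == result.n_min
        assert 2 * f[result.n_min] < n


def test_find_key_nodes_recovers_planted_bridges():
    hits = 0
    for seed in range(10):
        spec = PlantedGraphSpec(cluster_sizes=(9, 10), n_bridges=2, seed=seed)
        graph, bridges = make_planted_graph(spec)
        result, _ = kn.find_key_nodes(graph)
        hits += bridges <= set(result.key_genes)
    assert hits >= 9


def test_adaptive_mode_also_selects_hub():
    g = star(6)
    result, _ = kn.find_key_nodes(g, adaptive=True)
    assert result.key_genes[0] == "hub"
    assert result.n_min == 1
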