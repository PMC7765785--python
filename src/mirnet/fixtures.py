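"""Deterministic synthetic data: toy database files and planted graphs.

Everything the pipeline reads can be generated here at toy scale, so the
whole workflow is testable without downloading Human Protein Atlas,
miRTarBase, STRING or Reactome exports.  The toy tables are fixed,
hand-designed contents (the seed only shuffles row order, so regeneration
with one seed is byte-identical); the planted graphs are random two-cluster
networks whose bridge nodes are the unique inter-cluster articulation set,
used as ground truth for key-node recovery experiments.

Design of the toy tables
------------------------
* ``toy_hpa.tsv``: 30 genes x 3 tissues; exactly 18 genes pass the default
  expression filters for "heart muscle".
* ``toy_mirtarbase.tsv``: 25 rows over 3 miRNAs; ``hsa-miR-375`` has 12
  distinct targets (one duplicated row exercises deduplication).
* ``toy_links.txt`` + ``toy_string_aliases.tsv``: 40 raw rows collapse to
  14 gene-level edges at the default score threshold; CTNNB1 has two
  splice-variant protein ids to exercise variant merging.
* ``toy_reactome.gmt``: 12 gene sets over a 31-gene universe; with the key
  genes the toy network yields, exactly 4 sets survive the
  ">= 3 key genes and p < 0.05" filter and split into 2 clusters.

The 9 candidate genes (targets expressed in heart) form a 7-node, 8-edge
connected network plus 2 isolated candidates; its disintegration curve is
[7, 5, 3, 2, 1, 1, 1, 0], selecting 4 key genes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .exceptions import MirnetError
from .io_sources import EdgeTable, ExpressedGeneSet

# ---------------------------------------------------------------------------
# toy database contents (fixed, hand-designed)
# ---------------------------------------------------------------------------

HEART_TISSUE = "heart muscle"
TOY_MIRNA = "hsa-miR-375"

# gene -> (heart level, heart reliability); the first 18 pass the default
# filters, the last 12 fail on level or reliability.
_HEART_ROWS = {
    "CDC42": ("High", "Approved"),
    "CTNNB1": ("High", "Enhanced"),
    "ERBB2": ("Medium", "Approved"),
    "MAPK3": ("High", "Supported"),
    "MYC": ("Medium", "Enhanced"),
    "PIK3CA": ("Low", "Approved"),
    "RHOA": ("High", "Approved"),
    "DOK7": ("Low", "Supported"),
    "LDHB": ("High", "Approved"),
    "TNNI3": ("High", "Enhanced"),
    "CFL2": ("Medium", "Approved"),
    "ACTB": ("High", "Approved"),
    "GAPDH": ("High", "Supported"),
    "MYH7": ("High", "Enhanced"),
    "TPM1": ("High", "Approved"),
    "PRKCA": ("Medium", "Supported"),
    "PAFAH1B1": ("Low", "Enhanced"),
    "RAC1": ("Medium", "Approved"),
    # not expressed in heart under the default filters:
    "NPPB": ("High", "Uncertain"),
    "ANKRD1": ("Not detected", "Approved"),
    "NCAM1": ("Medium", "Uncertain"),
    "ALB": ("Not detected", "Approved"),
    "INS": ("Not detected", "Enhanced"),
    "CRP": ("Not detected", "Supported"),
    "KRT14": ("Not detected", "Approved"),
    "PAX6": ("Low", "Uncertain"),
    "GFAP": ("Not detected", "Approved"),
    "SFTPC": ("Not detected", "Enhanced"),
    "UGT1A1": ("Not detected", "Approved"),
    "CD19": ("High", "Uncertain"),
}

TOY_GENES = tuple(_HEART_ROWS)

_LIVER_EXPRESSED = {"ALB", "CRP", "UGT1A1", "GAPDH", "ACTB", "LDHB", "INS"}
_KIDNEY_EXPRESSED = {"GAPDH", "ACTB", "PAX6", "UGT1A1", "RAC1"}

# miRNA -> target rows (hsa-miR-375: 12 distinct targets, CDC42 duplicated)
_TARGET_ROWS = (
    [("hsa-miR-375", g) for g in (
        "CDC42", "CDC42", "CTNNB1", "ERBB2", "MAPK3", "MYC", "PIK3CA",
        "RHOA", "DOK7", "LDHB", "NPPB", "ANKRD1", "NCAM1",
    )]
    + [("hsa-miR-21", g) for g in (
        "TNNI3", "CFL2", "ACTB", "ALB", "INS", "MYH7", "TPM1",
    )]
    + [("hsa-miR-1", g) for g in ("GAPDH", "KRT14", "PAX6", "RAC1", "PRKCA")]
)

# protein ids: one per gene, plus a second CTNNB1 splice variant
_PROTEIN_IDS = {g: f"9606.ENSP{10001 + i:08d}" for i, g in enumerate(sorted(TOY_GENES))}
_CTNNB1_VARIANT = "9606.ENSP20000001"

# raw STRING-style rows (protein pairs in gene terms, score); 40 rows that
# collapse to 14 gene-level edges with score > 900.
_LINK_ROWS = [
    # the 8 edges of the connected candidate network
    ("CDC42", "ERBB2", 950),
    ("CDC42", "CTNNB1", 960),
    ("CDC42", "MAPK3", 980),
    ("CDC42", "PIK3CA", 910),
    ("ERBB2", "CTNNB1", 905),
    ("ERBB2", "MYC", 999),
    ("CTNNB1", "RHOA", 970),
    ("MAPK3", "MYC", 930),
    # 6 further high-confidence edges outside the candidate set
    ("ACTB", "CFL2", 915),
    ("ACTB", "MYH7", 970),
    ("MYH7", "TPM1", 925),
    ("GAPDH", "LDHB", 945),
    ("DOK7", "TNNI3", 910),
    ("RAC1", "RHOA", 940),
    # splice-variant duplicate of CDC42-CTNNB1 (collapses to max score 960)
    ("CTNNB1@variant", "CDC42", 920),
    # two CTNNB1 variants interact: a gene-level self-loop, dropped
    ("CTNNB1", "CTNNB1@variant", 999),
    # reversed lower-score duplicates (max-collapse keeps the higher row)
    ("ERBB2", "CDC42", 800),
    ("MYC", "ERBB2", 850),
    ("RHOA", "CTNNB1", 700),
    ("MYH7", "ACTB", 650),
    ("LDHB", "GAPDH", 900),
    # distinct pairs at or below the threshold (dropped by strict > 900)
    ("MYC", "RHOA", 850),
    ("PIK3CA", "RHOA", 900),
    ("ALB", "INS", 400),
    ("CRP", "ALB", 700),
    ("PAX6", "GFAP", 500),
    ("KRT14", "CD19", 300),
    ("NPPB", "ANKRD1", 880),
    ("NCAM1", "GFAP", 600),
    ("UGT1A1", "ALB", 750),
    ("SFTPC", "NPPB", 200),
    ("INS", "GAPDH", 350),
    ("TNNI3", "MYH7", 890),
    ("TPM1", "ACTB", 820),
    ("CFL2", "RAC1", 860),
    ("PRKCA", "PIK3CA", 900),
    ("PAFAH1B1", "RHOA", 840),
    ("DOK7", "NCAM1", 450),
    ("LDHB", "ALB", 550),
    ("MYC", "PIK3CA", 870),
]

_GMT_SETS = [
    ("R-TOY-0001", "Rho GTPase cycle",
     ["CDC42", "CTNNB1", "ERBB2", "RHOA", "RAC1"]),
    ("R-TOY-0002", "Actin cytoskeleton dynamics",
     ["CDC42", "CTNNB1", "ERBB2", "CFL2", "ACTB"]),
    ("R-TOY-0003", "MAPK cascade",
     ["CDC42", "CTNNB1", "MAPK3", "PRKCA"]),
    ("R-TOY-0004", "WNT signaling",
     ["CDC42", "CTNNB1", "MAPK3", "MYC", "PAFAH1B1"]),
    ("R-TOY-0005", "PI3K/AKT signaling",
     ["PIK3CA", "ERBB2", "MYC", "PRKCA"]),
    ("R-TOY-0006", "Cardiac muscle contraction",
     ["TNNI3", "MYH7", "TPM1", "ACTB", "ANKRD1", "NPPB"]),
    ("R-TOY-0007", "Glycolysis",
     ["GAPDH", "LDHB", "ALB"]),
    ("R-TOY-0008", "Apoptosis",
     ["MYC", "RHOA", "PRKCA", "CTNNB1"]),
    ("R-TOY-0009", "Neuronal development",
     ["NCAM1", "PAX6", "GFAP", "DOK7"]),
    ("R-TOY-0010", "Acute phase response",
     ["CRP", "ALB", "INS", "UGT1A1"]),
    ("R-TOY-0011", "Keratinization",
     ["KRT14", "SFTPC", "CD19"]),
    ("R-TOY-0012", "Cell cycle",
     ["MYC", "AURKA", "CDC42", "MAPK3"]),
]


def _protein_id(token: str) -> str:
    if token == "CTNNB1@variant":
        return _CTNNB1_VARIANT
    return _PROTEIN_IDS[token]


def make_toy_databases(out_dir, seed: int = 42) -> dict:
    """Write the four toy input files; returns a name -> path mapping.

    Contents are fixed; the seed only shuffles data-row order, so two runs
    with the same seed produce byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = {}

    def shuffled(rows):
        rows = list(rows)
        rng.shuffle(rows)
        return rows

    # expression table
    hpa_rows = []
    levels = ("High", "Medium", "Low")
    for i, gene in enumerate(TOY_GENES):
        level, reliability = _HEART_ROWS[gene]
        hpa_rows.append((gene, HEART_TISSUE, level, reliability))
        liver = levels[i % 3] if gene in _LIVER_EXPRESSED else "Not detected"
        hpa_rows.append((gene, "liver", liver, "Approved"))
        kidney = levels[(i + 1) % 3] if gene in _KIDNEY_EXPRESSED else "Not detected"
        hpa_rows.append((gene, "kidney", kidney, "Approved"))
    path = os.path.join(out_dir, "toy_hpa.tsv")
    with open(path, "wt") as fh:
        fh.write("gene\ttissue\tlevel\treliability\n")
        for row in shuffled(hpa_rows):
            fh.write("\t".join(row) + "\n")
    paths["expression"] = path

    # miRNA target table
    path = os.path.join(out_dir, "toy_mirtarbase.tsv")
    with open(path, "wt") as fh:
        fh.write("mirna\ttarget\tevidence\n")
        for i, (mirna, target) in enumerate(shuffled(_TARGET_ROWS)):
            evidence = "Functional MTI" if i % 3 else "Functional MTI (Weak)"
            fh.write(f"{mirna}\t{target}\t{evidence}\n")
    paths["targets"] = path

    # STRING-style links + alias table
    path = os.path.join(out_dir, "toy_links.txt")
    with open(path, "wt") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b, score in shuffled(_LINK_ROWS):
            fh.write(f"{_protein_id(a)} {_protein_id(b)} {score}\n")
    paths["links"] = path

    path = os.path.join(out_dir, "toy_string_aliases.tsv")
    alias_rows = [(pid, gene) for gene, pid in sorted(_PROTEIN_IDS.items())]
    alias_rows.append((_CTNNB1_VARIANT, "CTNNB1"))
    with open(path, "wt") as fh:
        fh.write("protein_id\tsymbol\n")
        for pid, gene in shuffled(alias_rows):
            fh.write(f"{pid}\t{gene}\n")
    paths["aliases"] = path

    # GMT pathway collection
    path = os.path.join(out_dir, "toy_reactome.gmt")
    with open(path, "wt") as fh:
        for pw_id, name, genes in shuffled(_GMT_SETS):
            fh.write("\t".join([pw_id, name] + genes) + "\n")
    paths["gmt"] = path

    return paths


# ---------------------------------------------------------------------------
# planted-structure random graphs
# ---------------------------------------------------------------------------


@dataclass
class PlantedGraphSpec:
    """Two dense clusters joined only through dedicated bridge nodes."""

    cluster_sizes: tuple[int, int] = (10, 10)
    p_intra: float = 0.9
    n_bridges: int = 2
    # Attachments per cluster, per bridge.  Bridges must behave as
    # hubs-bottlenecks: with dense (p ~ 0.9) clusters of 8-12 nodes, sparse
    # bridges are outranked in combined centrality by well-connected cluster
    # members and the plant loses its articulation property in practice; six
    # attachments per side keep every bridge in the top-b centralities.
    bridge_degree: int = 6
    seed: int = 0
    max_retries: int = field(default=50, repr=False)

    def __post_init__(self):
        if self.n_bridges < 1:
            raise MirnetError("need at least one bridge node")
        if min(self.cluster_sizes) < self.bridge_degree:
            raise MirnetError("clusters smaller than the bridge degree")


def make_planted_graph(spec: PlantedGraphSpec):
    """Generate the planted graph; returns (graph, bridge node set).

    Cluster nodes are named ``A..``/``B..``, bridges ``H..``.  There are no
    direct inter-cluster edges, so removing the bridge set provably
    disconnects the clusters (asserted).  Raises if a cluster fails to come
    out internally connected after ``max_retries`` resamplings.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = spec.cluster_sizes
    names = [
        [f"A{i + 1:02d}" for i in range(sizes[0])],
        [f"B{i + 1:02d}" for i in range(sizes[1])],
    ]
    bridges = [f"H{i + 1:02d}" for i in range(spec.n_bridges)]

    graph = nx.Graph()
    for cluster in names:
        for attempt in range(spec.max_retries + 1):
            edges = [
                (a, b)
                for i, a in enumerate(cluster)
                for b in cluster[i + 1:]
                if rng.random() < spec.p_intra
            ]
            sub = nx.Graph(edges)
            sub.add_nodes_from(cluster)
            if nx.is_connected(sub):
                graph.add_edges_from(edges)
                break
        else:
            raise MirnetError(
                f"cluster failed to connect after {spec.max_retries} retries "
                f"(seed {spec.seed})"
            )
    for bridge in bridges:
        for cluster in names:
            picks = rng.choice(cluster, size=spec.bridge_degree, replace=False)
            for node in picks:
                graph.add_edge(bridge, str(node))
    for a, b in graph.edges:
        graph.edges[a, b]["score"] = 999

    stripped = graph.copy()
    stripped.remove_nodes_from(bridges)
    assert not any(
        a[0] == "A" and b[0] == "B" or a[0] == "B" and b[0] == "A"
        for a, b in stripped.edges
    ), "planted graph grew a direct inter-cluster edge"
    return graph, frozenset(bridges)


def make_random_universe(
    n_genes: int = 250, edge_prob: float = 0.012, seed: int = 0
):
    """A synthetic expressed-gene universe with a random interaction table.

    Much larger than the toy databases, with edge density near the
    percolation threshold of typical draws, so the null distribution of
    LCC sizes takes many distinct values; heavy ties would make the
    add-one permutation p conservative in calibration experiments.
    Returns (ExpressedGeneSet, EdgeTable).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    records = [
        (a, b, 950)
        for i, a in enumerate(genes)
        for b in genes[i + 1:]
        if rng.random() < edge_prob
    ]
    return (
        ExpressedGeneSet(tissue="synthetic", genes=frozenset(genes)),
        EdgeTable.from_records(records),
    )


def make_random_network(n_nodes: int, edge_prob: float, seed: int = 0) -> nx.Graph:
    """Erdos-Renyi-style random gene graph for property tests."""
    rng = np.random.default_rng(seed)
    genes = [f"N{i + 1:03d}" for i in range(n_nodes)]
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            if rng.random() < edge_prob:
                graph.add_edge(a, b, score=950)
    return graph
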