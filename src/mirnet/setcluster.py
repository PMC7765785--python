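"""Clustering of surviving pathway sets by shared key-gene membership.

Each pathway becomes a binary membership row over the key genes; rows are
compared by Jaccard distance and clustered agglomeratively (average
linkage by default).  The tree is exported as Newick plus a label table
whose rows carry each pathway's cluster, leaf position and mean key-gene
centrality, which is what the centrality-graded dendrogram figure plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .exceptions import MirnetError


def membership_matrix(records, key_genes) -> pd.DataFrame:
    """Binary pathway x key-gene matrix.

    Rows follow the records sorted by raw p ascending (ties by pathway
    id); columns follow ``key_genes`` (callers pass them in descending
    centrality order).
    """
    if not records:
        raise MirnetError("no records to build a membership matrix from")
    ordered = sorted(records, key=lambda r: (r.p_exact, r.pathway_id))
    key_genes = list(key_genes)
    data = [
        [1 if g in set(r.overlap_genes) else 0 for g in key_genes]
        for r in ordered
    ]
    return pd.DataFrame(
        data,
        index=pd.Index([r.pathway_id for r in ordered], name="pathway_id"),
        columns=key_genes,
        dtype=int,
    )


def set_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distance 1 - |a&b|/|a|b| between membership rows."""
    if len(matrix) < 2:
        raise MirnetError("need at least two rows to compute distances")
    condensed = pdist(matrix.values.astype(bool), metric="jaccard")
    return pd.DataFrame(
        squareform(condensed), index=matrix.index, columns=matrix.index
    )


@dataclass
class SetDendrogram:
    """Agglomerative merge tree over pathway rows."""

    linkage: np.ndarray  # scipy linkage matrix
    ids: tuple[str, ...]  # row ids in input order
    labels: dict  # pathway_id -> cluster label (1-based)
    leaf_order: tuple[str, ...]  # left-to-right dendrogram leaves
    n_clusters: int

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def cluster_sets(
    dist: pd.DataFrame, linkage_method: str = "average", n_clusters: int = 2
) -> SetDendrogram:
    """Hierarchical clustering of the distance table, cut into n_clusters."""
    n = len(dist)
    if n_clusters > n:
        raise MirnetError(
            f"cannot cut {n} rows into {n_clusters} clusters"
        )
    condensed = squareform(dist.values, checks=False)
    linkage = hierarchy.linkage(condensed, method=linkage_method)
    flat = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    ids = tuple(dist.index)
    leaves = hierarchy.leaves_list(linkage)
    return SetDendrogram(
        linkage=linkage,
        ids=ids,
        labels={pid: int(c) for pid, c in zip(ids, flat)},
        leaf_order=tuple(ids[i] for i in leaves),
        n_clusters=n_clusters,
    )


def labels_table(dendrogram: SetDendrogram, records) -> pd.DataFrame:
    """Leaf-order table: pathway, cluster, leaf rank and mean centrality."""
    by_id = {r.pathway_id: r for r in records}
    rows = []
    for rank, pid in enumerate(dendrogram.leaf_order):
        rec = by_id.get(pid)
        rows.append(
            {
                "pathway_id": pid,
                "pathway_name": rec.pathway_name if rec else "",
                "cluster": dendrogram.labels[pid],
                "leaf_rank": rank,
                "mean_centrality": rec.mean_centrality if rec else float("nan"),
            }
        )
    return pd.DataFrame(rows)
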