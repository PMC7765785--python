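"""End-to-end orchestration of the miRNA-function-prediction workflow.

Stages: read inputs -> build tissue-filtered target network -> extract the
LCC -> permutation test of its size -> centrality ranking and key-node
selection -> pathway overrepresentation of the key genes -> >=N-key-gene
filter -> membership clustering.  Every artifact is written in a
text-based, Cytoscape- or spreadsheet-readable format, and the JSON run
report echoes the configuration plus all summary counts, so a rerun with
the same config and seed reproduces every file byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import networkx as nx
import yaml

from . import enrichment as enr
from . import io_sources as io
from . import keynodes as kn
from . import network as net
from . import setcluster as sc
from . import significance as sig
from .exceptions import EmptyResultError, MirnetError, StageError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults follow the published choices."""

    mirna_id: str
    tissue: str
    expression: str
    targets: str
    links: str
    aliases: str | None
    gmt: str
    out_dir: str
    min_score: int = io.DEFAULT_MIN_SCORE
    allowed_levels: tuple = tuple(sorted(io.DEFAULT_LEVELS))
    allowed_reliability: tuple = tuple(sorted(io.DEFAULT_RELIABILITY))
    n_perm: int = sig.DEFAULT_N_PERM
    seed: int = 0
    k: int | None = None  # permutation draw size; default: expressed targets
    min_key_genes: int = 3
    alpha: float = 0.05
    use_adjusted: bool = False
    n_clusters: int = 2
    linkage: str = "average"
    adaptive: bool = False

    @classmethod
    def from_yaml(cls, path, **overrides):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise MirnetError(
                f"unknown config keys: {', '.join(sorted(unknown))}"
            )
        raw.update({k: v for k, v in overrides.items() if v is not None})
        missing = {"mirna_id", "tissue", "expression", "targets", "links",
                   "gmt", "out_dir"} - set(raw)
        if missing:
            raise MirnetError(f"missing config keys: {', '.join(sorted(missing))}")
        raw.setdefault("aliases", None)
        for key in ("allowed_levels", "allowed_reliability"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self):
        out = dataclasses.asdict(self)
        out["allowed_levels"] = list(self.allowed_levels)
        out["allowed_reliability"] = list(self.allowed_reliability)
        return out

    def echo_dict(self):
        """Config echo for the run report: paths reduced to basenames so a
        rerun in a different directory still reproduces the report exactly."""
        out = self.to_dict()
        for key in ("expression", "targets", "links", "aliases", "gmt", "out_dir"):
            if out.get(key):
                out[key] = os.path.basename(str(out[key]))
        return out


@dataclass
class RunReport:
    config: dict
    counts: dict
    key_genes: tuple
    artifacts: dict
    partial_stages: tuple = field(default_factory=tuple)

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "counts": self.counts,
            "key_genes": list(self.key_genes),
            "artifacts": self.artifacts,
            "partial_stages": list(self.partial_stages),
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def _write_sif(graph: nx.Graph, path):
    with open(path, "wt") as fh:
        for a, b in sorted((min(e), max(e)) for e in graph.edges):
            fh.write(f"{a}\tpp\t{b}\n")
        for node in sorted(nx.isolates(graph)):
            fh.write(f"{node}\n")


def run_pipeline(config: RunConfig) -> RunReport:
    os.makedirs(config.out_dir, exist_ok=True)
    artifacts: dict[str, str] = {}
    partial: list[str] = []

    def out(name):
        artifacts[name.replace(".", "_")] = name
        return os.path.join(config.out_dir, name)

    with _stage("io_sources"):
        expressed = io.read_expression_table(
            config.expression,
            config.tissue,
            allowed_levels=frozenset(config.allowed_levels),
            allowed_reliability=frozenset(config.allowed_reliability),
        )
        targets = io.read_targets_table(config.targets, config.mirna_id)
        edges = io.read_links(
            config.links, config.aliases, min_score=config.min_score
        )
        pathways = io.read_gmt(config.gmt)

    with _stage("network_builder"):
        build = net.build_network(targets, expressed, edges)
        summary = net.connected_components(build.graph)
        if build.graph.number_of_nodes() == 0:
            raise EmptyResultError(
                "all expressed targets are isolated; no network to analyse"
            )
        lcc = net.largest_connected_component(build.graph)
        nx.write_graphml(build.graph, out("network.graphml"))
        _write_sif(build.graph, out("network.sif"))

    with _stage("lcc_significance"):
        k = config.k if config.k is not None else len(build.candidates)
        perm = sig.permutation_test(
            observed_lcc=summary.lcc_size,
            universe=expressed,
            k=k,
            edges=edges,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        with open(out("permutation_null.tsv"), "wt") as fh:
            fh.write("replicate\tlcc_size\n")
            for i, size in enumerate(perm.null_sizes):
                fh.write(f"{i}\t{size}\n")

    with _stage("centrality_keynodes"):
        result, centrality = kn.find_key_nodes(lcc, adaptive=config.adaptive)
        key_genes = result.key_genes
        table = centrality.table.copy()
        table["is_key"] = [int(g in set(key_genes)) for g in table.index]
        # extend to network nodes outside the LCC for Cytoscape styling
        for gene in sorted(set(build.graph.nodes) - set(table.index)):
            table.loc[gene] = [float("nan")] * 3 + [-1, 0]
        table["rank"] = table["rank"].astype(int)
        table.to_csv(out("node_attributes.tsv"), sep="\t", float_format="%.10g")
        with open(out("disintegration_curve.tsv"), "wt") as fh:
            fh.write("n_removed\tlcc_size\tremoved_gene\n")
            for n, size in enumerate(result.curve.f):
                gene = result.curve.ordering[n - 1] if n else ""
                fh.write(f"{n}\t{size}\t{gene}\n")

    with _stage("enrichment"):
        records = enr.overrepresentation(key_genes, pathways)
        annotated = [
            enr.mean_set_centrality(r, centrality) if r.overlap_genes else None
            for r in records
        ]
        records = [
            dataclasses.replace(r, mean_centrality=m)
            for r, m in zip(records, annotated)
        ]
        surviving = enr.filter_by_key_gene_count(
            records,
            min_genes=config.min_key_genes,
            alpha=config.alpha,
            use_adjusted=config.use_adjusted,
        )
        kept_ids = {r.pathway_id for r in surviving}
        with open(out("enrichment.tsv"), "wt") as fh:
            fh.write(
                "pathway_id\tpathway_name\tk_overlap\tset_size\tp_value\t"
                "p_adjusted\tmean_centrality\toverlap_genes\tpasses_filter\n"
            )
            for r in records:
                mean_c = "" if r.mean_centrality is None else f"{r.mean_centrality:.10g}"
                fh.write(
                    f"{r.pathway_id}\t{r.pathway_name}\t{r.k_overlap}\t"
                    f"{r.set_size}\t{r.p_value:.10g}\t{r.p_adjusted:.10g}\t"
                    f"{mean_c}\t{','.join(r.overlap_genes)}\t"
                    f"{int(r.pathway_id in kept_ids)}\n"
                )

    with _stage("setcluster"):
        n_clusters_found = 0
        if len(surviving) >= max(2, config.n_clusters):
            matrix = sc.membership_matrix(surviving, key_genes)
            dist = sc.set_distance(matrix)
            dendro = sc.cluster_sets(
                dist, linkage_method=config.linkage, n_clusters=config.n_clusters
            )
            with open(out("dendrogram.nwk"), "wt") as fh:
                fh.write(dendro.to_newick() + "\n")
            sc.labels_table(dendro, surviving).to_csv(
                out("dendrogram_labels.tsv"),
                sep="\t",
                index=False,
                float_format="%.10g",
            )
            n_clusters_found = len(set(dendro.labels.values()))
        else:
            partial.append("setcluster")
            logger.warning(
                "setcluster skipped: only %d pathways survive the filter",
                len(surviving),
            )

    counts = {
        "n_targets": len(targets),
        "n_expressed_genes": len(expressed),
        "n_expressed_targets": len(build.candidates),
        "n_connected_genes": build.graph.number_of_nodes(),
        "n_edges": build.graph.number_of_edges(),
        "n_isolated_targets": build.n_isolated,
        "component_sizes": list(summary.sizes),
        "lcc_size": summary.lcc_size,
        "n_min": result.n_min,
        "n_key_genes": len(key_genes),
        "permutation": {
            "n_perm": perm.n_perm,
            "observed_lcc": perm.observed_lcc,
            "exceedances": perm.exceedances,
            "empirical_p": str(perm.empirical_p),
            "empirical_p_float": float(perm.empirical_p),
            "formatted": perm.format_p(),
            "k": k,
        },
        "n_pathways_tested": len(records),
        "n_pathways_significant": sum(
            1 for r in records if r.p_value < config.alpha
        ),
        "n_pathways_filtered": len(surviving),
        "n_clusters": n_clusters_found,
        "links_skip_summary": edges.skip_summary,
    }
    report = RunReport(
        config=config.echo_dict(),
        counts=counts,
        key_genes=key_genes,
        artifacts=artifacts,
        partial_stages=tuple(partial),
    )
    with open(os.path.join(config.out_dir, "run_report.json"), "wt") as fh:
        fh.write(report.to_json())
    return report
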