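"""Overrepresentation analysis of key genes in pathway gene sets.

P-values are upper-tail hypergeometric probabilities computed exactly with
integer combinatorics (kept as :class:`fractions.Fraction` alongside the
float), Benjamini-Hochberg adjusted across all tested pathways.  Following
the original procedure, the significance filter uses the raw p-value by
default; switching to the adjusted value is a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from fractions import Fraction

from statsmodels.stats.multitest import multipletests

from .exceptions import MirnetError
from .io_sources import PathwayCollection
from .keynodes import CentralityTable

logger = logging.getLogger(__name__)


def hypergeom_tail(k: int, universe_size: int, set_size: int, draws: int) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeometric(universe_size, set_size, draws)."""
    if not (0 <= set_size <= universe_size and 0 <= draws <= universe_size):
        raise MirnetError("invalid hypergeometric configuration")
    total = math.comb(universe_size, draws)
    upper = min(set_size, draws)
    acc = 0
    for i in range(max(k, 0), upper + 1):
        acc += math.comb(set_size, i) * math.comb(universe_size - set_size, draws - i)
    return Fraction(acc, total)


@dataclass(frozen=True)
class EnrichmentRecord:
    pathway_id: str
    pathway_name: str
    overlap_genes: tuple[str, ...]
    k_overlap: int
    set_size: int
    p_value: float
    p_exact: Fraction
    p_adjusted: float = float("nan")
    mean_centrality: float | None = None


def overrepresentation(
    key_genes,
    pathways: PathwayCollection,
    universe=None,
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric test of the key genes against every pathway.

    ``universe`` defaults to the union of all pathway members (the
    collection's own background); it may be overridden with e.g. the
    tissue-expressed gene set.  Key genes absent from the universe are
    excluded from the draw count and logged.  Records are sorted by raw
    p ascending, ties broken by pathway id.
    """
    key = frozenset(g.upper() for g in key_genes)
    if not key:
        raise MirnetError("key_genes must be non-empty")
    universe = frozenset(universe) if universe is not None else pathways.universe
    annotated = key & universe
    dropped = key - annotated
    if dropped:
        logger.warning(
            "%d key genes absent from the ORA universe were excluded: %s",
            len(dropped), ", ".join(sorted(dropped)),
        )
    if not annotated:
        raise MirnetError("no key gene is present in the ORA universe")
    m = len(universe)
    draws = len(annotated)
    records = []
    for pw in pathways:
        members = pw.genes & universe
        if len(members) > m:  # pragma: no cover - guarded by universe definition
            raise MirnetError(f"pathway {pw.pathway_id} larger than the universe")
        overlap = tuple(sorted(annotated & members))
        p = hypergeom_tail(len(overlap), m, len(members), draws)
        records.append(
            EnrichmentRecord(
                pathway_id=pw.pathway_id,
                pathway_name=pw.name,
                overlap_genes=overlap,
                k_overlap=len(overlap),
                set_size=len(members),
                p_value=float(p),
                p_exact=p,
            )
        )
    records.sort(key=lambda r: (r.p_exact, r.pathway_id))
    if records:
        _, adjusted, _, _ = multipletests(
            [r.p_value for r in records], method="fdr_bh"
        )
        records = [
            replace(r, p_adjusted=float(q)) for r, q in zip(records, adjusted)
        ]
    return records


def filter_by_key_gene_count(
    records, min_genes: int = 3, alpha: float = 0.05, use_adjusted: bool = False
) -> list[EnrichmentRecord]:
    """Keep significant pathways containing at least ``min_genes`` key genes."""
    if min_genes < 1:
        raise MirnetError("min_genes must be >= 1")

    def significant(r: EnrichmentRecord) -> bool:
        p = r.p_adjusted if use_adjusted else r.p_value
        return p < alpha

    return [r for r in records if r.k_overlap >= min_genes and significant(r)]


def mean_set_centrality(record: EnrichmentRecord, centrality: CentralityTable) -> float:
    """Arithmetic mean combined centrality of the record's overlapping key genes."""
    if not record.overlap_genes:
        raise MirnetError(
            f"pathway {record.pathway_id} has no overlap genes to average"
        )
    missing = [g for g in record.overlap_genes if g not in centrality.table.index]
    if missing:
        raise MirnetError(
            f"genes absent from the centrality table: {', '.join(missing)}"
        )
    values = [centrality.combined(g) for g in record.overlap_genes]
    return sum(values) / len(values)


def attach_mean_centrality(records, centrality: CentralityTable):
    """Return records with ``mean_centrality`` filled in."""
    return [
        replace(r, mean_centrality=mean_set_centrality(r, centrality))
        for r in records
    ]
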