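"""Readers for the four input file kinds.

All readers accept plain or gzip-compressed files, fold gene symbols to
upper case, and return small immutable-ish containers that the rest of the
pipeline consumes.  Real database exports (Human Protein Atlas
``normal_tissue``, miRTarBase, STRING ``protein.links`` plus an alias
table, and GMT pathway collections) drift between releases, so every
tabular reader takes a ``columns`` mapping from the logical column names
used here to whatever the concrete file calls them.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import FormatError, MissingColumnError, TissueNotFoundError

logger = logging.getLogger(__name__)

#: Human Protein Atlas detection levels counted as "expressed".
DEFAULT_LEVELS = frozenset({"Low", "Medium", "High"})
#: HPA reliability classes counted as trustworthy annotation.
DEFAULT_RELIABILITY = frozenset({"Approved", "Enhanced", "Supported"})
#: STRING combined-score cutoff (0-1000 scale); edges must score strictly above.
DEFAULT_MIN_SCORE = 900


@dataclass(frozen=True)
class ExpressedGeneSet:
    """Genes detected in one tissue."""

    tissue: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.tissue:
            raise ValueError("tissue label must be non-empty")
        if any(not g for g in self.genes):
            raise ValueError("empty gene symbol in expressed set")

    def __len__(self):
        return len(self.genes)


@dataclass(frozen=True)
class TargetGeneSet:
    """Experimentally supported targets of one miRNA."""

    mirna_id: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.mirna_id:
            raise ValueError("mirna_id must be non-empty")

    def __len__(self):
        return len(self.genes)


@dataclass
class EdgeTable:
    """Undirected gene-gene interactions with a 0-1000 confidence score.

    Pairs are stored canonically (lexicographically smaller symbol first),
    deduplicated to the maximum score, with self-loops removed.
    """

    frame: pd.DataFrame  # columns: gene_a, gene_b, score
    skip_summary: dict = field(default_factory=dict)

    @classmethod
    def from_records(cls, records, skip_summary=None):
        """Build a canonical table from (gene_a, gene_b, score) triples."""
        best: dict[tuple[str, str], int] = {}
        for a, b, s in records:
            a, b = a.upper(), b.upper()
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            if s > best.get(key, -1):
                best[key] = s
        frame = pd.DataFrame(
            [(a, b, s) for (a, b), s in sorted(best.items())],
            columns=["gene_a", "gene_b", "score"],
        ).astype({"score": int}, errors="ignore")
        return cls(frame, skip_summary or {})

    def pairs(self):
        """Canonical (gene_a, gene_b) tuples."""
        return list(zip(self.frame["gene_a"], self.frame["gene_b"]))

    def records(self):
        return list(
            zip(self.frame["gene_a"], self.frame["gene_b"], self.frame["score"])
        )

    def __len__(self):
        return len(self.frame)


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    genes: frozenset[str]


@dataclass
class PathwayCollection:
    """A GMT-style collection of gene sets."""

    pathways: list[Pathway]

    def __post_init__(self):
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate pathway ids in collection")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return frozenset(out)

    def __len__(self):
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_table(path, logical_columns, columns=None, sep="\t"):
    """Read a delimited table and rename real-world headers to logical names."""
    mapping = dict(columns or {})
    with _open_text(path) as fh:
        frame = pd.read_csv(fh, sep=sep, dtype=str)
    rename = {v: k for k, v in mapping.items()}
    frame = frame.rename(columns=rename)
    for col in logical_columns:
        if col not in frame.columns:
            raise MissingColumnError(
                f"{path}: required column {col!r} not found "
                f"(have: {', '.join(frame.columns)})"
            )
    return frame


def read_expression_table(
    path,
    tissue,
    allowed_levels=DEFAULT_LEVELS,
    allowed_reliability=DEFAULT_RELIABILITY,
    columns=None,
) -> ExpressedGeneSet:
    """Genes detected in *tissue* according to an HPA-style table.

    A gene counts as expressed when its detection level is in
    ``allowed_levels`` and its annotation reliability is in
    ``allowed_reliability`` (defaults: any detected level; Approved,
    Enhanced or Supported reliability).
    """
    frame = _read_table(path, ("gene", "tissue", "level", "reliability"), columns)
    rows = frame[frame["tissue"] == tissue]
    if rows.empty:
        raise TissueNotFoundError(tissue, frame["tissue"].dropna().unique())
    keep = rows["level"].isin(allowed_levels) & rows["reliability"].isin(
        allowed_reliability
    )
    genes = frozenset(g.upper() for g in rows.loc[keep, "gene"] if isinstance(g, str) and g)
    logger.info(
        "expression table %s: %d/%d rows for tissue %r pass filters",
        path, int(keep.sum()), len(rows), tissue,
    )
    return ExpressedGeneSet(tissue=tissue, genes=genes)


def read_targets_table(path, mirna_id, columns=None) -> TargetGeneSet:
    """Deduplicated target symbols of one miRNA (case-insensitive id match)."""
    frame = _read_table(path, ("mirna", "target"), columns)
    rows = frame[frame["mirna"].str.lower() == mirna_id.lower()]
    genes = frozenset(g.upper() for g in rows["target"] if isinstance(g, str) and g)
    if not genes:
        warnings.warn(
            f"no targets found for miRNA {mirna_id!r} in {path}", stacklevel=2
        )
    return TargetGeneSet(mirna_id=mirna_id, genes=genes)


def read_aliases(path, columns=None) -> dict[str, str]:
    """Protein-id to gene-symbol map.

    A protein id mapping to several symbols is resolved to the
    lexicographically first one (logged), so runs are deterministic.
    """
    frame = _read_table(path, ("protein_id", "symbol"), columns)
    mapping: dict[str, str] = {}
    ambiguous = 0
    for pid, sym in zip(frame["protein_id"], frame["symbol"]):
        if not isinstance(sym, str) or not sym:
            continue
        sym = sym.upper()
        if pid in mapping and mapping[pid] != sym:
            ambiguous += 1
            mapping[pid] = min(mapping[pid], sym)
        else:
            mapping[pid] = sym
    if ambiguous:
        logger.warning(
            "%s: %d protein ids mapped to multiple symbols; kept the "
            "lexicographically first", path, ambiguous,
        )
    return mapping


def read_links(
    links_path, alias_path=None, min_score=DEFAULT_MIN_SCORE, columns=None
) -> EdgeTable:
    """Parse a STRING-style links file into a canonical gene-level EdgeTable.

    Protein ids are mapped through the alias table (identity when
    ``alias_path`` is None); duplicate unordered pairs collapse to their
    maximum score *before* the strict ``score > min_score`` threshold, and
    pairs whose proteins map to the same gene (splice variants) are dropped
    as self-loops.  Rows naming a protein with no alias are skipped and
    counted in ``skip_summary``.
    """
    aliases = read_aliases(alias_path, columns=columns) if alias_path else None
    records = []
    n_no_alias = 0
    n_self = 0
    with _open_text(links_path) as fh:
        header = fh.readline().split()
        if header[:3] != ["protein1", "protein2", "combined_score"] and not columns:
            raise FormatError(
                f"{links_path}: expected header 'protein1 protein2 combined_score', "
                f"got {' '.join(header[:3])!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise FormatError(f"{links_path}:{lineno}: expected 3 fields")
            p1, p2, raw_score = parts[0], parts[1], parts[2]
            try:
                score = int(raw_score)
            except ValueError as exc:
                raise FormatError(
                    f"{links_path}:{lineno}: malformed score {raw_score!r}"
                ) from exc
            if not 0 <= score <= 1000:
                raise FormatError(
                    f"{links_path}:{lineno}: score {score} outside 0-1000"
                )
            if aliases is not None:
                if p1 not in aliases or p2 not in aliases:
                    n_no_alias += 1
                    continue
                g1, g2 = aliases[p1], aliases[p2]
            else:
                g1, g2 = p1, p2
            if g1.upper() == g2.upper():
                n_self += 1
                continue
            records.append((g1, g2, score))
    # collapse duplicates to max score, then threshold
    table = EdgeTable.from_records(records)
    frame = table.frame[table.frame["score"] > min_score].reset_index(drop=True)
    summary = {"no_alias": n_no_alias, "self_loops": n_self}
    if n_no_alias:
        logger.warning(
            "%s: skipped %d rows naming proteins with no alias", links_path, n_no_alias
        )
    return EdgeTable(frame, summary)


def write_links(table: EdgeTable, path) -> None:
    """Write an EdgeTable in the STRING links dialect (symbols as ids)."""
    with open(path, "wt") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b, s in table.records():
            fh.write(f"{a} {b} {s}\n")


def read_gmt(path) -> PathwayCollection:
    """Standard GMT: one set per line, ``name TAB description TAB genes...``."""
    pathways = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, description = parts[0], parts[1]
            genes = frozenset(g.upper() for g in parts[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            pathways.append(
                Pathway(pathway_id=name, name=description or name, genes=genes)
            )
    return PathwayCollection(pathways)
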