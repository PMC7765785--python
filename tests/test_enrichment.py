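"""Hypergeometric overrepresentation, BH adjustment, filters, centralities."""

from fractions import Fraction

import pytest
from scipy.stats import hypergeom

from conftest import enumerate_hypergeom_tail
from mirnet import enrichment as enr
from mirnet.exceptions import MirnetError
from mirnet.io_sources import Pathway, PathwayCollection
from mirnet.keynodes import CentralityTable
import pandas as pd


def collection(*sets):
    return PathwayCollection(
        [Pathway(pathway_id=i, name=n, genes=frozenset(g)) for i, n, g in sets]
    )


def centrality_of(values: dict) -> CentralityTable:
    genes = sorted(values, key=lambda g: (-values[g], g))
    table = pd.DataFrame(
        {"betweenness": 0.0, "degree_centrality": 0.0,
         "combined": [values[g] for g in genes],
         "rank": range(len(genes))},
        index=pd.Index(genes, name="gene"),
    )
    return CentralityTable(table=table, ordering=tuple(genes))


def test_worked_example_exact_rational():
    # universe 10, one 4-gene set, 3 draws, overlap 3 -> 4/120
    p = enr.hypergeom_tail(3, 10, 4, 3)
    assert p == Fraction(4, 120)


def test_zero_overlap_is_one():
    assert enr.hypergeom_tail(0, 20, 5, 4) == 1


def test_pathway_equal_to_universe_is_one():
    assert enr.hypergeom_tail(3, 6, 6, 3) == 1


def test_tail_matches_scipy(rng):
    for _ in range(100):
        m = int(rng.integers(2, 60))
        k_set = int(rng.integers(1, m + 1))
        draws = int(rng.integers(1, m + 1))
        k = int(rng.integers(0, min(k_set, draws) + 1))
        ours = float(enr.hypergeom_tail(k, m, k_set, draws))
        oracle = float(hypergeom.sf(k - 1, m, k_set, draws))
        assert ours == pytest.approx(oracle, rel=1e-9, abs=1e-12)


def test_tail_matches_exhaustive_enumeration(rng):
    for _ in range(25):
        m = int(rng.integers(3, 10))
        k_set = int(rng.integers(1, m + 1))
        draws = int(rng.integers(1, m + 1))
        k = int(rng.integers(0, min(k_set, draws) + 1))
        assert enr.hypergeom_tail(k, m, k_set, draws) == enumerate_hypergeom_tail(
            k, m, k_set, draws
        )


def test_tail_monotone_in_overlap():
    values = [enr.hypergeom_tail(k, 30, 10, 8) for k in range(9)]
    assert all(a >= b for a, b in zip(values, values[1:]))


def test_overrepresentation_orders_and_adjusts():
    coll = collection(
        ("P1", "specific", ["A", "B", "C"]),
        ("P2", "broad", ["A", "B", "C", "D", "E", "F", "G"]),
        ("P3", "miss", ["H", "I", "J"]),
    )
    records = enr.overrepresentation(["A", "B", "C"], coll)
    assert [r.pathway_id for r in records] == ["P1", "P2", "P3"]
    assert records[0].p_exact == Fraction(1, 120)  # C(10,3) = 120
    assert records[2].p_value == 1.0
    # BH: adjusted monotone in raw-p order, capped at 1
    adjusted = [r.p_adjusted for r in records]
    assert all(a <= b for a, b in zip(adjusted, adjusted[1:]))
    assert all(r.p_adjusted >= r.p_value for r in records)
    assert max(adjusted) <= 1.0
    # hand-computed BH for 3 tests
    raw = [r.p_value for r in records]
    hand = [min(1.0, min(raw[j] * 3 / (j + 1) for j in range(i, 3)))
            for i in range(3)]
    assert adjusted == pytest.approx(hand)


def test_key_gene_outside_universe_excluded(caplog):
    coll = collection(("P1", "x", ["A", "B", "C", "D"]))
    with caplog.at_level("WARNING"):
        records = enr.overrepresentation(["A", "B", "ZZZ"], coll)
    assert "ZZZ" in caplog.text
    # draws reduced to the 2 annotated key genes
    assert records[0].p_exact == Fraction(1, 1)  # C(4,2)/C(4,2)
    assert records[0].k_overlap == 2


def test_filter_by_count_and_alpha():
    def rec(pid, k, p):
        return enr.EnrichmentRecord(
            pathway_id=pid, pathway_name=pid, overlap_genes=tuple("G%d" % i for i in range(k)),
            k_overlap=k, set_size=10, p_value=p, p_exact=Fraction(p).limit_denominator(),
            p_adjusted=p,
        )

    records = [rec("P1", 1, 0.01), rec("P2", 2, 0.01), rec("P3", 3, 0.01),
               rec("P4", 5, 0.01), rec("P5", 4, 0.2)]
    kept = enr.filter_by_key_gene_count(records, min_genes=3)
    assert [r.pathway_id for r in kept] == ["P3", "P4"]
    kept_all = enr.filter_by_key_gene_count(records, min_genes=1)
    assert [r.pathway_id for r in kept_all] == ["P1", "P2", "P3", "P4"]


def test_mean_set_centrality():
    cent = centrality_of({"A": 2.0, "B": 0.5, "C": 1.0})
    rec = enr.EnrichmentRecord(
        pathway_id="P", pathway_name="P", overlap_genes=("A", "B"),
        k_overlap=2, set_size=4, p_value=0.01, p_exact=Fraction(1, 100),
    )
    assert enr.mean_set_centrality(rec, cent) == pytest.approx(1.25)
    single = enr.EnrichmentRecord(
        pathway_id="P", pathway_name="P", overlap_genes=("C",),
        k_overlap=1, set_size=4, p_value=0.01, p_exact=Fraction(1, 100),
    )
    assert enr.mean_set_centrality(single, cent) == pytest.approx(1.0)
    empty = enr.EnrichmentRecord(
        pathway_id="P", pathway_name="P", overlap_genes=(),
        k_overlap=0, set_size=4, p_value=1.0, p_exact=Fraction(1, 1),
    )
    with pytest.raises(MirnetError):
        enr.mean_set_centrality(empty, cent)


def test_toy_run_has_four_surviving_pathways(toy_run):
    _, report = toy_run
    assert report.counts["n_pathways_tested"] == 12
    assert report.counts["n_pathways_filtered"] == 4
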