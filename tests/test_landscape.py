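"""Cohort summaries, gene matrices, recurrence, hotspots, overlap."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from _oracles import oracle_hotspots
from conftest import make_record
from ugtscape.landscape import (
    build_cohort_summary,
    cross_dataset_overlap,
    expression_stratify,
    find_hotspots,
    find_recurrent,
    floor_div,
    gene_type_matrix,
    multiplicity_distribution,
    summarize_cohorts,
    trunc3,
)
from ugtscape.records import SiftCall, VariantClass
from ugtscape.resources import cohort_table


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------


def test_reporting_conventions_floor_and_truncate():
    """Per-tumor burden is floored and the UGT fraction truncated: the
    bladder cohort gives 377 (not 378) and the lung adenocarcinoma cohort
    0.458 (not 0.459)."""
    assert floor_div(155233, 411) == 377
    assert trunc3(235 / 512) == 0.458


def test_published_cohort_rows_reproduce_derived_columns():
    raw = cohort_table()
    summ = build_cohort_summary(raw)
    skcm = summ[summ.cohort == "SKCM-metastatic"].iloc[0]
    assert skcm.mutations_per_tumor == 1204
    luad = summ[summ.cohort == "LUAD"].iloc[0]
    assert luad.fraction_with_ugt == 0.458
    total = summ[summ.cohort == "SUM"].iloc[0]
    assert total.n_tumors == 10069
    assert total.total_ugt_mutations == 3427


def test_single_sample_cohort_edge_cases():
    ugt_rec = make_record("4", 20100, "C", "T", gene="UGT2B4",
                          variant_class=VariantClass.MISSENSE,
                          sample_barcode="S1")
    summ = summarize_cohorts({"TOY": ["S1"]}, {"S1": 7}, [ugt_rec] * 1)
    row = summ[summ.cohort == "TOY"].iloc[0]
    assert row.mutations_per_tumor == 7
    assert row.fraction_with_ugt == 1.0
    summ0 = summarize_cohorts({"TOY": ["S1"]}, {"S1": 7}, [])
    assert summ0[summ0.cohort == "TOY"].iloc[0].fraction_with_ugt == 0.0


def test_zero_tumor_cohort_is_error():
    with pytest.raises(ValueError):
        summarize_cohorts({"TOY": []}, {}, [])


# ---------------------------------------------------------------------------
# gene/class matrix
# ---------------------------------------------------------------------------


def test_matrix_counts_each_record_once_with_deleterious_subcount():
    recs = [
        make_record("4", 20100, "C", "T", gene="UGT2B4",
                    variant_class=VariantClass.MISSENSE,
                    sift_call=SiftCall.DELETERIOUS, sample_barcode="S1"),
        make_record("4", 20105, "G", "A", gene="UGT2B4",
                    variant_class=VariantClass.SILENT, sample_barcode="S2"),
        make_record("2", 1750, "C", "T", gene="1A E2-5",
                    variant_class=VariantClass.MISSENSE, sample_barcode="S3"),
    ]
    m = gene_type_matrix(recs)
    assert int(m.Sum.sum()) == 3  # grand total = record count, no fan-out
    row = m[m.gene == "UGT2B4"].iloc[0]
    assert row["Missense"] == 1 and row["Silent"] == 1
    assert row["Missense_deleterious"] == 1
    assert m[m.gene == "1A E2-5"].iloc[0]["Sum"] == 1


def test_empty_record_set_gives_empty_matrix():
    m = gene_type_matrix([])
    assert m.empty


def test_unclassified_record_is_hard_error():
    rec = make_record("4", 20100, "C", "T", gene="UGT2B4")
    with pytest.raises(ValueError, match="unclassified"):
        gene_type_matrix([rec])


# ---------------------------------------------------------------------------
# recurrence
# ---------------------------------------------------------------------------


def _rec(g, sample, cancer="LUAD"):
    return make_record("4", g, "C", "T", gene="UGT2B4",
                       variant_class=VariantClass.MISSENSE,
                       sample_barcode=sample, cancer_type=cancer)


def test_triplicated_key_forms_one_group():
    recs = [_rec(100, f"S{i}") for i in range(3)] + [_rec(200, "S9")]
    groups = find_recurrent(recs)
    assert len(groups) == 1 and groups[0].count == 3


def test_group_spanning_three_cancer_types():
    recs = (
        [_rec(100, "S1", "COAD")]
        + [_rec(100, f"U{i}", "UCEC") for i in range(2)]
        + [_rec(100, f"T{i}", "STAD") for i in range(5)]
    )
    groups = find_recurrent(recs)
    assert groups[0].count == 8
    assert groups[0].cancer_types == ("COAD", "STAD", "UCEC")


def test_all_unique_set_has_no_groups():
    recs = [_rec(100 + i, f"S{i}") for i in range(10)]
    assert find_recurrent(recs) == []


def test_recurrence_accounting_identity():
    """Sum of group counts + singletons = total distinct (key, sample)
    occurrences."""
    rng = np.random.default_rng(3)
    recs = [_rec(int(rng.integers(100, 120)), f"S{i}") for i in range(60)]
    groups = find_recurrent(recs)
    n_grouped = sum(g.count for g in groups)
    keys = {r.key for r in recs}
    singles = sum(
        1 for k in keys if len({r.sample_barcode for r in recs if r.key == k}) == 1
    )
    assert n_grouped + singles == len(recs)


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------


def test_published_hotspot_examples_are_recovered():
    """Seven events in a 13 bp window and six in an 11 bp window qualify
    at the default scan parameters (window 31, min 6)."""
    pos_2b4 = [1556, 1558, 1560, 1562, 1564, 1566, 1568]
    pos_3a1 = [1396, 1398, 1400, 1402, 1404, 1406]
    hits = find_hotspots({"UGT2B4": pos_2b4, "UGT3A1": pos_3a1})
    by_gene = {h.gene: h for h in hits}
    assert by_gene["UGT2B4"].span_bp == 13 and by_gene["UGT2B4"].n_mutations == 7
    assert by_gene["UGT3A1"].span_bp == 11 and by_gene["UGT3A1"].n_mutations == 6


def test_uniformly_spread_events_yield_no_hotspot():
    assert find_hotspots({"G": list(range(100, 1100, 100))}) == []


def test_scan_matches_exhaustive_window_oracle():
    rng = np.random.default_rng(17)
    for _ in range(25):
        n = int(rng.integers(5, 120))
        pos = sorted(int(p) for p in rng.integers(1, 400, size=n))
        window, min_count = int(rng.integers(5, 40)), int(rng.integers(3, 8))
        got = find_hotspots({"G": pos}, window, min_count)
        got_clusters = sorted(h.positions for h in got)
        assert got_clusters == oracle_hotspots(pos, window, min_count)


# ---------------------------------------------------------------------------
# multiplicity
# ---------------------------------------------------------------------------


def test_multiplicity_histogram_and_threshold():
    recs = []
    for sample, k in (("S1", 1), ("S2", 2), ("S3", 2), ("S4", 5)):
        recs += [_rec(100 + i + hash(sample) % 50, sample) for i in range(k)]
    dist = multiplicity_distribution(recs)
    assert dist.histogram == {1: 1, 2: 2, 5: 1}
    assert dist.n_tumors_with_ugt == 4
    assert dist.n_with_2_or_more == 3


def test_all_single_mutation_tumors():
    recs = [_rec(100 + i, f"S{i}") for i in range(5)]
    assert multiplicity_distribution(recs).n_with_2_or_more == 0


def test_multiplicity_matches_direct_recount():
    rng = np.random.default_rng(8)
    recs = [_rec(int(rng.integers(100, 400)), f"S{int(rng.integers(0, 30))}")
            for _ in range(200)]
    dist = multiplicity_distribution(recs)
    from collections import Counter

    direct = Counter(Counter(r.sample_barcode for r in recs).values())
    assert dist.histogram == dict(sorted(direct.items()))


# ---------------------------------------------------------------------------
# cross-dataset overlap
# ---------------------------------------------------------------------------


def test_overlap_counts_shared_keys():
    tcga = [_rec(100, "S1"), _rec(200, "S2"), _rec(300, "S3")]
    ccle = [_rec(100, "CELL1"), _rec(300, "CELL2"), _rec(999, "CELL3")]
    report = cross_dataset_overlap(tcga, ccle)
    assert report.total == 2
    assert report.per_gene == {"UGT2B4": 2}


def test_disjoint_sets_have_zero_overlap():
    assert cross_dataset_overlap([_rec(1, "S")], [_rec(2, "C")]).total == 0


def test_overlap_requires_allele_identity():
    a = make_record("4", 100, "C", "T", gene="UGT2B4",
                    variant_class=VariantClass.MISSENSE, sample_barcode="S")
    b = make_record("4", 100, "C", "G", gene="UGT2B4",
                    variant_class=VariantClass.MISSENSE, sample_barcode="C")
    assert cross_dataset_overlap([a], [b]).total == 0


# ---------------------------------------------------------------------------
# expression stratification
# ---------------------------------------------------------------------------


def _expr_fixture(n_high: int, n_total: int):
    recs, table = [], {}
    for i in range(n_total):
        sample = f"S{i}"
        recs.append(_rec(100 + i, sample))
        table[(sample, "UGT2B4")] = "high" if i < n_high else "low/absent"
    return recs, table


def test_expression_fraction_rounds_to_three_decimals():
    recs, table = _expr_fixture(83, 267)
    strat = expression_stratify(recs, table)
    assert (strat.numerator, strat.denominator) == (83, 267)
    assert strat.fraction == 0.311


def test_empty_expression_table_warns_and_keeps_denominator():
    recs, _ = _expr_fixture(0, 5)
    strat = expression_stratify(recs, {})
    assert strat.denominator == 5 and strat.numerator == 0
    assert strat.warnings


def test_shared_category_counts_high_if_any_member_high():
    rec = make_record("2", 1750, "C", "T", gene="1A E2-5",
                      variant_class=VariantClass.MISSENSE, sample_barcode="S1")
    rec.affected_genes = ["UGT1A1", "UGT1A9"]
    strat = expression_stratify([rec], {("S1", "UGT1A9"): "high"})
    assert strat.numerator == 1


def test_expression_matches_direct_join_recount():
    rng = np.random.default_rng(21)
    recs, table = [], {}
    for i in range(150):
        sample, gene = f"S{int(rng.integers(0, 40))}", f"G{int(rng.integers(0, 5))}"
        recs.append(
            make_record("4", 100 + i, "C", "T", gene=gene,
                        variant_class=VariantClass.MISSENSE, sample_barcode=sample)
        )
        if rng.random() < 0.5:
            table[(sample, gene)] = "high" if rng.random() < 0.4 else "low/absent"
    strat = expression_stratify(recs, table)
    direct = sum(
        1 for r in recs if table.get((r.sample_barcode, r.gene_symbol)) == "high"
    )
    assert strat.numerator == direct
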