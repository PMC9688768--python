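"""Landscape aggregation: cohort summaries, per-gene matrices, recurrence,
hotspots, multiplicity, cross-dataset overlap and expression stratification.

Reporting conventions follow the published table layouts: mutations per
tumor is the floored integer quotient, and the fraction of tumors with
UGT mutations is truncated (not rounded) to three decimals.  Shared-exon
category rows ("1A E2-5", "2A1/2A2 E2-6") are rows in their own right so
that every record is counted exactly once, never fanned out into member
genes.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import (
    MutationRecord,
    PROTEIN_ALTERING_CLASSES,
    SiftCall,
    VariantClass,
)


def floor_div(total: float, n: int) -> int:
    return int(math.floor(total / n))


def trunc3(x: float) -> float:
    """Truncate to 3 decimals (0.4589 -> 0.458), guarding float error."""
    return math.floor(x * 1000 + 1e-9) / 1000


# ---------------------------------------------------------------------------
# per-cohort summary table
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "cohort",
    "n_tumors",
    "total_mutations",
    "mutations_per_tumor",
    "n_tumors_with_ugt",
    "total_ugt_mutations",
    "n_missense_frameshift_nonsense",
    "fraction_with_ugt",
]


def build_cohort_summary(raw: pd.DataFrame) -> pd.DataFrame:
    """Derive the per-cohort summary from raw counts, plus a SUM row.

    ``raw`` needs columns: cohort, n_tumors, total_mutations,
    n_tumors_with_ugt, total_ugt_mutations, n_missense_frameshift_nonsense.
    """
    if (raw["n_tumors"] <= 0).any():
        raise ValueError("cohort with n_tumors = 0")
    df = raw.copy()
    df["mutations_per_tumor"] = [
        floor_div(t, n) for t, n in zip(df["total_mutations"], df["n_tumors"])
    ]
    df["fraction_with_ugt"] = [
        trunc3(w / n) for w, n in zip(df["n_tumors_with_ugt"], df["n_tumors"])
    ]
    totals = {
        "cohort": "SUM",
        "n_tumors": int(df["n_tumors"].sum()),
        "total_mutations": int(df["total_mutations"].sum()),
        "n_tumors_with_ugt": int(df["n_tumors_with_ugt"].sum()),
        "total_ugt_mutations": int(df["total_ugt_mutations"].sum()),
        "n_missense_frameshift_nonsense": int(
            df["n_missense_frameshift_nonsense"].sum()
        ),
    }
    totals["mutations_per_tumor"] = floor_div(
        totals["total_mutations"], totals["n_tumors"]
    )
    totals["fraction_with_ugt"] = trunc3(
        totals["n_tumors_with_ugt"] / totals["n_tumors"]
    )
    df = pd.concat([df, pd.DataFrame([totals])], ignore_index=True)
    return df[SUMMARY_COLUMNS]


def summarize_cohorts(
    cohorts: Mapping[str, Sequence[str]],
    all_counts: Mapping[str, int],
    ugt_records: Sequence[MutationRecord],
) -> pd.DataFrame:
    """Cohort summary computed from retained samples and curated records.

    ``cohorts`` maps cohort name to its sample barcodes; ``all_counts``
    gives the all-gene mutation count per sample; ``ugt_records`` are the
    curated UGT records (sample_barcode identifies the tumor).
    """
    ugt_by_sample: Counter = Counter(r.sample_barcode for r in ugt_records)
    mfn_by_sample: Counter = Counter(
        r.sample_barcode
        for r in ugt_records
        if r.variant_class in PROTEIN_ALTERING_CLASSES
    )
    rows = []
    for name in sorted(cohorts):
        samples = cohorts[name]
        if not samples:
            raise ValueError(f"cohort {name} has no samples")
        rows.append(
            {
                "cohort": name,
                "n_tumors": len(samples),
                "total_mutations": int(sum(all_counts.get(s, 0) for s in samples)),
                "n_tumors_with_ugt": sum(1 for s in samples if ugt_by_sample.get(s)),
                "total_ugt_mutations": int(
                    sum(ugt_by_sample.get(s, 0) for s in samples)
                ),
                "n_missense_frameshift_nonsense": int(
                    sum(mfn_by_sample.get(s, 0) for s in samples)
                ),
            }
        )
    return build_cohort_summary(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# per-gene variant-class matrix
# ---------------------------------------------------------------------------

MATRIX_CLASS_ORDER = [
    VariantClass.UTR5,
    VariantClass.MISSENSE,
    VariantClass.TRANSLATION_START_SITE,
    VariantClass.NONSENSE,
    VariantClass.SILENT,
    VariantClass.FRAME_SHIFT_DEL,
    VariantClass.FRAME_SHIFT_INS,
    VariantClass.IN_FRAME_DEL,
    VariantClass.IN_FRAME_INS,
    VariantClass.NONSTOP,
    VariantClass.INTRON,
    VariantClass.SPLICE_SITE,
    VariantClass.UTR3,
]


def gene_type_matrix(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """Counts of each variant class per gene (or shared-category) row.

    Each record is counted exactly once under its label; the
    ``Missense_deleterious`` column is the SIFT-deleterious sub-count and
    is not part of the row sum.  Records still carrying the quarantine
    class are an upstream contract violation and raise.
    """
    cells: dict[str, Counter] = defaultdict(Counter)
    deleterious: Counter = Counter()
    for rec in records:
        if rec.variant_class is VariantClass.QUARANTINE:
            raise ValueError(
                f"unclassified record at {rec.chrom}:{rec.g_start} "
                f"({rec.gene_symbol}) reached the matrix"
            )
        cells[rec.gene_symbol][rec.variant_class] += 1
        if (
            rec.variant_class is VariantClass.MISSENSE
            and rec.sift_call is SiftCall.DELETERIOUS
        ):
            deleterious[rec.gene_symbol] += 1
    rows = []
    for label in sorted(cells):
        row = {"gene": label}
        row.update({vc.value: cells[label].get(vc, 0) for vc in MATRIX_CLASS_ORDER})
        row["Missense_deleterious"] = deleterious.get(label, 0)
        row["Sum"] = sum(cells[label].values())
        rows.append(row)
    columns = (
        ["gene"]
        + [vc.value for vc in MATRIX_CLASS_ORDER]
        + ["Missense_deleterious", "Sum"]
    )
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns]


# ---------------------------------------------------------------------------
# recurrence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecurrentGroup:
    key: tuple[str, int, str, str, str]  # chrom, g_start, ref, alt, label
    count: int
    samples: tuple[str, ...]
    cancer_types: tuple[str, ...]


def find_recurrent(records: Sequence[MutationRecord]) -> list[RecurrentGroup]:
    """Identical mutations (chrom, position, ref, alt, gene) in >= 2 samples.

    Counts tumor-occurrences: one per distinct sample carrying the key.
    """
    by_key: dict[tuple, set[str]] = defaultdict(set)
    cancers: dict[tuple, set[str]] = defaultdict(set)
    for rec in records:
        by_key[rec.key].add(rec.sample_barcode)
        if rec.cancer_type:
            cancers[rec.key].add(rec.cancer_type)
    groups = [
        RecurrentGroup(
            key=key,
            count=len(samples),
            samples=tuple(sorted(samples)),
            cancer_types=tuple(sorted(cancers[key])),
        )
        for key, samples in by_key.items()
        if len(samples) >= 2
    ]
    groups.sort(key=lambda g: (-g.count, g.key))
    return groups


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Hotspot:
    gene: str
    c_lo: int
    c_hi: int
    n_mutations: int
    positions: tuple[int, ...]

    @property
    def span_bp(self) -> int:
        return self.c_hi - self.c_lo + 1


def find_hotspots(
    positions_by_gene: Mapping[str, Sequence[int]],
    window_bp: int = 31,
    min_count: int = 6,
) -> list[Hotspot]:
    """Windowed scan for clustered mutation events on cDNA coordinates.

    A qualifying window is any stretch of <= ``window_bp`` consecutive
    cDNA bases containing >= ``min_count`` events (events = individual
    records; recurrent events at one position all count).  Overlapping
    qualifying windows are merged and reported once as the maximal
    cluster, whose span is the distance between its outermost events.
    """
    out: list[Hotspot] = []
    for gene in sorted(positions_by_gene):
        pos = sorted(positions_by_gene[gene])
        n = len(pos)
        if n < min_count:
            continue
        # two-pointer scan for maximal qualifying index ranges
        ranges: list[tuple[int, int]] = []
        j = 0
        for i in range(n):
            if j < i:
                j = i
            while j + 1 < n and pos[j + 1] - pos[i] + 1 <= window_bp:
                j += 1
            if j - i + 1 >= min_count:
                ranges.append((i, j))
        merged: list[list[int]] = []
        for i, j in ranges:  # merge ranges sharing at least one event
            if merged and i <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], j)
            else:
                merged.append([i, j])
        for i, j in merged:
            members = tuple(pos[i : j + 1])
            out.append(
                Hotspot(
                    gene=gene,
                    c_lo=members[0],
                    c_hi=members[-1],
                    n_mutations=len(members),
                    positions=members,
                )
            )
    return out


# ---------------------------------------------------------------------------
# multiplicity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MultiplicityDistribution:
    histogram: Mapping[int, int]  # per-tumor UGT mutation count -> n tumors
    n_tumors_with_ugt: int
    n_with_2_or_more: int


def multiplicity_distribution(
    records: Sequence[MutationRecord],
    samples: Iterable[str] | None = None,
) -> MultiplicityDistribution:
    """Histogram of per-tumor UGT mutation counts within one cohort."""
    counts = Counter(r.sample_barcode for r in records)
    if samples is not None:
        allowed = set(samples)
        counts = Counter({s: c for s, c in counts.items() if s in allowed})
    hist = Counter(counts.values())
    return MultiplicityDistribution(
        histogram=dict(sorted(hist.items())),
        n_tumors_with_ugt=sum(hist.values()),
        n_with_2_or_more=sum(n for k, n in hist.items() if k >= 2),
    )


# ---------------------------------------------------------------------------
# cross-dataset overlap
# ---------------------------------------------------------------------------


@dataclass
class OverlapReport:
    total: int
    per_gene: Mapping[str, int]
    matched_keys: list[tuple]


def cross_dataset_overlap(
    tcga_records: Sequence[MutationRecord],
    ccle_records: Sequence[MutationRecord],
) -> OverlapReport:
    """Mutations present in both datasets.

    Matching requires full identity of (chrom, g_start, ref, alt,
    gene-or-category) — allele identity, not just position.  Both sets
    must already be curated onto the same canonical transcripts.
    """
    tcga_keys = {r.key for r in tcga_records}
    ccle_keys = {r.key for r in ccle_records}
    matched = sorted(tcga_keys & ccle_keys)
    per_gene: Counter = Counter(key[4] for key in matched)
    return OverlapReport(
        total=len(matched), per_gene=dict(per_gene), matched_keys=matched
    )


# ---------------------------------------------------------------------------
# expression stratification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionStratification:
    numerator: int  # mutations in tumors with high expression of the gene
    denominator: int
    fraction: float
    warnings: tuple[str, ...] = ()


def expression_stratify(
    records: Sequence[MutationRecord],
    expression_class: Mapping[tuple[str, str], str],
) -> ExpressionStratification:
    """Fraction of coding-impact mutations in tumors expressing the gene.

    ``expression_class`` maps (sample_barcode, gene) -> "high" or
    "low/absent".  A shared-category mutation counts as expressed when ANY
    affected member gene is classed high in that tumor.  Missing pairs
    count as not-high; an entirely empty table keeps the denominator and
    warns.
    """
    warnings: list[str] = []
    if not expression_class:
        warnings.append("empty expression table: numerator forced to 0")
    numerator = 0
    for rec in records:
        genes = rec.affected_genes or [rec.gene_symbol]
        if any(
            expression_class.get((rec.sample_barcode, g)) == "high" for g in genes
        ):
            numerator += 1
    denominator = len(records)
    fraction = round(numerator / denominator, 3) if denominator else 0.0
    return ExpressionStratification(
        numerator=numerator,
        denominator=denominator,
        fraction=fraction,
        warnings=tuple(warnings),
    )
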