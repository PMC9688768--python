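"""Cohort curation and gene-family-aware correction of UGT annotations.

Pan-cancer MAF releases list mutations per tumor sample, not per cancer
type, and annotate the exon-sharing UGT loci inconsistently: mutations in
one member's unique first exon can be listed as intronic for a sibling,
mutations in the shared exon block are credited to a single member, some
records are annotated on a non-canonical variant transcript, and a subset
of records labelled as UGT introns actually fall in an unrelated embedded
gene (DNAJB3).  This module assembles per-cancer cohorts, applies the
sample exclusions (recurrent tumors, non-melanoma metastases, blocklisted
samples, hypermutators), and re-annotates UGT records against the family
registry so that every record carries its true gene — or the shared
category ("1A E2-5", "2A1/2A2 E2-6") counted once — with recomputed
cDNA/protein coordinates.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .gene_models import (
    Consequence,
    CoordinateError,
    GeneFamilyRegistry,
    ReferenceMismatchError,
    TranscriptModel,
    consequence_call,
    parse_c_position,
)
from .maf_io import parse_tcga_barcode
from .records import (
    MutationRecord,
    SampleMeta,
    SampleType,
    VariantClass,
)


# ---------------------------------------------------------------------------
# cohort assembly and sample filtering
# ---------------------------------------------------------------------------


class ExclusionReason(str, enum.Enum):
    RECURRENT = "recurrent"
    METASTATIC = "metastatic"
    BLOCKLIST = "blocklist"
    HYPERMUTATED = "hypermutated"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class HypermutatorStrategy(str, enum.Enum):
    ABSOLUTE_THRESHOLD = "absolute_threshold"
    PER_COHORT_IQR = "per_cohort_iqr"


@dataclass
class CohortPolicy:
    """Which samples a cohort keeps.

    Defaults follow the study design: primary solid tumors only, except
    melanoma (SKCM) where metastatic samples form their own sub-cohort;
    hypermutators are removed by an absolute per-sample mutation-count
    threshold (the per-cohort IQR strategy is the configurable
    alternative).
    """

    metastatic_subcohort_cancers: tuple[str, ...] = ("SKCM",)
    sample_blocklist: frozenset[str] = frozenset()
    hypermutator_strategy: HypermutatorStrategy = (
        HypermutatorStrategy.ABSOLUTE_THRESHOLD
    )
    hypermutator_threshold: int = 5000
    hypermutator_iqr_k: float = 3.0

    def to_dict(self) -> dict:
        return {
            "metastatic_subcohort_cancers": list(self.metastatic_subcohort_cancers),
            "sample_blocklist": sorted(self.sample_blocklist),
            "hypermutator_strategy": self.hypermutator_strategy.value,
            "hypermutator_threshold": self.hypermutator_threshold,
            "hypermutator_iqr_k": self.hypermutator_iqr_k,
        }


@dataclass(frozen=True)
class Exclusion:
    barcode: str
    cancer_type: str
    reason: ExclusionReason
    mutation_count: int


@dataclass
class Cohorts:
    """Samples grouped by cohort name (cancer code, with melanoma split
    into ``SKCM-primary`` / ``SKCM-metastatic``)."""

    samples: dict[str, list[SampleMeta]]
    quarantined: list[SampleMeta] = field(default_factory=list)

    def all_samples(self) -> list[SampleMeta]:
        return [s for group in self.samples.values() for s in group]

    def n_samples(self) -> int:
        return sum(len(g) for g in self.samples.values())


def assign_cohorts(
    barcodes: Iterable[str],
    cancer_of: Mapping[str, str],
    policy: CohortPolicy | None = None,
) -> Cohorts:
    """Group tumor samples into per-cancer cohorts from their barcodes.

    ``cancer_of`` maps barcode (or participant id) to a study code; samples
    with no resolvable cancer type are quarantined, never dropped silently.
    Melanoma metastatic samples form the ``SKCM-metastatic`` sub-cohort.
    """
    policy = policy or CohortPolicy()
    groups: dict[str, list[SampleMeta]] = defaultdict(list)
    quarantined: list[SampleMeta] = []
    for barcode in barcodes:
        meta = parse_tcga_barcode(barcode)
        cancer = cancer_of.get(barcode) or cancer_of.get(meta.participant_id)
        if cancer is None:
            quarantined.append(meta)
            continue
        meta.cancer_type = cancer
        name = cancer
        if (
            cancer in policy.metastatic_subcohort_cancers
            and meta.sample_type is SampleType.METASTATIC
        ):
            name = f"{cancer}-metastatic"
        elif cancer in policy.metastatic_subcohort_cancers:
            name = f"{cancer}-primary"
        groups[name].append(meta)
    return Cohorts(samples=dict(groups), quarantined=quarantined)


def detect_hypermutators(
    counts: Mapping[str, int],
    strategy: HypermutatorStrategy | str = HypermutatorStrategy.ABSOLUTE_THRESHOLD,
    threshold: int = 5000,
    k: float = 3.0,
) -> set[str]:
    """Flag samples with extreme mutation counts within one cohort.

    ``absolute_threshold`` flags count > threshold; ``per_cohort_iqr``
    flags count > Q3 + k*IQR (quartiles by linear interpolation).  Both
    are deterministic; an empty cohort yields an empty set.
    """
    strategy = HypermutatorStrategy(strategy)
    if not counts:
        return set()
    if strategy is HypermutatorStrategy.ABSOLUTE_THRESHOLD:
        return {s for s, n in counts.items() if n > threshold}
    values = np.array(list(counts.values()), dtype=float)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    cut = q3 + k * (q3 - q1)
    return {s for s, n in counts.items() if n > cut}


def filter_samples(
    cohorts: Cohorts,
    policy: CohortPolicy,
    mutation_counts: Mapping[str, int],
) -> tuple[Cohorts, list[Exclusion]]:
    """Apply the sample exclusions; every input sample is retained or logged.

    Order of precedence when several reasons apply: recurrent, metastatic
    (outside the melanoma sub-cohort), blocklist, hypermutated.
    Hypermutators are detected per cohort on the samples surviving the
    other exclusions.
    """
    retained: dict[str, list[SampleMeta]] = {}
    log: list[Exclusion] = []

    def count(s: SampleMeta) -> int:
        return int(mutation_counts.get(s.barcode, 0))

    for name, samples in cohorts.samples.items():
        survivors: list[SampleMeta] = []
        for s in samples:
            if s.sample_type is SampleType.RECURRENT:
                log.append(Exclusion(s.barcode, s.cancer_type, ExclusionReason.RECURRENT, count(s)))
            elif (
                s.sample_type is SampleType.METASTATIC
                and s.cancer_type not in policy.metastatic_subcohort_cancers
            ):
                log.append(Exclusion(s.barcode, s.cancer_type, ExclusionReason.METASTATIC, count(s)))
            elif s.barcode in policy.sample_blocklist:
                log.append(Exclusion(s.barcode, s.cancer_type, ExclusionReason.BLOCKLIST, count(s)))
            else:
                survivors.append(s)
        flagged = detect_hypermutators(
            {s.barcode: count(s) for s in survivors},
            policy.hypermutator_strategy,
            threshold=policy.hypermutator_threshold,
            k=policy.hypermutator_iqr_k,
        )
        kept = []
        for s in survivors:
            if s.barcode in flagged:
                log.append(
                    Exclusion(s.barcode, s.cancer_type, ExclusionReason.HYPERMUTATED, count(s))
                )
            else:
                kept.append(s)
        if kept:
            retained[name] = kept
    out = Cohorts(samples=retained, quarantined=list(cohorts.quarantined))
    assert cohorts.n_samples() == out.n_samples() + len(log)
    return out, log


# ---------------------------------------------------------------------------
# UGT extraction and mis-annotation correction
# ---------------------------------------------------------------------------


class CorrectionRule(str, enum.Enum):
    EXON1_AS_INTRON_FIX = "exon1_as_intron_fix"
    SHARED_EXON_FANOUT = "shared_exon_fanout"
    VARIANT_TRANSCRIPT_REMAP = "variant_transcript_remap"
    DECOY_DROP = "decoy_drop"
    NONE = "none"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class CorrectionRecord:
    original_gene: str
    original_class: VariantClass
    original_transcript: str
    corrected_label: str  # gene symbol or shared-category label
    affected_genes: tuple[str, ...]
    rule_applied: CorrectionRule


@dataclass(frozen=True)
class DropEntry:
    record: MutationRecord
    reason: str  # "decoy:<label>", "non-UGT", "conflict:<detail>"


#: intronic padding around a shared exon block / unique exon used when
#: attributing splice-dinucleotide and near-exon intron records
_FLANK_PAD = 10


def _recompute(
    tm: TranscriptModel, record: MutationRecord
) -> Consequence:
    return consequence_call(tm, record)


def extract_and_correct_ugt(
    records: Sequence[MutationRecord],
    registry: GeneFamilyRegistry,
) -> tuple[list[tuple[MutationRecord, CorrectionRecord]], list[DropEntry]]:
    """Re-annotate records against the family registry.

    For each record, in order: records inside a decoy interval are dropped
    and logged; records in (or flanking) a shared exon block are assigned
    the family's shared-category label with the full member fan-out and
    re-annotated on the family's canonical transcript — counted once
    downstream; records in a member's unique region are assigned that gene
    with class and c./p. recomputed (fixing sibling-intron mislabels);
    records overlapping nothing in the registry are dropped as non-UGT.
    Records whose reference allele contradicts the transcript sequence are
    quarantined as conflicts.
    """
    corrected: list[tuple[MutationRecord, CorrectionRecord]] = []
    drops: list[DropEntry] = []
    tms_by_id = registry.transcripts_by_id()

    for rec in records:
        decoy = registry.decoy_at(rec.chrom, rec.g_start)
        if decoy is not None:
            drops.append(DropEntry(rec, f"decoy:{decoy.label}"))
            continue

        fam = _shared_family_near(registry, rec.chrom, rec.g_start)
        if fam is not None:
            tm = tms_by_id[fam.canonical_transcript]
            label = fam.shared_category_label
            try:
                cons = _recompute(tm, rec)
            except (ReferenceMismatchError, CoordinateError) as exc:
                drops.append(DropEntry(rec, f"conflict:{exc}"))
                continue
            if registry.is_variant_transcript(rec.transcript_id):
                rule = CorrectionRule.VARIANT_TRANSCRIPT_REMAP
            elif (
                rec.gene_symbol == label
                and rec.variant_class is cons.variant_class
                and (not rec.cdna_change or rec.cdna_change == cons.cdna)
            ):
                rule = CorrectionRule.NONE
            else:
                rule = CorrectionRule.SHARED_EXON_FANOUT
            fixed = _apply(rec, label, cons, tm, tuple(fam.member_genes))
            corrected.append(
                (
                    fixed,
                    CorrectionRecord(
                        original_gene=rec.gene_symbol,
                        original_class=rec.variant_class,
                        original_transcript=rec.transcript_id,
                        corrected_label=label,
                        affected_genes=tuple(fam.member_genes),
                        rule_applied=rule,
                    ),
                )
            )
            continue

        gene = registry.unique_region_gene(rec.chrom, rec.g_start)
        if gene is None:
            drops.append(DropEntry(rec, "non-UGT"))
            continue
        tm = registry.transcripts[gene]
        try:
            cons = _recompute(tm, rec)
        except (ReferenceMismatchError, CoordinateError) as exc:
            drops.append(DropEntry(rec, f"conflict:{exc}"))
            continue
        if (
            rec.gene_symbol == gene
            and rec.variant_class is cons.variant_class
            and (not rec.cdna_change or rec.cdna_change == cons.cdna)
        ):
            rule = CorrectionRule.NONE
        else:
            rule = CorrectionRule.EXON1_AS_INTRON_FIX
        fixed = _apply(rec, gene, cons, tm, (gene,))
        corrected.append(
            (
                fixed,
                CorrectionRecord(
                    original_gene=rec.gene_symbol,
                    original_class=rec.variant_class,
                    original_transcript=rec.transcript_id,
                    corrected_label=gene,
                    affected_genes=(gene,),
                    rule_applied=rule,
                ),
            )
        )
    return corrected, drops


def _shared_family_near(registry: GeneFamilyRegistry, chrom: str, g: int):
    fam = registry.shared_family_at(chrom, g)
    if fam is not None:
        return fam
    for family in registry.families:
        for iv in family.shared_exons:
            if iv.contains(chrom, max(1, g - _FLANK_PAD)) or iv.contains(
                chrom, g + _FLANK_PAD
            ):
                # flanking intronic bases between two shared exons, or just
                # outside the block edge: attribute to the family
                return family
    return None


def _apply(
    rec: MutationRecord,
    label: str,
    cons: Consequence,
    tm: TranscriptModel,
    affected: tuple[str, ...],
) -> MutationRecord:
    fixed = replace(
        rec,
        gene_symbol=label,
        variant_class=cons.variant_class,
        transcript_id=tm.transcript_id,
        cdna_change=cons.cdna,
        protein_change=cons.protein,
    )
    fixed.affected_genes = list(affected)
    return fixed


# ---------------------------------------------------------------------------
# annotation consistency verification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Conflict:
    kind: str  # "position_mismatch" | "unparseable"
    stated: str
    recomputed: str


def verify_annotation_consistency(
    record: MutationRecord, tm: TranscriptModel
) -> Conflict | None:
    """Cross-check a record's stated c. string against its genomic position.

    Returns None when consistent (or when there is nothing to check: empty
    c. strings on UTR/intron classes).  Conflicted records are excluded
    from downstream counts by the caller.
    """
    stated = record.cdna_change.strip()
    if not stated:
        return None
    parsed = parse_c_position(stated)
    if parsed is None:
        return Conflict("unparseable", stated, "")
    try:
        cons = consequence_call(tm, record)
    except (ReferenceMismatchError, CoordinateError) as exc:
        return Conflict("position_mismatch", stated, str(exc))
    recomputed = parse_c_position(cons.cdna) if cons.cdna else None
    if recomputed is None:
        return Conflict("position_mismatch", stated, cons.cdna or "<none>")
    if parsed != recomputed:
        return Conflict("position_mismatch", stated, cons.cdna)
    return None
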