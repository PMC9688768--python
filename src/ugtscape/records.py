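"""Core record types shared across the pipeline.

A :class:`MutationRecord` is one somatic mutation as listed in a MAF-style
table: genomic coordinates (1-based inclusive, GRCh37 convention), alleles
("-" marks the empty side of a pure insertion/deletion, per MAF convention),
the variant classification, optional cDNA/protein HGVS-like strings, a SIFT
call for missense variants, and the originating sample.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class VariantClass(str, enum.Enum):
    """Closed set of variant classifications used throughout the pipeline.

    Unknown input labels are quarantined rather than coerced, because MAF
    producers disagree on the long tail of classification strings.
    """

    UTR5 = "5'UTR"
    UTR3 = "3'UTR"
    MISSENSE = "Missense"
    NONSENSE = "Nonsense"
    SILENT = "Silent"
    TRANSLATION_START_SITE = "Translation_Start_Site"
    NONSTOP = "Nonstop"
    FRAME_SHIFT_DEL = "Frame_Shift_Del"
    FRAME_SHIFT_INS = "Frame_Shift_Ins"
    IN_FRAME_DEL = "In_Frame_Del"
    IN_FRAME_INS = "In_Frame_Ins"
    INTRON = "Intron"
    SPLICE_SITE = "Splice_Site"
    QUARANTINE = "Quarantine"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The 13 analysable classes (everything except the quarantine bucket).
CANONICAL_CLASSES: tuple[VariantClass, ...] = tuple(
    c for c in VariantClass if c is not VariantClass.QUARANTINE
)

#: Classes that alter the protein sequence (missense / frameshift / nonsense
#: group used by the per-cohort summary tables).
PROTEIN_ALTERING_CLASSES: frozenset[VariantClass] = frozenset(
    {
        VariantClass.MISSENSE,
        VariantClass.NONSENSE,
        VariantClass.FRAME_SHIFT_DEL,
        VariantClass.FRAME_SHIFT_INS,
    }
)

#: Aliases seen in MC3 / DepMap / cBioPortal classification columns.
MAF_CLASS_ALIASES: dict[str, VariantClass] = {
    "5'UTR": VariantClass.UTR5,
    "5'utr": VariantClass.UTR5,
    "Five_prime_UTR": VariantClass.UTR5,
    "3'UTR": VariantClass.UTR3,
    "3'utr": VariantClass.UTR3,
    "Three_prime_UTR": VariantClass.UTR3,
    "Missense_Mutation": VariantClass.MISSENSE,
    "Missense": VariantClass.MISSENSE,
    "Nonsense_Mutation": VariantClass.NONSENSE,
    "Nonsense": VariantClass.NONSENSE,
    "Silent": VariantClass.SILENT,
    "Synonymous": VariantClass.SILENT,
    "Translation_Start_Site": VariantClass.TRANSLATION_START_SITE,
    "Start_Codon_SNP": VariantClass.TRANSLATION_START_SITE,
    "Nonstop_Mutation": VariantClass.NONSTOP,
    "Nonstop": VariantClass.NONSTOP,
    "Frame_Shift_Del": VariantClass.FRAME_SHIFT_DEL,
    "Frame_Shift_Ins": VariantClass.FRAME_SHIFT_INS,
    "In_Frame_Del": VariantClass.IN_FRAME_DEL,
    "In_Frame_Ins": VariantClass.IN_FRAME_INS,
    "Intron": VariantClass.INTRON,
    "Splice_Site": VariantClass.SPLICE_SITE,
}


def classify_label(label: str) -> VariantClass:
    """Map a raw classification string to the closed enum (quarantining unknowns)."""
    label = label.strip()
    if label in MAF_CLASS_ALIASES:
        return MAF_CLASS_ALIASES[label]
    try:
        return VariantClass(label)
    except ValueError:
        return VariantClass.QUARANTINE


class VariantType(str, enum.Enum):
    SNP = "SNP"
    DEL = "DEL"
    INS = "INS"
    DNP = "DNP"  # dinucleotide / other multi-base substitutions

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SiftCall(str, enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    NOT_ASSESSED = "not_assessed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def parse_sift(raw: str) -> SiftCall:
    """Parse SIFT column text such as ``deleterious(0.01)`` or ``tolerated(0.2)``."""
    raw = raw.strip().lower()
    if raw.startswith("deleterious"):
        return SiftCall.DELETERIOUS
    if raw.startswith("tolerated"):
        return SiftCall.TOLERATED
    return SiftCall.NOT_ASSESSED


class Source(str, enum.Enum):
    TCGA = "TCGA"
    CCLE = "CCLE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SampleType(str, enum.Enum):
    PRIMARY_SOLID = "primary_solid"
    RECURRENT = "recurrent"
    PRIMARY_BLOOD = "primary_blood"
    METASTATIC = "metastatic"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: TCGA sample-type codes (4th barcode field, first two characters).
#: Unknown codes map to ``other`` — the lookup never raises.
SAMPLE_TYPE_CODES: dict[str, SampleType] = {
    "01": SampleType.PRIMARY_SOLID,
    "02": SampleType.RECURRENT,
    "03": SampleType.PRIMARY_BLOOD,
    "04": SampleType.RECURRENT,  # recurrent blood-derived (bone marrow)
    "05": SampleType.OTHER,  # additional new primary
    "06": SampleType.METASTATIC,
    "07": SampleType.METASTATIC,  # additional metastatic
    "09": SampleType.PRIMARY_BLOOD,
}


@dataclass
class SampleMeta:
    """Sample identity parsed from a TCGA barcode plus the cohort assignment."""

    barcode: str
    participant_id: str
    sample_type_code: str
    sample_type: SampleType
    cancer_type: str = ""


class RecordError(ValueError):
    """A mutation record violates its structural invariants."""


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr`` prefix so sources with mixed styles agree."""
    chrom = chrom.strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


@dataclass
class MutationRecord:
    """One somatic mutation (see module docstring for conventions)."""

    gene_symbol: str
    chrom: str
    g_start: int
    g_end: int
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass
    variant_type: VariantType
    sample_barcode: str
    transcript_id: str = ""
    cdna_change: str = ""
    protein_change: str = ""
    sift_call: SiftCall = SiftCall.NOT_ASSESSED
    source: Source = Source.TCGA
    cancer_type: str = ""
    #: populated by curation for shared-exon records (family fan-out)
    affected_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        self.validate()

    def validate(self) -> None:
        if self.g_start > self.g_end:
            raise RecordError(
                f"g_start {self.g_start} > g_end {self.g_end} for {self.gene_symbol}"
            )
        if (
            self.ref_allele == self.alt_allele
            and self.ref_allele != "-"
        ):
            raise RecordError(
                f"ref and alt alleles identical ({self.ref_allele}) at "
                f"{self.chrom}:{self.g_start}"
            )

    @property
    def key(self) -> tuple[str, int, str, str, str]:
        """Identity key used for recurrence and cross-dataset matching."""
        return (
            self.chrom,
            self.g_start,
            self.ref_allele,
            self.alt_allele,
            self.gene_symbol,
        )

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele != "-"
            and self.alt_allele != "-"
        )
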