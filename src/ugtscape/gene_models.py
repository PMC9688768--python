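"""Transcript models, coordinate mapping and consequence calling.

The UGT loci are unusual: the nine UGT1A genes share exons 2–5 and
UGT2A1/UGT2A2 share exons 2–6, with unique first exons spliced onto the
common block.  This module represents transcript structures explicitly and
provides strand-aware genomic↔cDNA↔protein mapping, region location
(CDS / UTRs / introns / canonical splice dinucleotides), consequence
calling by codon translation, and HGVS-like rendering.

Conventions: genomic coordinates are 1-based inclusive; c.1 is the A of the
initiator ATG; 3'UTR offsets are 1-based from the first base after the stop
codon (``*1``); splice offsets count intronic bases away from the exon
boundary (donor offset 1 = the G of GT, acceptor offset 1 = the G of AG).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .records import MutationRecord, VariantClass, normalize_chrom


class RegistryError(ValueError):
    """A transcript or registry invariant is violated at load time."""


class CoordinateError(ValueError):
    """A position falls outside the domain of the requested mapping."""


class ReferenceMismatchError(ValueError):
    """A record's reference allele disagrees with the transcript sequence."""


class Strand(str, enum.Enum):
    PLUS = "+"
    MINUS = "-"


class ExonRole(str, enum.Enum):
    UNIQUE = "unique"
    SHARED = "shared"


@dataclass(frozen=True)
class ExonInterval:
    index: int  # 1-based, transcript order
    g_start: int
    g_end: int
    role: ExonRole = ExonRole.UNIQUE

    def __post_init__(self) -> None:
        if self.g_start > self.g_end:
            raise RegistryError(f"exon {self.index}: g_start > g_end")

    def __len__(self) -> int:
        return self.g_end - self.g_start + 1

    def contains(self, g: int) -> bool:
        return self.g_start <= g <= self.g_end


class RegionKind(str, enum.Enum):
    CDS = "CDS"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTRON = "intron"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    OUTSIDE = "outside"


#: severity used when a variant spans several regions (most severe wins)
_SEVERITY = {
    RegionKind.CDS: 4,
    RegionKind.SPLICE_DONOR: 3,
    RegionKind.SPLICE_ACCEPTOR: 3,
    RegionKind.UTR5: 2,
    RegionKind.UTR3: 2,
    RegionKind.INTRON: 1,
    RegionKind.OUTSIDE: 0,
}


@dataclass(frozen=True)
class RegionCall:
    kind: RegionKind
    exon_or_intron_index: int = 0
    c_pos: int | None = None  # set when kind == CDS
    utr5_offset: int | None = None  # bases before the A of ATG (1 = adjacent)
    utr3_offset: int | None = None  # *N offset (1 = first base after stop)
    splice_offset: int | None = None  # 1 or 2, distance from the exon


@dataclass
class TranscriptModel:
    """One transcript: exon structure, strand, CDS sequence and UTR context.

    ``utr5_seq_window`` is the 23-base transcript-sense sequence covering
    positions −10..+13 around the start codon (position +1 = A of ATG), the
    window used for Kozak-context assessment.
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: Strand
    exons: list[ExonInterval]
    cds_g_start: int  # genomic lower bound of coding region
    cds_g_end: int  # genomic upper bound of coding region
    cds_seq: str
    utr5_seq_window: str = ""
    utr3_seq: str = ""

    # ---- derived, built in __post_init__ ----
    _tx_positions: list[int] = field(default_factory=list, repr=False)
    _g_to_tx: dict[int, int] = field(default_factory=dict, repr=False)
    _cds_tx_start: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        self.strand = Strand(self.strand)
        self.cds_seq = self.cds_seq.upper()
        self.utr5_seq_window = self.utr5_seq_window.upper()
        self.utr3_seq = self.utr3_seq.upper()
        self._validate_exons()
        self._index()
        self._validate_cds()

    # -- validation ------------------------------------------------------
    def _validate_exons(self) -> None:
        if not self.exons:
            raise RegistryError(f"{self.gene}: transcript has no exons")
        order = sorted(self.exons, key=lambda e: e.index)
        if [e.index for e in order] != list(range(1, len(order) + 1)):
            raise RegistryError(f"{self.gene}: exon indices must be 1..n")
        genomic = sorted(order, key=lambda e: e.g_start)
        for a, b in zip(genomic, genomic[1:]):
            if a.g_end >= b.g_start:
                raise RegistryError(f"{self.gene}: exons overlap")
        # transcript order must run 5'→3' in transcript sense
        starts = [e.g_start for e in order]
        if self.strand is Strand.PLUS:
            if starts != sorted(starts):
                raise RegistryError(f"{self.gene}: + strand exons not ascending")
        else:
            if starts != sorted(starts, reverse=True):
                raise RegistryError(f"{self.gene}: - strand exons not descending")
        self.exons = order

    def _index(self) -> None:
        positions: list[int] = []
        for exon in self.exons:
            span = range(exon.g_start, exon.g_end + 1)
            positions.extend(span if self.strand is Strand.PLUS else reversed(span))
        self._tx_positions = positions
        self._g_to_tx = {g: i + 1 for i, g in enumerate(positions)}
        cds_5p = self.cds_g_start if self.strand is Strand.PLUS else self.cds_g_end
        if cds_5p not in self._g_to_tx:
            raise RegistryError(f"{self.gene}: CDS 5' bound not inside an exon")
        self._cds_tx_start = self._g_to_tx[cds_5p]

    def _validate_cds(self) -> None:
        n = len(self.cds_seq)
        if n == 0 or n % 3:
            raise RegistryError(f"{self.gene}: CDS length {n} not a positive multiple of 3")
        if not self.cds_seq.startswith("ATG"):
            raise RegistryError(f"{self.gene}: CDS does not start with ATG")
        if self.cds_seq[-3:] not in ("TAA", "TAG", "TGA"):
            raise RegistryError(f"{self.gene}: CDS does not end with a stop codon")
        if len(self._tx_positions) < n:
            raise RegistryError(f"{self.gene}: spliced exon length < CDS length")
        if self._cds_tx_start + n - 1 > len(self._tx_positions):
            raise RegistryError(f"{self.gene}: CDS runs off the transcript")

    # -- basic accessors -------------------------------------------------
    @property
    def cds_len(self) -> int:
        return len(self.cds_seq)

    @property
    def protein_len(self) -> int:
        """Residues excluding the terminal stop."""
        return self.cds_len // 3 - 1

    @property
    def footprint(self) -> tuple[int, int]:
        return (
            min(e.g_start for e in self.exons),
            max(e.g_end for e in self.exons),
        )

    def tx_index(self, g: int) -> int | None:
        """1-based transcript position of a genomic base, or None if intronic."""
        return self._g_to_tx.get(g)

    def transcript_sense(self, allele: str) -> str:
        """Convert a plus-strand allele string to transcript sense."""
        if allele == "-" or not allele:
            return allele
        if self.strand is Strand.PLUS:
            return allele.upper()
        return str(Seq(allele.upper()).reverse_complement())

    # -- coordinate mapping ----------------------------------------------
    def genomic_to_cdna(self, g: int) -> int:
        tx = self.tx_index(g)
        if tx is None:
            raise CoordinateError(f"{self.gene}: g.{g} is not exonic")
        c = tx - self._cds_tx_start + 1
        if not 1 <= c <= self.cds_len:
            raise CoordinateError(f"{self.gene}: g.{g} lies outside the CDS")
        return c

    def cdna_to_genomic(self, c: int) -> int:
        if not 1 <= c <= self.cds_len:
            raise CoordinateError(f"{self.gene}: c.{c} outside 1..{self.cds_len}")
        return self._tx_positions[self._cds_tx_start + c - 2]

    def utr5_to_genomic(self, n: int) -> int:
        """Genomic position of the n-th base before the A of ATG (n >= 1)."""
        idx = self._cds_tx_start - n
        if idx < 1:
            raise CoordinateError(f"{self.gene}: -{n} runs off the transcript")
        return self._tx_positions[idx - 1]

    def utr3_to_genomic(self, n: int) -> int:
        """Genomic position of 3'UTR offset *n (n = 1 just after the stop)."""
        idx = self._cds_tx_start + self.cds_len - 1 + n
        if idx > len(self._tx_positions):
            raise CoordinateError(f"{self.gene}: *{n} runs off the transcript")
        return self._tx_positions[idx - 1]

    def splice_site_genomic(self, intron_index: int, side: str, offset: int) -> int:
        """Genomic base of a splice dinucleotide position (offset 1 or 2
        intronic bases from the exon) for intron ``intron_index`` (between
        exons i and i+1 in transcript order)."""
        if not 1 <= intron_index <= len(self.exons) - 1:
            raise CoordinateError(f"{self.gene}: no intron {intron_index}")
        if offset not in (1, 2):
            raise CoordinateError("splice offset must be 1 or 2")
        up = self.exons[intron_index - 1]
        down = self.exons[intron_index]
        if side == "donor":
            return up.g_end + offset if self.strand is Strand.PLUS else up.g_start - offset
        if side == "acceptor":
            return down.g_start - offset if self.strand is Strand.PLUS else down.g_end + offset
        raise CoordinateError(f"unknown splice side {side!r}")

    # -- region location -------------------------------------------------
    def _locate_point(self, g: int) -> RegionCall:
        lo, hi = self.footprint
        if not lo <= g <= hi:
            return RegionCall(RegionKind.OUTSIDE)
        tx = self.tx_index(g)
        if tx is not None:
            exon_idx = next(e.index for e in self.exons if e.contains(g))
            c = tx - self._cds_tx_start + 1
            if c < 1:
                return RegionCall(RegionKind.UTR5, exon_idx, utr5_offset=1 - c)
            if c <= self.cds_len:
                return RegionCall(RegionKind.CDS, exon_idx, c_pos=c)
            return RegionCall(RegionKind.UTR3, exon_idx, utr3_offset=c - self.cds_len)
        # intronic: find flanking exons in transcript sense
        for k in range(len(self.exons) - 1):
            up, down = self.exons[k], self.exons[k + 1]  # transcript order
            if self.strand is Strand.PLUS:
                left, right = up.g_end, down.g_start
                if not left < g < right:
                    continue
                donor_dist = g - left  # bases past the upstream exon
                acceptor_dist = right - g
            else:
                left, right = down.g_end, up.g_start
                if not left < g < right:
                    continue
                donor_dist = right - g
                acceptor_dist = g - left
            intron_idx = k + 1
            if donor_dist in (1, 2):
                return RegionCall(RegionKind.SPLICE_DONOR, intron_idx, splice_offset=donor_dist)
            if acceptor_dist in (1, 2):
                return RegionCall(
                    RegionKind.SPLICE_ACCEPTOR, intron_idx, splice_offset=acceptor_dist
                )
            return RegionCall(RegionKind.INTRON, intron_idx)
        return RegionCall(RegionKind.OUTSIDE)


def locate_region(tm: TranscriptModel, g_start: int, g_end: int | None = None) -> RegionCall:
    """Locate a position (or spanning interval) on a transcript.

    Spanning variants take the most severe overlapping region
    (CDS > splice > UTR > intron); the representative call keeps the
    coordinates of the most severe base nearest ``g_start``.
    """
    if g_start < 1:
        raise CoordinateError(f"position {g_start} off chromosome")
    if g_end is None or g_end <= g_start:
        return tm._locate_point(g_start)
    best = RegionCall(RegionKind.OUTSIDE)
    for g in range(g_start, g_end + 1):
        call = tm._locate_point(g)
        if _SEVERITY[call.kind] > _SEVERITY[best.kind]:
            best = call
            if _SEVERITY[best.kind] == 4:
                break
    return best


def genomic_to_cdna(tm: TranscriptModel, g: int) -> int:
    return tm.genomic_to_cdna(g)


def cdna_to_genomic(tm: TranscriptModel, c: int) -> int:
    return tm.cdna_to_genomic(c)


# ---------------------------------------------------------------------------
# consequence calling
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class Consequence:
    variant_class: VariantClass
    cdna: str = ""
    protein: str = ""
    region: RegionCall | None = None


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def _translate(seq: str) -> str:
    usable = seq[: len(seq) - len(seq) % 3]
    return str(Seq(usable).translate())


def _frameshift_protein(tm: TranscriptModel, mutant_cds: str, first_c: int) -> str:
    """p.XnYfsTer{k}: translate the shifted sequence until the first stop.

    The search substrate extends into the 3'UTR so a shifted frame that
    runs past the old stop can still find its new termination codon.
    """
    ref_prot = _translate(tm.cds_seq)
    mut_prot = _translate(mutant_cds + tm.utr3_seq)
    start_res = (first_c - 1) // 3  # 0-based residue of first touched codon
    # first residue that actually differs (HGVS: first altered residue)
    i = start_res
    while i < len(ref_prot) and i < len(mut_prot) and ref_prot[i] == mut_prot[i]:
        i += 1
    if i >= len(mut_prot):
        return f"p.{_aa3(ref_prot[min(i, len(ref_prot) - 1)])}{i + 1}fs"
    new_aa = mut_prot[i]
    ref_aa = ref_prot[i] if i < len(ref_prot) else "?"
    if new_aa == "*":
        return f"p.{_aa3(ref_aa)}{i + 1}Ter"
    stop_rel = mut_prot[i:].find("*")
    ter = f"Ter{stop_rel + 1}" if stop_rel >= 0 else "Ter?"
    return f"p.{_aa3(ref_aa)}{i + 1}{_aa3(new_aa)}fs{ter}"


def consequence_call(tm: TranscriptModel, record: MutationRecord) -> Consequence:
    """Classify a mutation on a transcript and render its c./p. strings.

    CDS SNVs are classified by translating the affected codon before and
    after the change; CDS indels by frame arithmetic (frameshift when the
    length is not a multiple of 3) with the frameshift protein obtained by
    translating the shifted sequence until the first stop.  Non-CDS
    positions take their class from :func:`locate_region`.
    """
    region = locate_region(tm, record.g_start, record.g_end)
    kind = region.kind
    if kind is RegionKind.OUTSIDE:
        raise CoordinateError(
            f"{record.chrom}:{record.g_start} does not overlap {tm.gene}"
        )
    if kind is RegionKind.UTR5:
        return Consequence(VariantClass.UTR5, *_render_noncds(tm, record, region), region)
    if kind is RegionKind.UTR3:
        return Consequence(VariantClass.UTR3, *_render_noncds(tm, record, region), region)
    if kind in (RegionKind.SPLICE_DONOR, RegionKind.SPLICE_ACCEPTOR):
        return Consequence(VariantClass.SPLICE_SITE, "", "", region)
    if kind is RegionKind.INTRON:
        return Consequence(VariantClass.INTRON, "", "", region)

    # ---- CDS ----
    ref_t = tm.transcript_sense(record.ref_allele)
    alt_t = tm.transcript_sense(record.alt_allele)

    if record.is_snv:
        c = region.c_pos
        assert c is not None
        if tm.cds_seq[c - 1] != ref_t:
            raise ReferenceMismatchError(
                f"{tm.gene} c.{c}: reference allele {ref_t} != CDS base {tm.cds_seq[c - 1]}"
            )
        codon_i = (c - 1) // 3
        codon = tm.cds_seq[codon_i * 3 : codon_i * 3 + 3]
        mutant = codon[: (c - 1) % 3] + alt_t + codon[(c - 1) % 3 + 1 :]
        old_aa = _translate(codon)
        new_aa = _translate(mutant)
        cdna = f"c.{c}{ref_t}>{alt_t}"
        if codon_i == 0:
            return Consequence(
                VariantClass.TRANSLATION_START_SITE, cdna, "p.Met1?", region
            )
        prot = f"p.{_aa3(old_aa)}{codon_i + 1}{_aa3(new_aa)}"
        if old_aa == new_aa:
            return Consequence(VariantClass.SILENT, cdna, prot, region)
        if old_aa == "*":
            return Consequence(VariantClass.NONSTOP, cdna, prot, region)
        if new_aa == "*":
            return Consequence(VariantClass.NONSENSE, cdna, prot, region)
        return Consequence(VariantClass.MISSENSE, cdna, prot, region)

    # ---- CDS indels (located by g_start; alleles in transcript sense) ----
    if record.alt_allele == "-":  # deletion
        # map the deleted genomic run onto cDNA coordinates
        c_ends = sorted(
            tm.genomic_to_cdna(g) for g in (record.g_start, record.g_end)
        )
        c_lo, c_hi = c_ends[0], c_ends[-1]
        del_len = c_hi - c_lo + 1
        deleted = tm.cds_seq[c_lo - 1 : c_hi]
        if ref_t and ref_t != "-" and deleted != ref_t:
            raise ReferenceMismatchError(
                f"{tm.gene} c.{c_lo}_{c_hi}: deletion {ref_t} != CDS {deleted}"
            )
        mutant_cds = tm.cds_seq[: c_lo - 1] + tm.cds_seq[c_hi:]
        cdna = (
            f"c.{c_lo}del{deleted}"
            if del_len == 1
            else f"c.{c_lo}_{c_hi}del{deleted}"
        )
        if del_len % 3:
            prot = _frameshift_protein(tm, mutant_cds, c_lo)
            return Consequence(VariantClass.FRAME_SHIFT_DEL, cdna, prot, region)
        res_lo = (c_lo - 1) // 3 + 1
        res_hi = (c_hi - 1) // 3 + 1
        ref_prot = _translate(tm.cds_seq)
        prot = (
            f"p.{_aa3(ref_prot[res_lo - 1])}{res_lo}del"
            if res_lo == res_hi
            else f"p.{_aa3(ref_prot[res_lo - 1])}{res_lo}_{_aa3(ref_prot[res_hi - 1])}{res_hi}del"
        )
        return Consequence(VariantClass.IN_FRAME_DEL, cdna, prot, region)

    if record.ref_allele == "-":  # insertion after g_start (transcript sense)
        c_anchor = region.c_pos
        assert c_anchor is not None
        ins = alt_t
        # insertion goes between the anchor base and its transcript-sense successor
        mutant_cds = tm.cds_seq[:c_anchor] + ins + tm.cds_seq[c_anchor:]
        cdna = f"c.{c_anchor}_{c_anchor + 1}ins{ins}"
        if len(ins) % 3:
            prot = _frameshift_protein(tm, mutant_cds, c_anchor + 1)
            return Consequence(VariantClass.FRAME_SHIFT_INS, cdna, prot, region)
        res = (c_anchor - 1) // 3 + 1
        return Consequence(VariantClass.IN_FRAME_INS, cdna, f"p.{res}ins", region)

    # multi-base substitution: quarantined (out of modelling scope)
    return Consequence(VariantClass.QUARANTINE, "", "", region)


def _render_noncds(
    tm: TranscriptModel, record: MutationRecord, region: RegionCall
) -> tuple[str, str]:
    ref_t = tm.transcript_sense(record.ref_allele)
    alt_t = tm.transcript_sense(record.alt_allele)
    if region.kind is RegionKind.UTR3 and record.is_snv:
        return f"*{region.utr3_offset}{ref_t}>{alt_t}", ""
    if region.kind is RegionKind.UTR5 and record.is_snv:
        return f"c.-{region.utr5_offset}{ref_t}>{alt_t}", ""
    return "", ""


def render_hgvs(
    tm: TranscriptModel, record: MutationRecord
) -> tuple[str, str]:
    """Convenience wrapper returning the (c., p.) strings for a record."""
    cons = consequence_call(tm, record)
    return cons.cdna, cons.protein


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    g_start: int
    g_end: int
    label: str = ""

    def contains(self, chrom: str, g: int) -> bool:
        return normalize_chrom(chrom) == self.chrom and self.g_start <= g <= self.g_end


@dataclass
class GeneFamily:
    family_id: str
    member_genes: list[str]
    shared_exons: list[GenomicInterval]
    shared_category_label: str
    canonical_transcript: str  # member transcript used for shared-block c./p.

    def contains(self, chrom: str, g: int) -> bool:
        return any(iv.contains(chrom, g) for iv in self.shared_exons)


@dataclass
class VariantTranscriptRule:
    """A known alternative transcript whose annotations must be remapped."""

    variant_id: str
    canonical_gene: str


@dataclass
class GeneFamilyRegistry:
    """All UGT transcript models plus family topology and decoy intervals."""

    transcripts: dict[str, TranscriptModel]
    families: list[GeneFamily]
    decoy_intervals: list[GenomicInterval]
    variant_transcripts: list[VariantTranscriptRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check()

    def _check(self) -> None:
        for fam in self.families:
            owners = [
                g
                for g in fam.member_genes
                if g in self.transcripts
            ]
            if len(owners) < 2:
                raise RegistryError(f"family {fam.family_id}: fewer than 2 members")
            for iv in fam.shared_exons:
                n_own = sum(
                    1
                    for g in fam.member_genes
                    if any(
                        e.g_start <= iv.g_start and iv.g_end <= e.g_end
                        for e in self.transcripts[g].exons
                    )
                    and self.transcripts[g].chrom == iv.chrom
                )
                if n_own < 2:
                    raise RegistryError(
                        f"family {fam.family_id}: shared interval "
                        f"{iv.g_start}-{iv.g_end} owned by <2 members"
                    )
        for decoy in self.decoy_intervals:
            for tm in self.transcripts.values():
                if tm.chrom != decoy.chrom:
                    continue
                for e in tm.exons:
                    if e.g_start <= decoy.g_end and decoy.g_start <= e.g_end:
                        raise RegistryError(
                            f"decoy {decoy.label} overlaps exon of {tm.gene}"
                        )

    # -- queries ---------------------------------------------------------
    def family_of(self, gene: str) -> GeneFamily | None:
        for fam in self.families:
            if gene in fam.member_genes:
                return fam
        return None

    def family_for_label(self, label: str) -> GeneFamily | None:
        for fam in self.families:
            if fam.shared_category_label == label:
                return fam
        return None

    def shared_family_at(self, chrom: str, g: int) -> GeneFamily | None:
        for fam in self.families:
            if fam.contains(chrom, g):
                return fam
        return None

    def decoy_at(self, chrom: str, g: int) -> GenomicInterval | None:
        for decoy in self.decoy_intervals:
            if decoy.contains(chrom, g):
                return decoy
        return None

    def is_variant_transcript(self, transcript_id: str) -> bool:
        return any(v.variant_id == transcript_id for v in self.variant_transcripts)

    def unique_region_gene(self, chrom: str, g: int) -> str | None:
        """Gene whose unique (non-shared) exon-or-intron footprint contains g."""
        chrom = normalize_chrom(chrom)
        for gene, tm in self.transcripts.items():
            if tm.chrom != chrom:
                continue
            lo, hi = tm.footprint
            if not lo <= g <= hi:
                continue
            if self.shared_family_at(chrom, g) is not None:
                continue
            fam = self.family_of(gene)
            if fam is not None:
                # only this member's own unique stretch, not siblings' regions
                unique_exons = [e for e in tm.exons if e.role is ExonRole.UNIQUE]
                if not unique_exons:
                    continue
                u_lo = min(e.g_start for e in unique_exons)
                u_hi = max(e.g_end for e in unique_exons)
                pad = 10  # flanking intronic bases adjacent to the unique exon
                if not (u_lo - pad) <= g <= (u_hi + pad):
                    continue
            return gene
        return None

    def transcript_for_label(self, label: str) -> TranscriptModel:
        """Transcript carrying coordinates for a gene or shared-category label."""
        if label in self.transcripts:
            return self.transcripts[label]
        fam = self.family_for_label(label)
        if fam is not None:
            return self.transcripts_by_id()[fam.canonical_transcript]
        raise KeyError(label)

    def transcripts_by_id(self) -> dict[str, TranscriptModel]:
        return {tm.transcript_id: tm for tm in self.transcripts.values()}


def load_registry(
    config_path: str | Path, fasta_path: str | Path
) -> GeneFamilyRegistry:
    """Load and validate a registry from YAML config + sequence FASTA.

    FASTA entries are keyed ``{transcript_id}|cds``, ``{transcript_id}|utr5_window``
    and ``{transcript_id}|utr3``.  Every TYPE invariant is checked at load
    and violations raise :class:`RegistryError` naming the gene and rule.
    """
    with open(config_path) as handle:
        cfg = yaml.safe_load(handle)
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}

    transcripts: dict[str, TranscriptModel] = {}
    for gene, spec in cfg["genes"].items():
        tid = spec["transcript_id"]
        cds = seqs.get(f"{tid}|cds")
        if cds is None:
            raise RegistryError(f"{gene}: no CDS sequence for transcript {tid}")
        try:
            transcripts[gene] = TranscriptModel(
                gene=gene,
                transcript_id=tid,
                chrom=str(spec["chrom"]),
                strand=Strand(spec["strand"]),
                exons=[
                    ExonInterval(
                        index=e["index"],
                        g_start=e["g_start"],
                        g_end=e["g_end"],
                        role=ExonRole(e.get("role", "unique")),
                    )
                    for e in spec["exons"]
                ],
                cds_g_start=spec["cds_g_start"],
                cds_g_end=spec["cds_g_end"],
                cds_seq=cds,
                utr5_seq_window=seqs.get(f"{tid}|utr5_window", ""),
                utr3_seq=seqs.get(f"{tid}|utr3", ""),
            )
        except RegistryError:
            raise
        except Exception as exc:  # surface the gene name in any load failure
            raise RegistryError(f"{gene}: {exc}") from exc

    families = [
        GeneFamily(
            family_id=f["family_id"],
            member_genes=list(f["member_genes"]),
            shared_exons=[
                GenomicInterval(
                    chrom=str(iv["chrom"]), g_start=iv["g_start"], g_end=iv["g_end"]
                )
                for iv in f["shared_exons"]
            ],
            shared_category_label=f["shared_category_label"],
            canonical_transcript=f["canonical_transcript"],
        )
        for f in cfg.get("families", [])
    ]
    decoys = [
        GenomicInterval(
            chrom=str(d["chrom"]),
            g_start=d["g_start"],
            g_end=d["g_end"],
            label=d.get("label", "decoy"),
        )
        for d in cfg.get("decoys", [])
    ]
    variants = [
        VariantTranscriptRule(
            variant_id=v["variant_id"], canonical_gene=v["canonical_gene"]
        )
        for v in cfg.get("variant_transcripts", [])
    ]
    return GeneFamilyRegistry(
        transcripts=transcripts,
        families=families,
        decoy_intervals=decoys,
        variant_transcripts=variants,
    )


_C_POS_RE = re.compile(r"^c\.(\d+)")
_UTR3_RE = re.compile(r"^\*(\d+)")


def parse_c_position(cdna: str) -> tuple[str, int] | None:
    """Extract the leading coordinate of a c. / *N string, or None."""
    cdna = cdna.strip()
    m = _C_POS_RE.match(cdna)
    if m:
        return ("c", int(m.group(1)))
    m = _UTR3_RE.match(cdna)
    if m:
        return ("*", int(m.group(1)))
    return None
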