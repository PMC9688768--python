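"""Rule-based functional annotation of curated UGT mutations.

Four independent annotators:

* Kozak context — the translation-initiation window around the start
  codon.  The window spans positions -9..+4 (+1 is the A of ATG; there is
  no position 0); the optimal motif has A or G at -3 and G at +4.  A U at
  +5 negates the +4 G, so a +5 U→other change is a potential enhancement
  and the reverse a potential weakening.  Positions -10 and +6..+13 are
  adjacent context with no or weak expected effect.
* Splice dinucleotides — any substitution inside the canonical donor GT /
  acceptor AG disrupts the site.
* miRNA target sites — overlap of 3'UTR mutations (*N offsets) with a
  catalog of known sites; within a site, the seed target subinterval is
  distinguished from the 5' remainder of the site.
* Conservation — fully conserved columns (100% residue identity, no gaps)
  of a protein multiple alignment, mapped back to each member's own
  residue numbering, used to find convergent mutation of the same
  conserved residue across family members.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import AlignIO

from .gene_models import (
    RegionKind,
    ReferenceMismatchError,
    TranscriptModel,
    locate_region,
)
from .records import MutationRecord


# ---------------------------------------------------------------------------
# Kozak context
# ---------------------------------------------------------------------------


class KozakRule(str, enum.Enum):
    START_CODON_HIT = "start_codon_hit"
    OPTIMAL_DISRUPTED = "optimal_disrupted"
    PLUS5_U_TO_OTHER = "plus5_U_to_other"  # potential enhancement
    PLUS5_TO_U = "plus5_to_U"  # potential weakening
    OTHER_IN_WINDOW_WEAK = "other_in_window_weak"
    ADJACENT_WEAK_OR_NONE = "adjacent_weak_or_none"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class KozakCall:
    position: int  # -10..-1 or +1..+13 (no 0)
    in_kozak: bool  # within the -9..+4 window
    rule: KozakRule
    ref_base: str
    alt_base: str
    gene_has_optimal_motif: bool


#: index into the 23-base utr5_seq_window for a -10..+13 position
def _window_index(pos: int) -> int:
    return pos + 10 if pos < 0 else pos + 9


def kozak_assess(tm: TranscriptModel, record: MutationRecord) -> KozakCall | None:
    """Assess an SNV near the start codon against the Kozak-context rules.

    Returns None for non-SNVs and positions outside -10..+13.  The ref
    allele is checked against the stored window sequence (transcript
    sense); a mismatch raises :class:`ReferenceMismatchError`.
    """
    if not record.is_snv or not tm.utr5_seq_window:
        return None
    region = locate_region(tm, record.g_start)
    if region.kind is RegionKind.CDS:
        pos = region.c_pos
        assert pos is not None
        if pos > 13:
            return None
    elif region.kind is RegionKind.UTR5:
        assert region.utr5_offset is not None
        pos = -region.utr5_offset
        if pos < -10:
            return None
    else:
        return None

    window = tm.utr5_seq_window
    ref_t = tm.transcript_sense(record.ref_allele)
    alt_t = tm.transcript_sense(record.alt_allele)
    idx = _window_index(pos)
    if idx < len(window) and window[idx] != ref_t:
        raise ReferenceMismatchError(
            f"{tm.gene} Kozak position {pos:+d}: ref {ref_t} != window base {window[idx]}"
        )
    minus3 = window[_window_index(-3)]
    plus4 = window[_window_index(4)]
    optimal = minus3 in "AG" and plus4 == "G"

    if 1 <= pos <= 3:
        rule = KozakRule.START_CODON_HIT
    elif pos == -3 and ref_t in "AG" and alt_t not in "AG":
        rule = KozakRule.OPTIMAL_DISRUPTED
    elif pos == 4 and ref_t == "G" and alt_t != "G":
        rule = KozakRule.OPTIMAL_DISRUPTED
    elif pos == 5 and ref_t == "T":
        rule = KozakRule.PLUS5_U_TO_OTHER
    elif pos == 5 and alt_t == "T":
        rule = KozakRule.PLUS5_TO_U
    elif -9 <= pos <= 5:
        rule = KozakRule.OTHER_IN_WINDOW_WEAK
    else:  # -10 or +6..+13
        rule = KozakRule.ADJACENT_WEAK_OR_NONE

    return KozakCall(
        position=pos,
        in_kozak=-9 <= pos <= 4,
        rule=rule,
        ref_base=ref_t,
        alt_base=alt_t,
        gene_has_optimal_motif=optimal,
    )


# ---------------------------------------------------------------------------
# splice dinucleotides
# ---------------------------------------------------------------------------


class SpliceSiteKind(str, enum.Enum):
    DONOR_GT = "donor_GT"
    ACCEPTOR_AG = "acceptor_AG"


@dataclass(frozen=True)
class SpliceCall:
    site: SpliceSiteKind
    dinucleotide_position: int  # 1|2 reading the dinucleotide 5'->3'
    disrupted: bool
    ref_base: str
    alt_base: str


def splice_assess(record: MutationRecord, tm: TranscriptModel) -> SpliceCall | None:
    """Assess whether an SNV disrupts a canonical splice dinucleotide.

    Donor sites read GT (first two intronic bases past an exon), acceptor
    sites AG (last two before the next exon), in transcript sense.  Any
    base change within the dinucleotide disrupts it.
    """
    if not record.is_snv:
        return None
    region = locate_region(tm, record.g_start)
    if region.kind not in (RegionKind.SPLICE_DONOR, RegionKind.SPLICE_ACCEPTOR):
        return None
    assert region.splice_offset in (1, 2)
    ref_t = tm.transcript_sense(record.ref_allele)
    alt_t = tm.transcript_sense(record.alt_allele)
    if region.kind is RegionKind.SPLICE_DONOR:
        site = SpliceSiteKind.DONOR_GT
        dinuc_pos = region.splice_offset  # offset 1 = G, 2 = T
        canonical = "GT"[dinuc_pos - 1]
    else:
        site = SpliceSiteKind.ACCEPTOR_AG
        dinuc_pos = 3 - region.splice_offset  # offset 1 = G (position 2), 2 = A
        canonical = "AG"[dinuc_pos - 1]
    disrupted = alt_t != canonical
    return SpliceCall(
        site=site,
        dinucleotide_position=dinuc_pos,
        disrupted=disrupted,
        ref_base=ref_t,
        alt_base=alt_t,
    )


# ---------------------------------------------------------------------------
# miRNA target sites
# ---------------------------------------------------------------------------


class MirnaZone(str, enum.Enum):
    SEED = "seed"
    FIVE_PRIME_OF_SITE = "five_prime_of_site"


@dataclass(frozen=True)
class MirnaSite:
    gene: str  # gene symbol or shared-category label owning the 3'UTR
    mirna: str
    site_start: int  # *N offsets, inclusive
    site_end: int
    seed_start: int
    seed_end: int

    def __post_init__(self) -> None:
        if not (self.site_start <= self.seed_start <= self.seed_end <= self.site_end):
            raise ValueError(
                f"{self.mirna}@{self.gene}: seed interval not inside site interval"
            )


@dataclass(frozen=True)
class MirnaSiteHit:
    mirna: str
    site_interval: tuple[int, int]
    seed_subinterval: tuple[int, int]
    zone: MirnaZone
    mutation_offset: int


def load_mirna_catalog(path: str | Path) -> list[MirnaSite]:
    """Load a TSV catalog: gene, mirna, site_start, site_end, seed_start, seed_end."""
    import csv

    sites: list[MirnaSite] = []
    with open(path, encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            sites.append(
                MirnaSite(
                    gene=row["gene"],
                    mirna=row["mirna"],
                    site_start=int(row["site_start"]),
                    site_end=int(row["site_end"]),
                    seed_start=int(row["seed_start"]),
                    seed_end=int(row["seed_end"]),
                )
            )
    return sites


def mirna_site_overlap(
    gene: str, utr3_offset: int, catalog: Sequence[MirnaSite]
) -> list[MirnaSiteHit]:
    """All catalog sites of ``gene`` overlapping a 3'UTR *N offset.

    Offsets within the seed subinterval are zone ``seed``; anything else
    inside the site (necessarily 5' of the seed, which sits at the 3' end
    of the target site) is ``five_prime_of_site``.
    """
    hits: list[MirnaSiteHit] = []
    for site in catalog:
        if site.gene != gene:
            continue
        if not site.site_start <= utr3_offset <= site.site_end:
            continue
        zone = (
            MirnaZone.SEED
            if site.seed_start <= utr3_offset <= site.seed_end
            else MirnaZone.FIVE_PRIME_OF_SITE
        )
        hits.append(
            MirnaSiteHit(
                mirna=site.mirna,
                site_interval=(site.site_start, site.site_end),
                seed_subinterval=(site.seed_start, site.seed_end),
                zone=zone,
                mutation_offset=utr3_offset,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConservedColumn:
    column: int  # 1-based alignment column
    residue: str  # one-letter code
    residue_index: Mapping[str, int]  # per-member residue number


@dataclass
class ConservationMap:
    alignment_id: str
    member_set: tuple[str, ...]
    columns: list[ConservedColumn]

    @property
    def n_conserved(self) -> int:
        return len(self.columns)


def build_conservation_map(
    alignment_path: str | Path,
    member_set: Iterable[str] | None = None,
    alignment_id: str = "",
) -> ConservationMap:
    """Identify fully conserved columns of an aligned protein FASTA.

    A column is conserved iff every member shows the identical residue and
    no gap.  Per-member residue numbers are recovered by counting non-gap
    positions up to the column.  Ragged alignments are an error.
    """
    aln = AlignIO.read(str(alignment_path), "fasta")
    seqs = {rec.id: str(rec.seq).upper() for rec in aln}
    members = tuple(member_set) if member_set is not None else tuple(seqs)
    missing = [m for m in members if m not in seqs]
    if missing:
        raise ValueError(f"members absent from alignment: {missing}")
    lengths = {len(seqs[m]) for m in members}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: member sequences differ in length")
    length = lengths.pop()

    residue_counter = {m: 0 for m in members}
    columns: list[ConservedColumn] = []
    for col in range(length):
        chars = {m: seqs[m][col] for m in members}
        for m, ch in chars.items():
            if ch != "-":
                residue_counter[m] += 1
        values = set(chars.values())
        if len(values) == 1 and "-" not in values:
            columns.append(
                ConservedColumn(
                    column=col + 1,
                    residue=next(iter(values)),
                    residue_index=dict(residue_counter),
                )
            )
    return ConservationMap(
        alignment_id=alignment_id or str(alignment_path),
        member_set=members,
        columns=columns,
    )


import re

_P_RES_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)")


def protein_position(protein_change: str) -> int | None:
    """Residue number of the first affected residue in a p. string."""
    m = _P_RES_RE.match(protein_change.strip())
    return int(m.group(2)) if m else None


@dataclass(frozen=True)
class ConvergenceEntry:
    column: int
    residue: str
    genes: tuple[str, ...]

    @property
    def convergence(self) -> int:
        return len(self.genes)


def flag_conserved_hits(
    records: Sequence[MutationRecord],
    cmap: ConservationMap,
    gene_of: Mapping[str, str] | None = None,
) -> list[ConvergenceEntry]:
    """Convergence table: conserved columns mutated in multiple members.

    For each conserved alignment column, lists the member genes with at
    least one mutation at that column's codon (residue numbering per the
    member's own protein).  ``gene_of`` optionally maps record labels to
    alignment member names.  Rows with no hits are omitted.
    """
    hits_by_gene: dict[str, set[int]] = defaultdict(set)
    for rec in records:
        gene = rec.gene_symbol
        if gene_of is not None:
            gene = gene_of.get(gene, gene)
        pos = protein_position(rec.protein_change)
        if pos is not None:
            hits_by_gene[gene].add(pos)

    table: list[ConvergenceEntry] = []
    for col in cmap.columns:
        genes = tuple(
            sorted(
                g
                for g in cmap.member_set
                if col.residue_index[g] in hits_by_gene.get(g, ())
            )
        )
        if genes:
            table.append(
                ConvergenceEntry(column=col.column, residue=col.residue, genes=genes)
            )
    return table
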