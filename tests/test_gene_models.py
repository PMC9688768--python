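"""Coordinate mapping, region location, consequence calling and HGVS."""

from __future__ import annotations

import numpy as np
import pytest

from _oracles import oracle_indel_class, oracle_snv_class
from conftest import make_cds, make_record
from ugtscape.gene_models import (
    CoordinateError,
    ExonInterval,
    RegionKind,
    RegistryError,
    Strand,
    TranscriptModel,
    consequence_call,
    load_registry,
    locate_region,
    parse_c_position,
    render_hgvs,
)
from ugtscape.records import VariantClass

CDS_CLASSES = {
    VariantClass.SILENT,
    VariantClass.MISSENSE,
    VariantClass.NONSENSE,
    VariantClass.NONSTOP,
    VariantClass.TRANSLATION_START_SITE,
}


# ---------------------------------------------------------------------------
# registry loading
# ---------------------------------------------------------------------------


def test_packaged_registry_topology(registry):
    """22 genes; a 9-member family sharing a 4-exon block and a 2-member
    family sharing a 5-exon block; decoy overlaps no exon."""
    assert len(registry.transcripts) == 22
    assert len(registry.families) == 2
    sizes = sorted(len(f.member_genes) for f in registry.families)
    assert sizes == [2, 9]
    blocks = sorted(len(f.shared_exons) for f in registry.families)
    assert blocks == [4, 5]
    labels = {f.shared_category_label for f in registry.families}
    assert labels == {"1A E2-5", "2A1/2A2 E2-6"}


def test_registry_rejects_cds_without_stop(tmp_path, registry):
    cfg = tmp_path / "bad.yaml"
    fas = tmp_path / "bad.fasta"
    cfg.write_text(
        "genes:\n"
        "  GENEA:\n"
        "    transcript_id: T1\n"
        "    chrom: '1'\n"
        "    strand: '+'\n"
        "    exons: [{index: 1, g_start: 101, g_end: 112}]\n"
        "    cds_g_start: 101\n"
        "    cds_g_end: 112\n"
    )
    fas.write_text(">T1|cds\nATGGCTGCTGCT\n")  # no terminal stop
    with pytest.raises(RegistryError, match="GENEA"):
        load_registry(cfg, fas)


# ---------------------------------------------------------------------------
# region location
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "g, kind, attr, value",
    [
        (101, RegionKind.CDS, "c_pos", 1),
        (301, RegionKind.CDS, "c_pos", 101),
        (201, RegionKind.SPLICE_DONOR, "splice_offset", 1),
        (202, RegionKind.SPLICE_DONOR, "splice_offset", 2),
        (299, RegionKind.SPLICE_ACCEPTOR, "splice_offset", 2),
        (300, RegionKind.SPLICE_ACCEPTOR, "splice_offset", 1),
        (250, RegionKind.INTRON, "exon_or_intron_index", 1),
        (399, RegionKind.UTR3, "utr3_offset", 1),
        (50, RegionKind.OUTSIDE, "c_pos", None),
    ],
)
def test_locate_region_plus_strand(tiny_plus_tm, g, kind, attr, value):
    call = locate_region(tiny_plus_tm, g)
    assert call.kind is kind
    assert getattr(call, attr) == value


def test_locate_region_minus_strand_mirror(tiny_minus_tm):
    """On the minus strand the transcript 5' end is the highest genomic
    coordinate: g=400 is c.1 and splice sites flip sides genomically."""
    assert locate_region(tiny_minus_tm, 400).c_pos == 1
    assert locate_region(tiny_minus_tm, 103).c_pos == 198
    donor = locate_region(tiny_minus_tm, 300)  # first intronic base past exon 1
    assert donor.kind is RegionKind.SPLICE_DONOR and donor.splice_offset == 1
    acceptor = locate_region(tiny_minus_tm, 201)
    assert acceptor.kind is RegionKind.SPLICE_ACCEPTOR and acceptor.splice_offset == 1
    assert locate_region(tiny_minus_tm, 102).utr3_offset == 1


def test_locate_region_per_base_map_matches_independent_enumeration(tiny_minus_tm):
    """Brute-force: walk exons in transcript sense and check every exonic
    base against locate_region."""
    tm = tiny_minus_tm
    tx = 0
    for exon in tm.exons:
        for g in range(exon.g_end, exon.g_start - 1, -1):  # minus strand
            tx += 1
            c = tx - (tm._cds_tx_start - 1)
            call = locate_region(tm, g)
            if 1 <= c <= tm.cds_len:
                assert call.kind is RegionKind.CDS and call.c_pos == c
            elif c < 1:
                assert call.kind is RegionKind.UTR5
            else:
                assert call.kind is RegionKind.UTR3


def test_spanning_variant_takes_most_severe_overlap(tiny_plus_tm):
    # deletion spanning the exon/intron boundary: CDS beats splice
    call = locate_region(tiny_plus_tm, 199, 202)
    assert call.kind is RegionKind.CDS
    # fully intronic span touching the donor dinucleotide
    call = locate_region(tiny_plus_tm, 201, 205)
    assert call.kind is RegionKind.SPLICE_DONOR


def test_off_chromosome_position_is_error(tiny_plus_tm):
    with pytest.raises(CoordinateError):
        locate_region(tiny_plus_tm, -5)


# ---------------------------------------------------------------------------
# genomic <-> cDNA mapping
# ---------------------------------------------------------------------------


def test_cdna_mapping_examples(tiny_plus_tm):
    assert tiny_plus_tm.cdna_to_genomic(101) == 301
    assert tiny_plus_tm.genomic_to_cdna(301) == 101
    with pytest.raises(CoordinateError):
        tiny_plus_tm.cdna_to_genomic(0)
    with pytest.raises(CoordinateError):
        tiny_plus_tm.genomic_to_cdna(250)  # intronic


def test_exhaustive_round_trip_on_all_fixture_transcripts(registry):
    """genomic_to_cdna and cdna_to_genomic are mutually inverse bijections
    over every CDS base of every fixture transcript, both strands."""
    for tm in registry.transcripts.values():
        seen = set()
        for c in range(1, tm.cds_len + 1):
            g = tm.cdna_to_genomic(c)
            assert tm.genomic_to_cdna(g) == c
            seen.add(g)
        assert len(seen) == tm.cds_len


# ---------------------------------------------------------------------------
# consequence calling
# ---------------------------------------------------------------------------


def _tm_with_cds(cds: str) -> TranscriptModel:
    return TranscriptModel(
        gene="MINI",
        transcript_id="MINI.1",
        chrom="1",
        strand=Strand.PLUS,
        exons=[ExonInterval(1, 101, 100 + len(cds))],
        cds_g_start=101,
        cds_g_end=100 + len(cds),
        cds_seq=cds,
        utr3_seq="GTAACGGATT",
    )


def test_snv_consequences_on_hand_translated_codons():
    """CDS ATG TGG AAA TAA: c.4 T>C is Trp2Arg, c.6 G>A is Trp2Ter."""
    tm = _tm_with_cds("ATGTGGAAATAA")
    cons = consequence_call(tm, make_record("1", 104, "T", "C"))
    assert cons.variant_class is VariantClass.MISSENSE
    assert (cons.cdna, cons.protein) == ("c.4T>C", "p.Trp2Arg")
    cons = consequence_call(tm, make_record("1", 106, "G", "A"))
    assert cons.variant_class is VariantClass.NONSENSE
    assert cons.protein == "p.Trp2Ter"


def test_single_base_deletion_is_frameshift_with_fs_naming():
    """Deleting c.4 of ATG TGG AAA TAA shifts the frame: the new protein
    reads Met-Gly-Asn-Lys-stop, i.e. p.Trp2GlyfsTer4."""
    tm = _tm_with_cds("ATGTGGAAATAA")
    cons = consequence_call(tm, make_record("1", 104, "T", "-", g_end=104))
    assert cons.variant_class is VariantClass.FRAME_SHIFT_DEL
    assert cons.cdna == "c.4delT"
    assert cons.protein == "p.Trp2GlyfsTer4"


def test_in_frame_deletion():
    tm = _tm_with_cds("ATGTGGAAATAA")
    cons = consequence_call(tm, make_record("1", 104, "TGG", "-", g_end=106))
    assert cons.variant_class is VariantClass.IN_FRAME_DEL


def test_start_and_stop_codon_hits():
    tm = _tm_with_cds("ATGTGGAAATAA")
    cons = consequence_call(tm, make_record("1", 101, "A", "G"))
    assert cons.variant_class is VariantClass.TRANSLATION_START_SITE
    cons = consequence_call(tm, make_record("1", 110, "T", "C"))  # TAA -> CAA
    assert cons.variant_class is VariantClass.NONSTOP


def test_reference_mismatch_raises():
    from ugtscape.gene_models import ReferenceMismatchError

    tm = _tm_with_cds("ATGTGGAAATAA")
    with pytest.raises(ReferenceMismatchError):
        consequence_call(tm, make_record("1", 104, "G", "C"))


def test_every_cds_snv_maps_to_exactly_one_coding_class(tiny_plus_tm):
    tm = tiny_plus_tm
    for c in (1, 2, 3, 4, 50, 100, 150, 196, 197, 198):
        g = tm.cdna_to_genomic(c)
        ref = tm.cds_seq[c - 1]
        for alt in "ACGT":
            if alt == ref:
                continue
            cons = consequence_call(tm, make_record("1", g, ref, alt))
            assert cons.variant_class in CDS_CLASSES


def test_consequence_agrees_with_splice_edit_translate_oracle(registry):
    """Random SNVs and indels over fixture transcripts: the per-codon
    implementation must match the whole-sequence translate-and-diff
    oracle."""
    rng = np.random.default_rng(42)
    tms = list(registry.transcripts.values())
    n_checked = 0
    while n_checked < 1200:
        tm = tms[int(rng.integers(0, len(tms)))]
        kind = rng.random()
        if kind < 0.7:  # SNV
            c = int(rng.integers(1, tm.cds_len + 1))
            ref_t = tm.cds_seq[c - 1]
            alt_t = "ACGT"[int(rng.integers(0, 4))]
            if alt_t == ref_t:
                continue
            g = tm.cdna_to_genomic(c)
            rec = make_record(
                tm.chrom, g, tm.transcript_sense(ref_t), tm.transcript_sense(alt_t)
            )
            cons = consequence_call(tm, rec)
            assert cons.variant_class is oracle_snv_class(tm, c, alt_t), (
                tm.gene, c, ref_t, alt_t)
        else:  # deletion of 1-3 bases inside one exon
            length = int(rng.integers(1, 4))
            c = int(rng.integers(4, tm.cds_len - 3 - length))
            gs = sorted(tm.cdna_to_genomic(cc) for cc in range(c, c + length))
            if gs[-1] - gs[0] != length - 1:
                continue  # crosses an exon boundary
            deleted = tm.cds_seq[c - 1 : c - 1 + length]
            rec = make_record(
                tm.chrom, gs[0], tm.transcript_sense(deleted), "-", g_end=gs[-1]
            )
            cons = consequence_call(tm, rec)
            assert cons.variant_class is oracle_indel_class(length, True)
        n_checked += 1


# ---------------------------------------------------------------------------
# HGVS rendering
# ---------------------------------------------------------------------------


def test_hgvs_rendering_styles(registry):
    """c.463C>T / *70A>T / c.1566delA style strings."""
    tm = registry.transcripts["UGT2B4"]
    c = 77
    g = tm.cdna_to_genomic(c)
    ref = tm.cds_seq[c - 1]
    alt = "A" if ref != "A" else "G"
    cdna, prot = render_hgvs(tm, make_record(tm.chrom, g, ref, alt))
    assert cdna == f"c.{c}{ref}>{alt}"
    assert prot.startswith("p.")
    # 3'UTR offset rendering
    g3 = tm.utr3_to_genomic(70)
    ref3 = tm.utr3_seq[69]
    alt3 = "T" if ref3 != "T" else "A"
    cdna, prot = render_hgvs(tm, make_record(tm.chrom, g3, ref3, alt3))
    assert cdna == f"*70{ref3}>{alt3}" and prot == ""
    # single-base deletion rendering
    c = 90
    gdel = tm.cdna_to_genomic(c)
    cdna, prot = render_hgvs(
        tm, make_record(tm.chrom, gdel, tm.cds_seq[c - 1], "-", g_end=gdel)
    )
    assert cdna == f"c.{c}del{tm.cds_seq[c - 1]}"
    assert "fsTer" in prot


def test_parse_c_position():
    assert parse_c_position("c.463C>T") == ("c", 463)
    assert parse_c_position("*70A>T") == ("*", 70)
    assert parse_c_position("p.Arg100Ter") is None
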