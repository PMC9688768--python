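"""Kozak context, splice dinucleotides, miRNA sites, conservation."""

from __future__ import annotations

import numpy as np
import pytest

from _oracles import oracle_conserved_columns
from conftest import make_record
from ugtscape.annotation import (
    ConservationMap,
    ConservedColumn,
    KozakRule,
    MirnaZone,
    SpliceSiteKind,
    build_conservation_map,
    flag_conserved_hits,
    kozak_assess,
    mirna_site_overlap,
    splice_assess,
)
from ugtscape.records import VariantClass


# ---------------------------------------------------------------------------
# Kozak
# ---------------------------------------------------------------------------


def _kozak_snv(tm, pos: int, alt_t: str):
    """Build an SNV at a -10..+13 position using the stored window."""
    idx = pos + 10 if pos < 0 else pos + 9
    ref_t = tm.utr5_seq_window[idx]
    if pos > 0:
        g = tm.cdna_to_genomic(pos)
    else:
        g = tm.utr5_to_genomic(-pos)
    return make_record(
        tm.chrom, g, tm.transcript_sense(ref_t), tm.transcript_sense(alt_t),
        gene=tm.gene,
    )


def test_plus4_G_loss_disrupts_optimal_motif(registry):
    """The UGT2B28 context has a G at +4; +4 G>T disrupts the motif."""
    tm = registry.transcripts["UGT2B28"]
    assert tm.utr5_seq_window[13] == "G"
    call = kozak_assess(tm, _kozak_snv(tm, 4, "T"))
    assert call is not None
    assert call.rule is KozakRule.OPTIMAL_DISRUPTED
    assert call.in_kozak and call.gene_has_optimal_motif


def test_plus5_U_to_C_is_potential_enhancement(registry):
    """UGT3A1 carries G at +4 with T(U) at +5; +5 T>C negates the weak
    element and may enhance initiation."""
    tm = registry.transcripts["UGT3A1"]
    assert tm.utr5_seq_window[13] == "G" and tm.utr5_seq_window[14] == "T"
    call = kozak_assess(tm, _kozak_snv(tm, 5, "C"))
    assert call.rule is KozakRule.PLUS5_U_TO_OTHER
    assert not call.in_kozak  # +5 is outside the -9..+4 window


def test_plus5_gain_of_U_is_potential_weakening(registry):
    tm = registry.transcripts["UGT2B28"]  # +5 is C in this context
    call = kozak_assess(tm, _kozak_snv(tm, 5, "T"))
    assert call.rule is KozakRule.PLUS5_TO_U


def test_adjacent_positions_are_weak_or_none(registry):
    tm = registry.transcripts["UGT2B4"]
    for pos in (-10, 9, 13):
        call = kozak_assess(tm, _kozak_snv(tm, pos, _other(tm, pos)))
        assert call.rule is KozakRule.ADJACENT_WEAK_OR_NONE


def test_start_codon_hit_and_minus3(registry):
    tm = registry.transcripts["UGT1A1"]  # optimal motif, minus strand gene
    call = kozak_assess(tm, _kozak_snv(tm, 2, "C"))
    assert call.rule is KozakRule.START_CODON_HIT
    call = kozak_assess(tm, _kozak_snv(tm, -3, "C"))  # A/G at -3 lost
    assert call.rule is KozakRule.OPTIMAL_DISRUPTED


def test_every_window_position_gets_exactly_one_rule(registry):
    """Totality: every in-window SNV receives a rule; beyond +13 none."""
    tm = registry.transcripts["UGT2B10"]
    for pos in list(range(-10, 0)) + list(range(1, 14)):
        call = kozak_assess(tm, _kozak_snv(tm, pos, _other(tm, pos)))
        assert call is not None and isinstance(call.rule, KozakRule)
    c14 = tm.cdna_to_genomic(14)
    rec = make_record(tm.chrom, c14, tm.transcript_sense(tm.cds_seq[13]),
                      tm.transcript_sense(_flip(tm.cds_seq[13])), gene=tm.gene)
    assert kozak_assess(tm, rec) is None


def _other(tm, pos):
    idx = pos + 10 if pos < 0 else pos + 9
    return _flip(tm.utr5_seq_window[idx])


def _flip(base):
    return {"A": "G", "G": "A", "C": "T", "T": "C"}[base]


# ---------------------------------------------------------------------------
# splice
# ---------------------------------------------------------------------------


def test_donor_G_to_A_disrupts(tiny_plus_tm):
    call = splice_assess(make_record("1", 201, "G", "A"), tiny_plus_tm)
    assert call.site is SpliceSiteKind.DONOR_GT
    assert call.dinucleotide_position == 1
    assert call.disrupted


def test_acceptor_G_to_C_disrupts(tiny_plus_tm):
    call = splice_assess(make_record("1", 300, "G", "C"), tiny_plus_tm)
    assert call.site is SpliceSiteKind.ACCEPTOR_AG
    assert call.dinucleotide_position == 2
    assert call.disrupted


def test_deep_intronic_snv_is_not_a_splice_call(tiny_plus_tm):
    assert splice_assess(make_record("1", 206, "A", "G"), tiny_plus_tm) is None


def test_splice_call_implies_splice_region(registry):
    """Any disrupted call must come from a dinucleotide position."""
    from ugtscape.gene_models import RegionKind, locate_region

    tm = registry.transcripts["UGT2B7"]
    for k in (1, 2):
        for side, offsets in (("donor", (1, 2)), ("acceptor", (1, 2))):
            for off in offsets:
                g = tm.splice_site_genomic(k, side, off)
                canonical = {"donor": "GT", "acceptor": "AG"}[side]
                ref_t = canonical[off - 1] if side == "donor" else canonical[2 - off]
                rec = make_record(tm.chrom, g, ref_t, _flip(ref_t))
                call = splice_assess(rec, tm)
                assert call is not None and call.disrupted
                kind = locate_region(tm, g).kind
                assert kind in (RegionKind.SPLICE_DONOR, RegionKind.SPLICE_ACCEPTOR)


# ---------------------------------------------------------------------------
# miRNA sites
# ---------------------------------------------------------------------------


def test_shared_utr_offset_70_hits_two_mirna_seeds(mirna_catalog):
    hits = mirna_site_overlap("1A E2-5", 70, mirna_catalog)
    assert {h.mirna for h in hits} == {"miR-200a-3p", "miR-141-3p"}
    assert all(h.zone is MirnaZone.SEED for h in hits)


def test_ugt2b4_offset_83_hits_mir216b_seed(mirna_catalog):
    hits = mirna_site_overlap("UGT2B4", 83, mirna_catalog)
    assert [h.mirna for h in hits] == ["miR-216b-5p"]
    assert hits[0].zone is MirnaZone.SEED


def test_offset_in_site_but_not_seed_is_five_prime(mirna_catalog):
    hits = mirna_site_overlap("UGT2B7", 25, mirna_catalog)
    assert hits and hits[0].zone is MirnaZone.FIVE_PRIME_OF_SITE


def test_offset_outside_all_sites_has_no_hits(mirna_catalog):
    assert mirna_site_overlap("UGT2B4", 5, mirna_catalog) == []


def test_hit_offsets_always_inside_site_interval(mirna_catalog):
    for gene in ("1A E2-5", "UGT2B4", "UGT2B7", "UGT2B15"):
        for off in range(1, 101):
            for hit in mirna_site_overlap(gene, off, mirna_catalog):
                lo, hi = hit.site_interval
                assert lo <= hit.mutation_offset <= hi


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------


def _write_alignment(tmp_path, seqs: dict[str, str]):
    path = tmp_path / "aln.fasta"
    path.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
    return path


def test_identical_columns_counted(tmp_path):
    path = _write_alignment(
        tmp_path, {"g1": "MKL-A", "g2": "MKI-A", "g3": "MKV-A"}
    )
    cmap = build_conservation_map(path)
    assert cmap.n_conserved == 3  # columns 1, 2 and 5; gap column excluded
    assert [c.column for c in cmap.columns] == [1, 2, 5]


def test_gap_column_is_never_conserved(tmp_path):
    path = _write_alignment(tmp_path, {"g1": "M-", "g2": "M-"})
    cmap = build_conservation_map(path)
    assert [c.column for c in cmap.columns] == [1]


def test_ragged_alignment_is_error(tmp_path):
    path = _write_alignment(tmp_path, {"g1": "MKL", "g2": "MK"})
    with pytest.raises(ValueError, match="ragged|same length"):
        build_conservation_map(path)


def test_conserved_count_matches_column_scan_oracle(tmp_path):
    rng = np.random.default_rng(5)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
    for trial in range(10):
        n, L = int(rng.integers(2, 6)), int(rng.integers(5, 40))
        seqs = {
            f"g{i}": "".join(rng.choice(alphabet, size=L)) for i in range(n)
        }
        # force a few identical columns
        for col in rng.integers(0, L, size=3):
            ch = alphabet[int(rng.integers(0, 20))]
            seqs = {k: v[:col] + ch + v[col + 1 :] for k, v in seqs.items()}
        path = _write_alignment(tmp_path, seqs)
        cmap = build_conservation_map(path)
        assert [c.column for c in cmap.columns] == oracle_conserved_columns(seqs)


def test_shuffling_member_order_does_not_change_the_map(tmp_path):
    seqs = {"a": "MKLPW", "b": "MKIPW", "c": "MKLPW"}
    p1 = _write_alignment(tmp_path, seqs)
    cols1 = [c.column for c in build_conservation_map(p1, ["a", "b", "c"]).columns]
    cols2 = [c.column for c in build_conservation_map(p1, ["c", "a", "b"]).columns]
    assert cols1 == cols2


def test_adding_divergent_member_only_shrinks_conserved_set(tmp_path):
    seqs = {"a": "MKLPW", "b": "MKLPW", "c": "AAAAA"}
    path = _write_alignment(tmp_path, seqs)
    small = {c.column for c in build_conservation_map(path, ["a", "b"]).columns}
    big = {c.column for c in build_conservation_map(path, ["a", "b", "c"]).columns}
    assert big <= small


def test_residue_numbering_skips_gaps(tmp_path):
    path = _write_alignment(tmp_path, {"a": "M-KW", "b": "MLKW"})
    cmap = build_conservation_map(path)
    col3 = next(c for c in cmap.columns if c.column == 3)
    assert col3.residue_index == {"a": 2, "b": 3}


# ---------------------------------------------------------------------------
# convergence on conserved residues
# ---------------------------------------------------------------------------


def test_convergence_counts_distinct_mutated_members():
    cmap = ConservationMap(
        alignment_id="toy",
        member_set=("g1", "g2", "g3", "g4", "g5"),
        columns=[
            ConservedColumn(7, "R", {f"g{i}": 7 for i in range(1, 6)}),
            ConservedColumn(9, "P", {f"g{i}": 9 for i in range(1, 6)}),
        ],
    )
    recs = [
        make_record("1", 100 + i, "A", "G", gene=f"g{i}",
                    protein_change="p.Arg7Cys")
        for i in (1, 2, 3)
    ]
    table = flag_conserved_hits(recs, cmap)
    assert len(table) == 1
    assert table[0].column == 7 and table[0].convergence == 3


def test_mutations_only_at_nonconserved_columns_yield_empty_table():
    cmap = ConservationMap("toy", ("g1", "g2"), [
        ConservedColumn(5, "W", {"g1": 5, "g2": 5})
    ])
    recs = [make_record("1", 1, "A", "G", gene="g1", protein_change="p.Lys9Arg")]
    assert flag_conserved_hits(recs, cmap) == []


def test_engineered_full_family_convergence(registry, alignment_path):
    """A conserved column mutated in many members is reported with the
    full convergence count (packaged 9-member family alignment)."""
    cmap = build_conservation_map(alignment_path)
    assert cmap.n_conserved > 0
    col = cmap.columns[len(cmap.columns) // 2]
    recs = []
    for gene in cmap.member_set:
        res = col.residue_index[gene]
        recs.append(
            make_record("2", 2000, "A", "G", gene=gene,
                        protein_change=f"p.Ala{res}Gly")
        )
    table = flag_conserved_hits(recs, cmap)
    entry = next(e for e in table if e.column == col.column)
    assert entry.convergence == 9
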