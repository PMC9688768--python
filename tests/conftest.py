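from __future__ import annotations

import pytest

from ugtscape.gene_models import ExonInterval, ExonRole, Strand, TranscriptModel
from ugtscape.records import (
    MutationRecord,
    SiftCall,
    VariantClass,
    VariantType,
)
from ugtscape.resources import (
    toy_mirna_catalog,
    toy_protein_alignment_path,
    toy_registry,
)

SAFE_CODONS = ["GCT", "TGG", "AAA", "CCG", "GAT", "TTC", "CAT", "GTA"]


def make_cds(n_codons: int) -> str:
    """ATG + cycling non-stop codons + TAA, total n_codons codons."""
    body = [SAFE_CODONS[i % len(SAFE_CODONS)] for i in range(n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def make_record(
    chrom: str,
    g_start: int,
    ref: str,
    alt: str,
    gene: str = "TOYGENE",
    g_end: int | None = None,
    variant_class: VariantClass = VariantClass.QUARANTINE,
    **kw,
) -> MutationRecord:
    if ref == "-":
        vt = VariantType.INS
    elif alt == "-":
        vt = VariantType.DEL
    elif len(ref) == 1 and len(alt) == 1:
        vt = VariantType.SNP
    else:
        vt = VariantType.DNP
    return MutationRecord(
        gene_symbol=gene,
        chrom=chrom,
        g_start=g_start,
        g_end=g_end if g_end is not None else g_start + max(len(ref), 1) - 1
        if alt == "-"
        else g_start,
        ref_allele=ref,
        alt_allele=alt,
        variant_class=variant_class,
        variant_type=vt,
        sample_barcode=kw.pop("sample_barcode", "TCGA-00-0001-01A-11D-A000-09"),
        **kw,
    )


@pytest.fixture(scope="session")
def registry():
    return toy_registry()


@pytest.fixture(scope="session")
def mirna_catalog():
    return toy_mirna_catalog()


@pytest.fixture(scope="session")
def alignment_path():
    return toy_protein_alignment_path()


@pytest.fixture
def tiny_plus_tm():
    """Two-exon plus-strand transcript: exons 101-200 and 301-400, CDS
    101..398 (198 nt, 66 codons), 2 nt of 3'UTR."""
    return TranscriptModel(
        gene="TOYPLUS",
        transcript_id="TOYPLUS.1",
        chrom="1",
        strand=Strand.PLUS,
        exons=[
            ExonInterval(1, 101, 200, ExonRole.UNIQUE),
            ExonInterval(2, 301, 400, ExonRole.UNIQUE),
        ],
        cds_g_start=101,
        cds_g_end=398,
        cds_seq=make_cds(66),
        utr3_seq="GT",
    )


@pytest.fixture
def tiny_minus_tm():
    """Mirror of tiny_plus_tm on the minus strand: transcript exon 1 is
    301-400 (5' end at g=400), CDS 103..400."""
    return TranscriptModel(
        gene="TOYMINUS",
        transcript_id="TOYMINUS.1",
        chrom="1",
        strand=Strand.MINUS,
        exons=[
            ExonInterval(1, 301, 400, ExonRole.UNIQUE),
            ExonInterval(2, 101, 200, ExonRole.UNIQUE),
        ],
        cds_g_start=103,
        cds_g_end=400,
        cds_seq=make_cds(66),
        utr3_seq="GT",
    )
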