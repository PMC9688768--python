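"""Build the packaged toy UGT locus registry (YAML + FASTA + alignment).

The toy registry reproduces the real topology of the 22-gene UGT
superfamily at reduced exon sizes: nine UGT1A genes with unique first
exons and a shared 4-exon block (exons 2-5, minus strand), UGT2A1/UGT2A2
with unique first exons and a shared 5-exon block (exons 2-6, plus
strand), eleven standalone genes, a DNAJB3-like decoy interval between
two UGT1A first exons, and a known variant UGT2A1 transcript id.

Deterministic: re-running reproduces byte-identical fixtures.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parents[1] / "src" / "ugtscape" / "data"

STOPS = {"TAA", "TAG", "TGA"}
CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
)

UGT1A = ["UGT1A1", "UGT1A3", "UGT1A4", "UGT1A5", "UGT1A6",
         "UGT1A7", "UGT1A8", "UGT1A9", "UGT1A10"]
UGT2A_SHARED = ["UGT2A1", "UGT2A2"]
STANDALONE = ["UGT2A3", "UGT2B4", "UGT2B7", "UGT2B10", "UGT2B11",
              "UGT2B15", "UGT2B17", "UGT2B28", "UGT3A1", "UGT3A2", "UGT8"]

# Kozak context per gene: (-3 base, +4 base, +5 base).  Nine genes carry the
# optimal motif (A/G at -3, G at +4); UGT3A1 and UGT2A1 have G at +4 with a
# T at +5 (weak element); the rest are non-optimal.
KOZAK = {
    "UGT1A1": ("A", "G", "C"), "UGT1A3": ("G", "G", "C"),
    "UGT1A4": ("A", "G", "C"), "UGT1A5": ("A", "G", "C"),
    "UGT1A6": ("G", "G", "C"), "UGT2B10": ("A", "G", "C"),
    "UGT2B28": ("A", "G", "C"), "UGT3A1": ("A", "G", "T"),
    "UGT3A2": ("G", "G", "C"),
    "UGT2A1": ("C", "G", "T"),
    "UGT1A7": ("T", "A", "C"), "UGT1A8": ("C", "C", "C"),
    "UGT1A9": ("T", "A", "C"), "UGT1A10": ("C", "T", "C"),
    "UGT2A2": ("T", "C", "C"), "UGT2A3": ("C", "A", "C"),
    "UGT2B4": ("T", "C", "C"), "UGT2B7": ("C", "A", "C"),
    "UGT2B11": ("T", "T", "C"), "UGT2B15": ("C", "A", "C"),
    "UGT2B17": ("T", "C", "C"), "UGT8": ("C", "A", "C"),
}


def rand_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(CODONS[i] for i in rng.integers(0, len(CODONS), size=n))


def exon1_cds(rng: np.random.Generator, ancestral: str, mut_rate: float, kozak) -> str:
    """Member exon-1 CDS: ancestral 42 codons with per-member codon mutations."""
    codons = [ancestral[i : i + 3] for i in range(0, len(ancestral), 3)]
    for i in range(1, len(codons)):
        if rng.random() < mut_rate:
            codons[i] = CODONS[rng.integers(0, len(CODONS))]
    # codon 2 carries the +4/+5 Kozak positions
    _, p4, p5 = kozak
    third = codons[1][2]
    cand = p4 + p5 + third
    codons[1] = cand if cand not in STOPS else p4 + p5 + "C"
    return "".join(codons)


def utr5(rng: np.random.Generator, kozak) -> str:
    """24 nt of 5'UTR; built from sense-frame non-stop codons so the variant
    transcript that absorbs a whole exon 1 stays open."""
    seq = list(rand_codons(rng, 8))
    seq[21] = kozak[0]  # -3 position
    s = "".join(seq)
    # keep codon 8 non-stop after the -3 edit
    if s[21:24] in STOPS:
        s = s[:23] + "C"
    return s


def main() -> None:
    rng = np.random.default_rng(20221121)
    OUT.mkdir(parents=True, exist_ok=True)

    genes: dict[str, dict] = {}
    fasta: list[tuple[str, str]] = []
    proteins_1a: list[tuple[str, str]] = []

    # ---------------- UGT1A family (chrom 2, minus strand) ----------------
    shared1a_cds = rand_codons(rng, 105) + "TAA"  # 318 nt over exons 2-5
    shared1a_utr3 = rand_codons(rng, 34)[:100]
    anc1a = "ATG" + rand_codons(rng, 41)  # ancestral exon-1 CDS, 126 nt
    shared1a_exons = [  # transcript order E2..E5, minus strand
        (1700, 1790), (1500, 1590), (1300, 1390), (1000, 1144)
    ]
    exon1_starts = {
        "UGT1A1": 2000, "UGT1A3": 2500, "UGT1A4": 2800, "UGT1A5": 3100,
        "UGT1A6": 3400, "UGT1A7": 3700, "UGT1A8": 4000, "UGT1A9": 4300,
        "UGT1A10": 4600,
    }
    from Bio.Seq import Seq

    for gene in UGT1A:
        s = exon1_starts[gene]
        e1 = (s, s + 149)
        cds1 = exon1_cds(rng, anc1a, 0.6, KOZAK[gene])
        cds = cds1 + shared1a_cds
        u5 = utr5(rng, KOZAK[gene])
        tid = f"TOY_{gene}"
        genes[gene] = {
            "transcript_id": tid,
            "chrom": "2",
            "strand": "-",
            "exons": [
                {"index": 1, "g_start": e1[0], "g_end": e1[1], "role": "unique"},
            ]
            + [
                {"index": i + 2, "g_start": a, "g_end": b, "role": "shared"}
                for i, (a, b) in enumerate(shared1a_exons)
            ],
            "cds_g_start": 1100,
            "cds_g_end": e1[1] - 24,
        }
        fasta += [
            (f"{tid}|cds", cds),
            (f"{tid}|utr5_window", u5[-10:] + cds[:13]),
            (f"{tid}|utr3", shared1a_utr3),
        ]
        proteins_1a.append((gene, str(Seq(cds).translate())[:-1]))

    # ---------------- UGT2A1/2A2 family (chrom 4, plus strand) ------------
    shared2a_cds = rand_codons(rng, 135) + rand_codons(rng, 1)  # 408 nt
    # exons 2-6 carry 364 + 44 = 408 CDS nt; terminal codon must be a stop
    shared2a_cds = shared2a_cds[:405] + "TGA"
    shared2a_utr3 = rand_codons(rng, 34)[:100]
    shared2a_exons = [(1800, 1890), (2000, 2090), (2200, 2290),
                      (2400, 2490), (2600, 2743)]
    anc2a = "ATG" + rand_codons(rng, 41)
    for gene, e1s in (("UGT2A1", 1000), ("UGT2A2", 1400)):
        e1 = (e1s, e1s + 149)
        cds1 = exon1_cds(rng, anc2a, 0.6, KOZAK[gene])
        cds = cds1 + shared2a_cds
        u5 = utr5(rng, KOZAK[gene])
        tid = f"TOY_{gene}"
        genes[gene] = {
            "transcript_id": tid,
            "chrom": "4",
            "strand": "+",
            "exons": [
                {"index": 1, "g_start": e1[0], "g_end": e1[1], "role": "unique"},
            ]
            + [
                {"index": i + 2, "g_start": a, "g_end": b, "role": "shared"}
                for i, (a, b) in enumerate(shared2a_exons)
            ],
            "cds_g_start": e1[0] + 24,
            "cds_g_end": 2643,
        }
        fasta += [
            (f"{tid}|cds", cds),
            (f"{tid}|utr5_window", u5[-10:] + cds[:13]),
            (f"{tid}|utr3", shared2a_utr3),
        ]

    # ---------------- standalone genes ------------------------------------
    standalone_coords = {
        "UGT2A3": ("4", 10000), "UGT2B4": ("4", 20000), "UGT2B7": ("4", 30000),
        "UGT2B10": ("4", 40000), "UGT2B11": ("4", 50000), "UGT2B15": ("4", 60000),
        "UGT2B17": ("4", 70000), "UGT2B28": ("4", 80000), "UGT8": ("4", 90000),
        "UGT3A1": ("5", 10000), "UGT3A2": ("5", 20000),
    }
    for gene in STANDALONE:
        chrom, s = standalone_coords[gene]
        cds1 = exon1_cds(rng, "ATG" + rand_codons(rng, 41), 0.0, KOZAK[gene])
        cds = cds1 + rand_codons(rng, 44)  # 126 + 132 = 258; add stop codon
        cds = cds[:258] + "TAA"
        u5 = utr5(rng, KOZAK[gene])
        u3 = rand_codons(rng, 34)[:100]
        tid = f"TOY_{gene}"
        genes[gene] = {
            "transcript_id": tid,
            "chrom": chrom,
            "strand": "+",
            "exons": [
                {"index": 1, "g_start": s, "g_end": s + 149, "role": "unique"},
                {"index": 2, "g_start": s + 300, "g_end": s + 390, "role": "unique"},
                {"index": 3, "g_start": s + 600, "g_end": s + 743, "role": "unique"},
            ],
            "cds_g_start": s + 24,
            "cds_g_end": s + 643,
        }
        fasta += [
            (f"{tid}|cds", cds),
            (f"{tid}|utr5_window", u5[-10:] + cds[:13]),
            (f"{tid}|utr3", u3),
        ]

    registry = {
        "genes": genes,
        "families": [
            {
                "family_id": "UGT1A",
                "member_genes": UGT1A,
                "shared_exons": [
                    {"chrom": "2", "g_start": a, "g_end": b}
                    for a, b in shared1a_exons
                ],
                "shared_category_label": "1A E2-5",
                "canonical_transcript": "TOY_UGT1A10",
            },
            {
                "family_id": "UGT2A1/2A2",
                "member_genes": UGT2A_SHARED,
                "shared_exons": [
                    {"chrom": "4", "g_start": a, "g_end": b}
                    for a, b in shared2a_exons
                ],
                "shared_category_label": "2A1/2A2 E2-6",
                "canonical_transcript": "TOY_UGT2A1",
            },
        ],
        "decoys": [
            {"label": "DNAJB3", "chrom": "2", "g_start": 2200, "g_end": 2350},
        ],
        "variant_transcripts": [
            {"variant_id": "TOY_UGT2A1_VAR", "canonical_gene": "UGT2A1"},
        ],
    }

    import yaml

    (OUT / "toy_registry.yaml").write_text(
        yaml.safe_dump(registry, sort_keys=True), encoding="utf-8"
    )
    with open(OUT / "toy_registry.fasta", "w", encoding="utf-8") as fh:
        for name, seq in fasta:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(OUT / "ugt1a_toy_protein_alignment.fasta", "w", encoding="utf-8") as fh:
        for gene, prot in proteins_1a:
            fh.write(f">{gene}\n")
            for i in range(0, len(prot), 60):
                fh.write(prot[i : i + 60] + "\n")
    print(f"wrote registry fixtures to {OUT}")


if __name__ == "__main__":
    sys.exit(main())
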