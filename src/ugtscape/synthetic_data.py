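"""Synthetic MAF/CCLE-style cohorts with a complete ground-truth ledger.

The generator emulates the phenomena the pipeline must handle, on the toy
UGT registry: per-cohort mutation burdens spanning roughly 15–1200
mutations per tumor (log-normal within cohort) with rare hypermutators at
a large burden multiplier; TCGA barcodes carrying sample-type codes
(primary / recurrent / metastatic); UGT-locus mutations of all 13 variant
classes placed so that class semantics hold (splice records sit in
canonical dinucleotides, 3'UTR records carry *N offsets, indel lengths
mod 3 match the frameshift/in-frame truth); and the documented MAF
mis-annotation quirks of the exon-sharing loci (unique-exon mutations
listed as a sibling's intron, shared-block mutations credited to a single
member, annotation on a non-canonical variant transcript, and decoy-gene
records inside the family locus).

Every emitted record and sample is covered exactly once by the
:class:`TruthLedger`, and a single integer seed drives one generator for
all randomness, so a fixed seed reproduces byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .gene_models import (
    ExonRole,
    GeneFamilyRegistry,
    Strand,
    TranscriptModel,
    consequence_call,
)
from .records import (
    MutationRecord,
    SampleType,
    SiftCall,
    Source,
    VariantClass,
    VariantType,
)

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """One synthetic cancer cohort."""

    cancer: str
    n_tumors: int
    burden_median: float  # median somatic mutations per tumor (all genes)
    burden_sigma: float = 0.5  # log-normal dispersion (natural-log scale)
    hypermutator_fraction: float = 0.005
    hypermutator_multiplier: float = 20.0
    metastatic_fraction: float = 0.0
    recurrent_fraction: float = 0.0


@dataclass
class MisannotationRates:
    """Per-rule corruption rates (probabilities except ``decoy_per_tumor``)."""

    exon1_as_intron: float = 1.0  # unique-exon records of `exon1_victim_gene`
    shared_exon_relabel: float = 1.0  # shared-block records -> one member label
    variant_transcript: float = 1.0  # 2-member family shared block -> variant tx
    decoy_per_tumor: float = 0.01  # expected decoy-interval records per tumor
    exon1_victim_gene: str = "UGT1A1"
    exon1_sibling_label: str = "UGT1A8"


@dataclass
class HotspotSpec:
    gene: str
    c_lo: int
    c_hi: int
    n_events: int


def _default_cohorts() -> list[CohortSpec]:
    return [
        CohortSpec("PCPG", 250, 15.0),
        CohortSpec("GBM", 250, 106.0, recurrent_fraction=0.02),
        CohortSpec("LUAD", 250, 475.0, recurrent_fraction=0.02),
        CohortSpec("SKCM", 250, 1204.0, metastatic_fraction=0.75),
    ]


def _default_class_mix() -> dict[VariantClass, float]:
    # proportions follow the observed pan-cancer UGT class census, with a
    # small floor so every one of the 13 classes can occur
    weights = {
        VariantClass.UTR5: 99,
        VariantClass.MISSENSE: 1998,
        VariantClass.TRANSLATION_START_SITE: 2,
        VariantClass.NONSENSE: 184,
        VariantClass.SILENT: 754,
        VariantClass.FRAME_SHIFT_DEL: 93,
        VariantClass.FRAME_SHIFT_INS: 29,
        VariantClass.IN_FRAME_DEL: 6,
        VariantClass.IN_FRAME_INS: 2,
        VariantClass.NONSTOP: 2,
        VariantClass.INTRON: 36,
        VariantClass.SPLICE_SITE: 45,
        VariantClass.UTR3: 182,
    }
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


@dataclass
class SimConfig:
    seed: int = 0
    cohorts: list[CohortSpec] = field(default_factory=_default_cohorts)
    #: expected UGT mutations per background somatic mutation
    ugt_per_mutation: float = 0.00128
    class_mix: dict[VariantClass, float] = field(default_factory=_default_class_mix)
    misannotation: MisannotationRates = field(default_factory=MisannotationRates)
    #: probability a new UGT mutation reuses an existing key (recurrence)
    recurrence_boost: float = 0.08
    hotspots: list[HotspotSpec] = field(
        default_factory=lambda: [HotspotSpec("UGT2B4", 100, 112, 7)]
    )
    sift_deleterious_fraction: float = 0.55

    def validate(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix sums to {total}, not 1")
        for name, rate in (
            ("ugt_per_mutation", self.ugt_per_mutation),
            ("recurrence_boost", self.recurrence_boost),
            ("sift_deleterious_fraction", self.sift_deleterious_fraction),
            ("exon1_as_intron", self.misannotation.exon1_as_intron),
            ("shared_exon_relabel", self.misannotation.shared_exon_relabel),
            ("variant_transcript", self.misannotation.variant_transcript),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name}={rate} outside [0, 1]")
        for spec in self.cohorts:
            if spec.n_tumors <= 0 or spec.burden_median <= 0:
                raise ValueError(f"invalid cohort spec {spec}")


# ---------------------------------------------------------------------------
# truth ledger
# ---------------------------------------------------------------------------


@dataclass
class SampleTruth:
    barcode: str
    cohort: str
    sample_type: str
    burden: int
    hypermutator: bool


@dataclass
class MutationTruth:
    key: tuple[str, str, int, str, str]  # barcode, chrom, g_start, ref, alt
    true_label: str  # gene symbol or shared-category label
    true_class: str
    true_cdna: str
    true_protein: str
    misannotation_rule: str = "none"
    recurrence_key: str = ""
    hotspot_id: str = ""
    ccle_overlap: bool = False


@dataclass
class TruthLedger:
    samples: dict[str, SampleTruth] = field(default_factory=dict)
    mutations: dict[tuple, MutationTruth] = field(default_factory=dict)

    def add_mutation(self, truth: MutationTruth) -> None:
        if truth.key in self.mutations:
            raise ValueError(f"duplicate ledger key {truth.key}")
        self.mutations[truth.key] = truth

    def truth_for(self, rec: MutationRecord) -> MutationTruth:
        return self.mutations[
            (rec.sample_barcode, rec.chrom, rec.g_start, rec.ref_allele, rec.alt_allele)
        ]

    def hypermutators(self) -> set[str]:
        return {b for b, s in self.samples.items() if s.hypermutator}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "samples": {b: asdict(s) for b, s in self.samples.items()},
            "mutations": [
                {**asdict(m), "key": list(m.key)} for m in self.mutations.values()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=0, sort_keys=True))


# ---------------------------------------------------------------------------
# placement machinery
# ---------------------------------------------------------------------------


def _plus_strand(tm: TranscriptModel, allele: str) -> str:
    return tm.transcript_sense(allele)  # reverse-complement is an involution


class _Placer:
    """Places class-consistent mutations on registry transcripts."""

    def __init__(self, registry: GeneFamilyRegistry, rng: np.random.Generator):
        self.registry = registry
        self.rng = rng
        self.tms_by_id = registry.transcripts_by_id()
        # labels: standalone genes, family members, shared categories
        self.member_genes = sorted(
            g for g in registry.transcripts if registry.family_of(g) is not None
        )
        self.standalone = sorted(
            g for g in registry.transcripts if registry.family_of(g) is None
        )
        self.categories = [f.shared_category_label for f in registry.families]

    # ---- label geometry -------------------------------------------------
    def tm_for(self, label: str) -> TranscriptModel:
        return self.registry.transcript_for_label(label)

    def cds_range(self, label: str) -> tuple[int, int]:
        tm = self.tm_for(label)
        fam = self.registry.family_for_label(label)
        if fam is not None:  # shared block: CDS past the unique exon 1
            unique_len = sum(
                len(e) for e in tm.exons if e.role is ExonRole.UNIQUE
            )
            utr5_len = tm._cds_tx_start - 1
            return (unique_len - utr5_len + 1, tm.cds_len)
        if self.registry.family_of(label) is not None:  # member: exon 1 only
            tm_m = self.registry.transcripts[label]
            unique_len = sum(len(e) for e in tm_m.exons if e.role is ExonRole.UNIQUE)
            utr5_len = tm_m._cds_tx_start - 1
            return (1, unique_len - utr5_len)
        return (1, tm.cds_len)

    def labels_for_class(self, vc: VariantClass) -> list[str]:
        if vc in (VariantClass.UTR5, VariantClass.TRANSLATION_START_SITE):
            return self.standalone + self.member_genes
        if vc is VariantClass.UTR3:
            return self.standalone + self.categories
        if vc in (VariantClass.INTRON, VariantClass.SPLICE_SITE):
            return self.standalone + self.categories + self.member_genes
        return self.standalone + self.member_genes + self.categories

    # ---- per-class placement --------------------------------------------
    def place(self, vc: VariantClass, label: str) -> dict | None:
        tm = self.tm_for(label)
        rng = self.rng
        if vc is VariantClass.UTR5:
            n = int(rng.integers(1, 11))  # within the stored -10..-1 window
            g = tm.utr5_to_genomic(n)
            ref_t = tm.utr5_seq_window[10 - n]
            alt_t = self._other_base(ref_t)
            return self._snv(tm, g, ref_t, alt_t)
        if vc is VariantClass.UTR3:
            n = int(rng.integers(1, len(tm.utr3_seq) + 1))
            g = tm.utr3_to_genomic(n)
            ref_t = tm.utr3_seq[n - 1]
            alt_t = self._other_base(ref_t)
            return self._snv(tm, g, ref_t, alt_t)
        if vc is VariantClass.TRANSLATION_START_SITE:
            c = int(rng.integers(1, 4))
            return self._cds_snv(tm, c)
        if vc is VariantClass.NONSTOP:
            c = tm.cds_len - int(rng.integers(0, 3))
            for _ in range(6):
                out = self._cds_snv(tm, c)
                if out and out["truth_class"] is VariantClass.NONSTOP:
                    return out
            return None
        if vc in (
            VariantClass.MISSENSE,
            VariantClass.NONSENSE,
            VariantClass.SILENT,
        ):
            lo, hi = self.cds_range(label)
            lo = max(lo, 4)  # keep clear of the start codon
            hi = min(hi, tm.cds_len - 3)  # and of the stop codon
            for _ in range(300):
                c = int(rng.integers(lo, hi + 1))
                out = self._cds_snv(tm, c)
                if out and out["truth_class"] is vc:
                    return out
            return None
        if vc in (VariantClass.FRAME_SHIFT_DEL, VariantClass.IN_FRAME_DEL):
            length = 3 if vc is VariantClass.IN_FRAME_DEL else int(rng.integers(1, 3))
            return self._deletion(tm, label, length)
        if vc in (VariantClass.FRAME_SHIFT_INS, VariantClass.IN_FRAME_INS):
            length = 3 if vc is VariantClass.IN_FRAME_INS else int(rng.integers(1, 3))
            return self._insertion(tm, label, length)
        if vc is VariantClass.SPLICE_SITE:
            return self._splice(tm, label)
        if vc is VariantClass.INTRON:
            return self._intron(tm, label)
        raise AssertionError(vc)

    # ---- primitives ------------------------------------------------------
    def _other_base(self, ref: str) -> str:
        choices = [b for b in _BASES if b != ref]
        return choices[int(self.rng.integers(0, 3))]

    def _snv(self, tm: TranscriptModel, g: int, ref_t: str, alt_t: str) -> dict:
        return {
            "tm": tm,
            "g_start": g,
            "g_end": g,
            "ref": _plus_strand(tm, ref_t),
            "alt": _plus_strand(tm, alt_t),
            "variant_type": VariantType.SNP,
        }

    def _cds_snv(self, tm: TranscriptModel, c: int) -> dict | None:
        ref_t = tm.cds_seq[c - 1]
        alt_t = self._other_base(ref_t)
        g = tm.cdna_to_genomic(c)
        out = self._snv(tm, g, ref_t, alt_t)
        probe = MutationRecord(
            gene_symbol=tm.gene,
            chrom=tm.chrom,
            g_start=g,
            g_end=g,
            ref_allele=out["ref"],
            alt_allele=out["alt"],
            variant_class=VariantClass.QUARANTINE,
            variant_type=VariantType.SNP,
            sample_barcode="probe",
        )
        cons = consequence_call(tm, probe)
        out["truth_class"] = cons.variant_class
        out["cdna"] = cons.cdna
        out["protein"] = cons.protein
        return out

    def _contiguous_run(self, tm: TranscriptModel, c_lo: int, length: int) -> bool:
        gs = [tm.cdna_to_genomic(c) for c in range(c_lo, c_lo + length)]
        return max(gs) - min(gs) == length - 1

    def _deletion(self, tm: TranscriptModel, label: str, length: int) -> dict | None:
        lo, hi = self.cds_range(label)
        lo = max(lo, 4)
        hi = min(hi, tm.cds_len - 3 - length)
        for _ in range(100):
            c = int(self.rng.integers(lo, hi + 1))
            if not self._contiguous_run(tm, c, length):
                continue
            gs = sorted(tm.cdna_to_genomic(cc) for cc in range(c, c + length))
            deleted_t = tm.cds_seq[c - 1 : c - 1 + length]
            return {
                "tm": tm,
                "g_start": gs[0],
                "g_end": gs[-1],
                "ref": _plus_strand(tm, deleted_t),
                "alt": "-",
                "variant_type": VariantType.DEL,
            }
        return None

    def _insertion(self, tm: TranscriptModel, label: str, length: int) -> dict | None:
        lo, hi = self.cds_range(label)
        lo = max(lo, 4)
        hi = min(hi, tm.cds_len - 4)
        for _ in range(100):
            c = int(self.rng.integers(lo, hi + 1))
            if not self._contiguous_run(tm, c, 2):
                continue
            ins_t = "".join(
                _BASES[int(self.rng.integers(0, 4))] for _ in range(length)
            )
            g = tm.cdna_to_genomic(c)
            return {
                "tm": tm,
                "g_start": g,
                "g_end": g,
                "ref": "-",
                "alt": _plus_strand(tm, ins_t),
                "variant_type": VariantType.INS,
            }
        return None

    def _splice(self, tm: TranscriptModel, label: str) -> dict | None:
        fam = self.registry.family_for_label(label)
        n_introns = len(tm.exons) - 1
        if fam is not None:
            choices = [
                (k, side)
                for k in range(1, n_introns + 1)
                for side in ("donor", "acceptor")
                if not (k == 1 and side == "donor")  # member-specific side
            ]
        elif self.registry.family_of(tm.gene) is not None:
            choices = [(1, "donor")]  # the unique exon's own splice site
        else:
            choices = [
                (k, side)
                for k in range(1, n_introns + 1)
                for side in ("donor", "acceptor")
            ]
        k, side = choices[int(self.rng.integers(0, len(choices)))]
        offset = int(self.rng.integers(1, 3))
        canonical = {"donor": "GT", "acceptor": "AG"}[side]
        ref_t = canonical[offset - 1] if side == "donor" else canonical[2 - offset]
        alt_t = self._other_base(ref_t)
        g = tm.splice_site_genomic(k, side, offset)
        return self._snv(tm, g, ref_t, alt_t)

    def _intron(self, tm: TranscriptModel, label: str) -> dict | None:
        fam = self.registry.family_for_label(label)
        n_introns = len(tm.exons) - 1
        if fam is not None:
            introns = list(range(2, n_introns + 1)) or [1]
        elif self.registry.family_of(tm.gene) is not None:
            introns = [1]
        else:
            introns = list(range(1, n_introns + 1))
        k = introns[int(self.rng.integers(0, len(introns)))]
        offset = int(self.rng.integers(3, 9))  # clear of both dinucleotides
        side = "donor" if self.registry.family_of(tm.gene) is not None and fam is None else (
            "donor" if self.rng.random() < 0.5 else "acceptor"
        )
        up = tm.exons[k - 1]
        down = tm.exons[k]
        if tm.strand is Strand.PLUS:
            g = up.g_end + offset if side == "donor" else down.g_start - offset
        else:
            g = up.g_start - offset if side == "donor" else down.g_end + offset
        ref_t = _BASES[int(self.rng.integers(0, 4))]
        alt_t = self._other_base(ref_t)
        return self._snv(tm, g, ref_t, alt_t)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_BACKGROUND_GENES = [f"BGGENE{i}" for i in range(1, 51)]


def _barcode(cohort_i: int, tumor_i: int, code: str) -> str:
    site = f"{cohort_i + 10:02d}"
    part = f"A{tumor_i:04d}"
    return f"TCGA-{site}-{part}-{code}A-11D-A000-09"


def generate_cohort(
    config: SimConfig,
    registry: GeneFamilyRegistry,
) -> tuple[list[MutationRecord], TruthLedger]:
    """Generate a multi-cohort synthetic MAF record set with ground truth.

    Deterministic for a fixed ``config.seed``.  Returns all records
    (background + truthfully-annotated UGT records) and the ledger; apply
    :func:`inject_misannotations` to obtain the corrupted MAF the pipeline
    is expected to repair.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    placer = _Placer(registry, rng)
    ledger = TruthLedger()
    records: list[MutationRecord] = []

    classes = list(config.class_mix)
    class_p = np.array([config.class_mix[c] for c in classes])
    recurrence_pool: list[tuple[dict, str]] = []  # (placement, label)

    for ci, spec in enumerate(config.cohorts):
        for ti in range(spec.n_tumors):
            u = rng.random()
            if u < spec.recurrent_fraction:
                code, stype = "02", SampleType.RECURRENT
            elif u < spec.recurrent_fraction + spec.metastatic_fraction:
                code, stype = "06", SampleType.METASTATIC
            else:
                code, stype = "01", SampleType.PRIMARY_SOLID
            barcode = _barcode(ci, ti, code)
            burden = float(
                spec.burden_median * np.exp(spec.burden_sigma * rng.standard_normal())
            )
            hyper = bool(rng.random() < spec.hypermutator_fraction)
            if hyper:
                burden *= spec.hypermutator_multiplier
            n_background = max(1, int(round(burden)))
            ledger.samples[barcode] = SampleTruth(
                barcode=barcode,
                cohort=spec.cancer,
                sample_type=stype.value,
                burden=n_background,
                hypermutator=hyper,
            )
            records.extend(_background(rng, barcode, spec.cancer, n_background))

            n_ugt = int(rng.poisson(config.ugt_per_mutation * n_background))
            for _ in range(n_ugt):
                _emit_ugt(
                    config, placer, rng, ledger, records, barcode, spec.cancer,
                    classes, class_p, recurrence_pool,
                )

    _emit_hotspots(config, placer, rng, ledger, records)
    return records, ledger


def _background(rng, barcode: str, cancer: str, n: int) -> list[MutationRecord]:
    out = []
    genes = rng.integers(0, len(_BACKGROUND_GENES), size=n)
    positions = rng.integers(1_000_000, 50_000_000, size=n)
    refs = rng.integers(0, 4, size=n)
    alts = rng.integers(1, 4, size=n)
    for i in range(n):
        ref = _BASES[refs[i]]
        alt = _BASES[(refs[i] + alts[i]) % 4]
        out.append(
            MutationRecord(
                gene_symbol=_BACKGROUND_GENES[genes[i]],
                chrom="7",
                g_start=int(positions[i]),
                g_end=int(positions[i]),
                ref_allele=ref,
                alt_allele=alt,
                variant_class=VariantClass.MISSENSE,
                variant_type=VariantType.SNP,
                sample_barcode=barcode,
                cancer_type=cancer,
            )
        )
    return out


def _materialize(
    placer: _Placer,
    placement: dict,
    label: str,
    barcode: str,
    cancer: str,
    sift_p: float,
    rng,
) -> tuple[MutationRecord, MutationTruth] | None:
    tm = placement["tm"]
    rec = MutationRecord(
        gene_symbol=label,
        chrom=tm.chrom,
        g_start=placement["g_start"],
        g_end=placement["g_end"],
        ref_allele=placement["ref"],
        alt_allele=placement["alt"],
        variant_class=VariantClass.QUARANTINE,
        variant_type=placement["variant_type"],
        transcript_id=tm.transcript_id,
        sample_barcode=barcode,
        cancer_type=cancer,
    )
    cons = consequence_call(tm, rec)
    rec.variant_class = cons.variant_class
    rec.cdna_change = cons.cdna
    rec.protein_change = cons.protein
    if cons.variant_class is VariantClass.MISSENSE:
        rec.sift_call = (
            SiftCall.DELETERIOUS if rng.random() < sift_p else SiftCall.TOLERATED
        )
    truth = MutationTruth(
        key=(barcode, rec.chrom, rec.g_start, rec.ref_allele, rec.alt_allele),
        true_label=label,
        true_class=cons.variant_class.value,
        true_cdna=cons.cdna,
        true_protein=cons.protein,
    )
    return rec, truth


def _emit_ugt(
    config: SimConfig,
    placer: _Placer,
    rng,
    ledger: TruthLedger,
    records: list[MutationRecord],
    barcode: str,
    cancer: str,
    classes,
    class_p,
    recurrence_pool,
) -> None:
    for _ in range(40):  # retries against key collisions / placement failure
        if recurrence_pool and rng.random() < config.recurrence_boost:
            placement, label = recurrence_pool[
                int(rng.integers(0, len(recurrence_pool)))
            ]
            rec_key = "recur"
        else:
            vc = classes[int(rng.choice(len(classes), p=class_p))]
            labels = placer.labels_for_class(vc)
            label = labels[int(rng.integers(0, len(labels)))]
            placement = placer.place(vc, label)
            rec_key = ""
            if placement is None:
                continue
        out = _materialize(
            placer, placement, label, barcode, cancer,
            config.sift_deleterious_fraction, rng,
        )
        if out is None:
            continue
        rec, truth = out
        if truth.key in ledger.mutations:
            continue  # same sample already carries this key
        truth.recurrence_key = (
            f"{rec.chrom}:{rec.g_start}:{rec.ref_allele}:{rec.alt_allele}"
            if rec_key
            else ""
        )
        ledger.add_mutation(truth)
        records.append(rec)
        if placement["variant_type"] is VariantType.SNP and not rec_key:
            recurrence_pool.append((placement, label))
        return


def _emit_hotspots(config, placer, rng, ledger, records) -> None:
    """Extra clustered events in configured cDNA windows, on fresh samples."""
    for hi, spec in enumerate(config.hotspots):
        tm = placer.tm_for(spec.gene)
        for ev in range(spec.n_events):
            barcode = _barcode(90 + hi, ev, "01")
            if barcode not in ledger.samples:
                ledger.samples[barcode] = SampleTruth(
                    barcode=barcode,
                    cohort=config.cohorts[0].cancer,
                    sample_type=SampleType.PRIMARY_SOLID.value,
                    burden=1,
                    hypermutator=False,
                )
            for _ in range(60):
                c = (
                    spec.c_lo
                    if ev == 0
                    else spec.c_hi
                    if ev == 1
                    else int(rng.integers(spec.c_lo, spec.c_hi + 1))
                )
                out = placer._cds_snv(tm, c)
                if out is None:
                    continue
                mat = _materialize(
                    placer, out, spec.gene, barcode, config.cohorts[0].cancer,
                    config.sift_deleterious_fraction, rng,
                )
                if mat is None:
                    continue
                rec, truth = mat
                if truth.key in ledger.mutations:
                    continue
                truth.hotspot_id = f"hotspot{hi}"
                ledger.add_mutation(truth)
                records.append(rec)
                break


# ---------------------------------------------------------------------------
# mis-annotation injection
# ---------------------------------------------------------------------------


def inject_misannotations(
    records: Sequence[MutationRecord],
    ledger: TruthLedger,
    registry: GeneFamilyRegistry,
    rates: MisannotationRates,
    seed: int,
) -> tuple[list[MutationRecord], TruthLedger]:
    """Corrupt truthful records with the documented MAF annotation quirks.

    Returns a new record list (ledger entries are updated in place with
    the applied rule).  With all rates at zero the output equals the
    input.  The decoy rule adds new records inside decoy intervals,
    ledgered with rule ``decoy`` (truth: to be dropped).
    """
    rng = np.random.default_rng(seed)
    out: list[MutationRecord] = []
    category_labels = {f.shared_category_label: f for f in registry.families}

    for rec in records:
        key = (rec.sample_barcode, rec.chrom, rec.g_start, rec.ref_allele, rec.alt_allele)
        truth = ledger.mutations.get(key)
        if truth is None:  # background record
            out.append(rec)
            continue
        label = truth.true_label
        fam = category_labels.get(label)
        if fam is not None and len(fam.member_genes) == 2:
            if rng.random() < rates.variant_transcript:
                variant_id = next(
                    v.variant_id
                    for v in registry.variant_transcripts
                    if v.canonical_gene in fam.member_genes
                )
                out.append(
                    _shift_variant_tx(rec, fam.member_genes[0], variant_id)
                )
                truth.misannotation_rule = "variant_transcript"
                continue
        if fam is not None:
            if rng.random() < rates.shared_exon_relabel:
                member = fam.member_genes[int(rng.integers(0, len(fam.member_genes)))]
                bad = replace(rec, gene_symbol=member)
                bad.affected_genes = []
                out.append(bad)
                truth.misannotation_rule = "shared_exon_relabel"
                continue
        if label == rates.exon1_victim_gene:
            if rng.random() < rates.exon1_as_intron:
                bad = replace(
                    rec,
                    gene_symbol=rates.exon1_sibling_label,
                    variant_class=VariantClass.INTRON,
                    cdna_change="",
                    protein_change="",
                )
                bad.affected_genes = []
                out.append(bad)
                truth.misannotation_rule = "exon1_as_intron"
                continue
        out.append(rec)

    # decoy-interval records mis-labelled as family-member introns
    n_samples = len(ledger.samples)
    barcodes = sorted(ledger.samples)
    for decoy in registry.decoy_intervals:
        n_decoy = int(rng.poisson(rates.decoy_per_tumor * n_samples))
        fam_member = None
        for family in registry.families:
            tm = registry.transcripts[family.member_genes[0]]
            if tm.chrom == decoy.chrom:
                fam_member = family.member_genes[-1]
                break
        if fam_member is None:
            continue
        emitted = 0
        while emitted < n_decoy:
            g = int(rng.integers(decoy.g_start, decoy.g_end + 1))
            barcode = barcodes[int(rng.integers(0, n_samples))]
            ref = _BASES[int(rng.integers(0, 4))]
            alt = [b for b in _BASES if b != ref][int(rng.integers(0, 3))]
            key = (barcode, decoy.chrom, g, ref, alt)
            if key in ledger.mutations:
                continue
            rec = MutationRecord(
                gene_symbol=fam_member,
                chrom=decoy.chrom,
                g_start=g,
                g_end=g,
                ref_allele=ref,
                alt_allele=alt,
                variant_class=VariantClass.INTRON,
                variant_type=VariantType.SNP,
                sample_barcode=barcode,
                cancer_type=ledger.samples[barcode].cohort,
            )
            ledger.add_mutation(
                MutationTruth(
                    key=key,
                    true_label=decoy.label,
                    true_class="decoy",
                    true_cdna="",
                    true_protein="",
                    misannotation_rule="decoy",
                )
            )
            out.append(rec)
            emitted += 1
    return out, ledger


def _shift_variant_tx(
    rec: MutationRecord, member_label: str, variant_id: str
) -> MutationRecord:
    """Annotate a shared-block record on the extended variant transcript:
    single-member label, variant transcript id, cDNA coordinate shifted by
    the inserted exon's length (150 nt in the toy locus)."""
    from .gene_models import parse_c_position

    shifted = rec.cdna_change
    parsed = parse_c_position(rec.cdna_change) if rec.cdna_change else None
    if parsed and parsed[0] == "c":
        import re

        shifted = re.sub(
            r"^c\.(\d+)",
            lambda m: f"c.{int(m.group(1)) + 150}",
            rec.cdna_change,
        )
    bad = replace(
        rec,
        gene_symbol=member_label,
        transcript_id=variant_id,
        cdna_change=shifted,
    )
    bad.affected_genes = []
    return bad


# ---------------------------------------------------------------------------
# CCLE-like table
# ---------------------------------------------------------------------------


def generate_ccle_like(
    config: SimConfig,
    tcga_records: Sequence[MutationRecord],
    overlap_k: int,
    registry: GeneFamilyRegistry,
    ledger: TruthLedger,
    n_extra: int = 30,
) -> list[MutationRecord]:
    """A CCLE-dialect record set sharing exactly ``overlap_k`` keys with
    the given (truth-annotated) TCGA UGT records."""
    rng = np.random.default_rng(config.seed + 1)
    ugt_keys = [
        r.key for r in tcga_records if r.key[0] != "7"  # skip background chrom
    ]
    unique_keys = sorted(set(ugt_keys))
    if overlap_k > len(unique_keys):
        raise ValueError(f"overlap_k={overlap_k} exceeds {len(unique_keys)} TCGA keys")
    chosen_idx = rng.choice(len(unique_keys), size=overlap_k, replace=False)
    chosen = {unique_keys[i] for i in chosen_idx}
    by_key = {}
    for r in tcga_records:
        by_key.setdefault(r.key, r)

    out: list[MutationRecord] = []
    for ki, key in enumerate(sorted(chosen)):
        src = by_key[key]
        rec = replace(src, sample_barcode=f"TOYCELL{ki:04d}", cancer_type="")
        rec.source = Source.CCLE
        rec.affected_genes = []
        out.append(rec)
        truth_key = (src.sample_barcode, src.chrom, src.g_start, src.ref_allele, src.alt_allele)
        if truth_key in ledger.mutations:
            ledger.mutations[truth_key].ccle_overlap = True

    placer = _Placer(registry, rng)
    tcga_key_set = set(unique_keys)
    classes = [VariantClass.MISSENSE, VariantClass.NONSENSE, VariantClass.SILENT]
    emitted = 0
    while emitted < n_extra:
        vc = classes[int(rng.integers(0, len(classes)))]
        labels = placer.labels_for_class(vc)
        label = labels[int(rng.integers(0, len(labels)))]
        placement = placer.place(vc, label)
        if placement is None:
            continue
        mat = _materialize(
            placer, placement, label, f"TOYCELL{1000 + emitted:04d}", "",
            config.sift_deleterious_fraction, rng,
        )
        if mat is None:
            continue
        rec, _ = mat
        rec.source = Source.CCLE
        if rec.key in tcga_key_set or any(r.key == rec.key for r in out):
            continue
        out.append(rec)
        emitted += 1
    return out
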