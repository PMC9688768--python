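"""Reading and writing MAF-dialect and CCLE-dialect mutation tables.

The three upstream sources (the pan-cancer MC3 MAF, DepMap's mutation CSV
and cBioPortal exports) carry the same information under different column
names.  Dialects are therefore declared as data — a column map plus a
separator — and the reader is a single code path.  Parsing is total: every
data row either becomes a :class:`~ugtscape.records.MutationRecord` or a
logged skip, and the counts reconcile.
"""

from __future__ import annotations

import csv
import gzip
import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .records import (
    MutationRecord,
    RecordError,
    SAMPLE_TYPE_CODES,
    SampleMeta,
    SampleType,
    SiftCall,
    Source,
    VariantClass,
    VariantType,
    classify_label,
    parse_sift,
)


class MafFormatError(ValueError):
    """The file cannot be read at all (missing header column, empty file)."""


class BarcodeError(ValueError):
    """A TCGA barcode does not follow the dash-separated convention."""


@dataclass(frozen=True)
class Dialect:
    """Column-name map for one mutation-table flavour.

    ``columns`` maps record fields to header names; only the required core
    set must be present in a file, extra columns are ignored.
    """

    name: str
    sep: str
    columns: dict[str, str]
    source: Source

    REQUIRED = (
        "gene_symbol",
        "chrom",
        "g_start",
        "ref_allele",
        "alt_allele",
        "variant_class",
        "sample_barcode",
    )


MC3 = Dialect(
    name="mc3",
    sep="\t",
    columns={
        "gene_symbol": "Hugo_Symbol",
        "chrom": "Chromosome",
        "g_start": "Start_Position",
        "g_end": "End_Position",
        "ref_allele": "Reference_Allele",
        "alt_allele": "Tumor_Seq_Allele2",
        "variant_class": "Variant_Classification",
        "variant_type": "Variant_Type",
        "transcript_id": "Transcript_ID",
        "cdna_change": "HGVSc",
        "protein_change": "HGVSp_Short",
        "sift_call": "SIFT",
        "sample_barcode": "Tumor_Sample_Barcode",
    },
    source=Source.TCGA,
)

DEPMAP = Dialect(
    name="depmap",
    sep=",",
    columns={
        "gene_symbol": "Hugo_Symbol",
        "chrom": "Chromosome",
        "g_start": "Start_position",
        "g_end": "End_position",
        "ref_allele": "Reference_Allele",
        "alt_allele": "Tumor_Seq_Allele1",
        "variant_class": "Variant_Classification",
        "variant_type": "Variant_Type",
        "transcript_id": "Annotation_Transcript",
        "cdna_change": "cDNA_Change",
        "protein_change": "Protein_Change",
        "sample_barcode": "CCLE_Name",
    },
    source=Source.CCLE,
)

CBIOPORTAL = Dialect(
    name="cbioportal",
    sep="\t",
    columns={
        "gene_symbol": "Hugo_Symbol",
        "chrom": "Chromosome",
        "g_start": "Start_Position",
        "g_end": "End_Position",
        "ref_allele": "Reference_Allele",
        "alt_allele": "Tumor_Seq_Allele2",
        "variant_class": "Variant_Classification",
        "variant_type": "Variant_Type",
        "transcript_id": "Transcript_ID",
        "cdna_change": "HGVSc",
        "protein_change": "HGVSp_Short",
        "sample_barcode": "SAMPLE_ID",
    },
    source=Source.CCLE,
)

DIALECTS: dict[str, Dialect] = {d.name: d for d in (MC3, DEPMAP, CBIOPORTAL)}


@dataclass
class Diagnostics:
    """Line-oriented account of one read: every row is a record or a skip."""

    path: str = ""
    n_rows: int = 0
    n_records: int = 0
    skips: list[tuple[int, str]] = field(default_factory=list)
    class_census: Counter = field(default_factory=Counter)
    notes: list[str] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skips)

    def reconciles(self) -> bool:
        return self.n_rows == self.n_records + self.n_skipped

    def log_lines(self) -> list[str]:
        lines = [f"INFO\tread {self.n_records} records, {self.n_skipped} skips from {self.path}"]
        lines += [f"WARN\trow {row}\t{reason}" for row, reason in self.skips]
        lines += [f"INFO\t{n}" for n in self.notes]
        return lines


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8", newline="")
    return open(path, "r", encoding="utf-8", newline="")


def _parse_row(
    row: dict[str, str], dialect: Dialect
) -> MutationRecord:
    cols = dialect.columns

    def get(fieldname: str, default: str = "") -> str:
        col = cols.get(fieldname)
        if col is None:
            return default
        return (row.get(col) or default).strip()

    barcode = get("sample_barcode")
    if not barcode:
        raise RecordError("missing sample barcode")
    gene = get("gene_symbol")
    if not gene:
        raise RecordError("missing gene symbol")
    chrom = get("chrom")
    if not chrom:
        raise RecordError("missing chromosome")
    try:
        g_start = int(get("g_start"))
    except ValueError as exc:
        raise RecordError(f"unparseable start position {get('g_start')!r}") from exc
    g_end_raw = get("g_end")
    g_end = int(g_end_raw) if g_end_raw else g_start

    vt_raw = get("variant_type", "SNP").upper()
    try:
        variant_type = VariantType(vt_raw)
    except ValueError:
        variant_type = VariantType.DNP

    variant_class = classify_label(get("variant_class"))
    sift = parse_sift(get("sift_call"))
    if variant_class is not VariantClass.MISSENSE:
        sift = SiftCall.NOT_ASSESSED

    return MutationRecord(
        gene_symbol=gene,
        chrom=chrom,
        g_start=g_start,
        g_end=g_end,
        ref_allele=get("ref_allele") or "-",
        alt_allele=get("alt_allele") or "-",
        variant_class=variant_class,
        variant_type=variant_type,
        transcript_id=get("transcript_id"),
        cdna_change=get("cdna_change"),
        protein_change=get("protein_change"),
        sift_call=sift,
        sample_barcode=barcode,
        source=dialect.source,
    )


def _read_table(
    path: str | Path, dialect: Dialect
) -> tuple[list[MutationRecord], Diagnostics]:
    diag = Diagnostics(path=str(path))
    with _open_text(path) as handle:
        reader = csv.DictReader(handle, delimiter=dialect.sep)
        if reader.fieldnames is None:
            raise MafFormatError(f"{path}: empty file")
        header = set(reader.fieldnames)
        for fieldname in Dialect.REQUIRED:
            col = dialect.columns[fieldname]
            if col not in header:
                raise MafFormatError(
                    f"{path}: required column {col!r} (field {fieldname}) missing "
                    f"from header for dialect {dialect.name!r}"
                )
        records: list[MutationRecord] = []
        for i, row in enumerate(reader, start=2):  # 1 is the header line
            diag.n_rows += 1
            try:
                rec = _parse_row(row, dialect)
            except (RecordError, ValueError) as exc:
                diag.skips.append((i, str(exc)))
                continue
            if rec.variant_class is VariantClass.QUARANTINE:
                diag.notes.append(
                    f"row {i}: unknown classification quarantined"
                )
            diag.class_census[rec.variant_class.value] += 1
            records.append(rec)
            diag.n_records += 1
    return records, diag


def read_maf(
    path: str | Path, dialect: Dialect | str = MC3
) -> tuple[list[MutationRecord], Diagnostics]:
    """Read a tab-separated (optionally gzipped) MAF into mutation records.

    Rows failing required-field parsing are skipped and logged with the row
    number and reason; missing required header columns are a hard error.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    return _read_table(path, dialect)


def read_ccle_table(
    path: str | Path, dialect: Dialect | str = DEPMAP
) -> tuple[list[MutationRecord], Diagnostics]:
    """Read a CCLE-style mutation table (CSV or TSV per dialect).

    The sample identifier is the cell-line name and ``source`` is CCLE.
    CCLE exports carry no UTR classes; their absence is tolerated, not
    required, and the per-class census in the diagnostics records what was
    actually present (e.g. Silent rows appear in DepMap exports but not in
    cBioPortal ones).
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    records, diag = _read_table(path, dialect)
    silent = diag.class_census.get(VariantClass.SILENT.value, 0)
    diag.notes.append(f"class census: {dict(diag.class_census)}; silent rows: {silent}")
    return records, diag


def parse_tcga_barcode(barcode: str) -> SampleMeta:
    """Split a TCGA barcode into participant identity and sample type.

    ``TCGA-D1-A17Q-01A-11D-A12J-09`` → participant ``TCGA-D1-A17Q``, sample
    type code ``01`` (primary solid tumor).  Unknown codes map to ``other``.
    """
    fields = barcode.strip().split("-")
    if len(fields) < 4:
        raise BarcodeError(f"barcode {barcode!r} has fewer than 4 dash-separated fields")
    code = fields[3][:2]
    if len(code) != 2 or not code.isdigit():
        raise BarcodeError(f"barcode {barcode!r}: sample field {fields[3]!r} lacks a 2-digit code")
    return SampleMeta(
        barcode=barcode.strip(),
        participant_id="-".join(fields[:3]),
        sample_type_code=code,
        sample_type=SAMPLE_TYPE_CODES.get(code, SampleType.OTHER),
    )


def write_records(
    records: Iterable[MutationRecord],
    path: str | Path,
    dialect: Dialect | str = MC3,
) -> Path:
    """Write records in the given dialect; ``read_maf`` round-trips all mapped fields."""
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    path = Path(path)
    cols = dialect.columns
    fieldnames = list(cols.values())
    opener = (
        (lambda p: io.TextIOWrapper(gzip.open(p, "wb"), encoding="utf-8", newline=""))
        if path.suffix == ".gz"
        else (lambda p: open(p, "w", encoding="utf-8", newline=""))
    )
    with opener(path) as handle:
        writer = csv.DictWriter(handle, fieldnames=fieldnames, delimiter=dialect.sep)
        writer.writeheader()
        for rec in records:
            row = {}
            for fieldname, col in cols.items():
                value = getattr(rec, fieldname)
                if isinstance(value, (VariantClass, VariantType, SiftCall)):
                    value = value.value
                row[col] = value
            writer.writerow(row)
    return path


def records_to_frame(records: Sequence[MutationRecord]):
    """Flatten records into a pandas DataFrame for aggregation layers."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_symbol": [r.gene_symbol for r in records],
            "chrom": [r.chrom for r in records],
            "g_start": [r.g_start for r in records],
            "g_end": [r.g_end for r in records],
            "ref_allele": [r.ref_allele for r in records],
            "alt_allele": [r.alt_allele for r in records],
            "variant_class": [r.variant_class.value for r in records],
            "variant_type": [r.variant_type.value for r in records],
            "transcript_id": [r.transcript_id for r in records],
            "cdna_change": [r.cdna_change for r in records],
            "protein_change": [r.protein_change for r in records],
            "sift_call": [r.sift_call.value for r in records],
            "sample_barcode": [r.sample_barcode for r in records],
            "source": [r.source.value for r in records],
            "cancer_type": [r.cancer_type for r in records],
        }
    )
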