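"""Access to the packaged fixtures (toy registry, catalogs, table TSVs)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .annotation import MirnaSite, load_mirna_catalog
from .gene_models import GeneFamilyRegistry, load_registry


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("ugtscape").joinpath("data", name))


def toy_registry() -> GeneFamilyRegistry:
    """The packaged toy UGT registry: real 22-gene topology (9-member
    shared-exon family, 2-member shared-exon family, 11 standalone genes,
    decoy interval, variant transcript) at reduced exon sizes."""
    return load_registry(data_path("toy_registry.yaml"), data_path("toy_registry.fasta"))


def toy_mirna_catalog() -> list[MirnaSite]:
    return load_mirna_catalog(data_path("mirna_sites.tsv"))


def toy_protein_alignment_path() -> Path:
    return data_path("ugt1a_toy_protein_alignment.fasta")


def cohort_table() -> pd.DataFrame:
    """Published per-cohort raw counts (tumors, mutations, UGT mutations)."""
    return pd.read_csv(data_path("cohort_table.tsv"), sep="\t")


def gene_class_table() -> pd.DataFrame:
    """Published per-gene variant-class counts for the 22 genes + 2 shared
    category rows."""
    return pd.read_csv(data_path("gene_class_table.tsv"), sep="\t")


def ccle_gene_table() -> pd.DataFrame:
    """Published per-gene CCLE mutation counts with TCGA-overlap counts."""
    return pd.read_csv(data_path("ccle_gene_table.tsv"), sep="\t")


def multiplicity_table() -> pd.DataFrame:
    """Published per-tumor UGT mutation multiplicity histogram (UCEC)."""
    return pd.read_csv(data_path("ucec_multiplicity.tsv"), sep="\t")


def recurrence_table() -> pd.DataFrame:
    """Published recurrence-size histogram (occurrences -> n groups)."""
    return pd.read_csv(data_path("recurrence_histogram.tsv"), sep="\t")
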