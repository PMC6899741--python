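"""Normalized gene and transcript abundances from read-mapping counts.

Metagenomic (DNA) abundances of key metabolic genes are expressed relative
to the average read recruitment of a panel of single-copy COGs (by default
35 of them), which puts every sample on a per-genome-equivalent scale and
cancels library size.  Metatranscriptomic (RNA) abundances are expressed
relative to the total number of reads in the library.  In both assays, when
several ORFs share one annotation their read hits are averaged, so gene
copy number inside one sample does not inflate the signal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDenominatorError, ValidationError

__all__ = [
    "Assay",
    "Normalization",
    "ReadHitTable",
    "KeyGeneCatalog",
    "SingleCopyCOGSet",
    "AbundanceMatrix",
    "mean_hits_per_annotation",
    "normalize_gene_abundance_mg",
    "normalize_transcript_abundance",
    "build_abundance_matrix",
]


class Assay(str, enum.Enum):
    METAGENOME = "METAGENOME"
    METATRANSCRIPTOME = "METATRANSCRIPTOME"


class Normalization(str, enum.Enum):
    SCG_MEAN = "SCG_MEAN"        # single-copy-COG mean recruitment
    TOTAL_READS = "TOTAL_READS"  # library size


@dataclass
class ReadHitTable:
    """Per-ORF mapped-read counts for one sample.

    ``total_reads`` is the library size, not the sum of hits (most reads map
    to ORFs outside any catalog, or nowhere).
    """

    sample_id: str
    df: pd.DataFrame  # columns: orf_id, annotation_id, hits
    total_reads: int
    assay: Assay

    REQUIRED = ("orf_id", "annotation_id", "hits")

    def __post_init__(self):
        self.assay = Assay(self.assay)
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(
                f"read-hit table {self.sample_id!r} missing columns: {missing}")
        if (self.df["hits"] < 0).any():
            raise ValidationError(
                f"negative hit counts in sample {self.sample_id!r}")
        if self.total_reads <= 0:
            raise ValidationError(
                f"sample {self.sample_id!r} has non-positive total_reads")


@dataclass
class KeyGeneCatalog:
    """Functional catalog: category -> gene -> KO list.

    ``entries`` rows: (category, gene_name, ko_ids).  Gene names are unique
    across the whole catalog.
    """

    entries: pd.DataFrame  # columns: category, gene_name, ko_ids (list[str])

    def __post_init__(self):
        missing = [c for c in ("category", "gene_name", "ko_ids")
                   if c not in self.entries.columns]
        if missing:
            raise ValidationError(f"catalog missing columns: {missing}")
        dupes = self.entries["gene_name"][self.entries["gene_name"].duplicated()]
        if len(dupes):
            raise ValidationError(f"duplicate gene names: {sorted(set(dupes))}")
        if (self.entries["ko_ids"].map(len) == 0).any():
            raise ValidationError("catalog gene with empty KO list")

    def ordered(self) -> pd.DataFrame:
        """Entries sorted by category then gene name (display order)."""
        return self.entries.sort_values(
            ["category", "gene_name"], kind="stable").reset_index(drop=True)


@dataclass
class SingleCopyCOGSet:
    """The normalization panel of single-copy COGs (35 by default)."""

    cog_ids: tuple
    expected_size: int = 35

    def __post_init__(self):
        self.cog_ids = tuple(self.cog_ids)
        if len(set(self.cog_ids)) != len(self.cog_ids):
            raise ValidationError("duplicate COG ids in single-copy set")
        if self.expected_size is not None and len(self.cog_ids) != self.expected_size:
            raise ValidationError(
                f"single-copy COG set has {len(self.cog_ids)} ids, "
                f"expected {self.expected_size}")


@dataclass
class AbundanceMatrix:
    """Entity (gene or MAG) x sample normalized abundances."""

    df: pd.DataFrame  # index: entity ids, columns: sample ids
    assay: Assay
    normalization: Normalization

    def __post_init__(self):
        self.assay = Assay(self.assay)
        self.normalization = Normalization(self.normalization)
        vals = self.df.to_numpy(dtype=float)
        if vals.size and (not np.isfinite(vals).all() or vals.min() < 0):
            raise ValidationError("abundances must be finite and non-negative")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)


# ---------------------------------------------------------------------------
# Scalar operations
# ---------------------------------------------------------------------------

def mean_hits_per_annotation(table: ReadHitTable, annotation_id: str) -> float:
    """Mean read hits over all ORFs carrying ``annotation_id`` (0 if none).

    ORFs with zero hits are real observations and count toward the mean.
    """
    sub = table.df.loc[table.df["annotation_id"] == annotation_id, "hits"]
    return float(sub.mean()) if len(sub) else 0.0


def _mean_gene_hits(table: ReadHitTable, ko_ids: Sequence[str]) -> float:
    """A key gene may map to several KOs (e.g. hydrogenase subfamilies);
    its signal is the mean of the per-KO means, mirroring the
    same-annotation averaging rule."""
    if not ko_ids:
        raise ValidationError("empty KO list for key gene")
    return float(np.mean([mean_hits_per_annotation(table, ko) for ko in ko_ids]))


def scg_mean_hits(table: ReadHitTable, scg: SingleCopyCOGSet) -> float:
    """Average, over the single-copy COG panel, of each COG's mean hits."""
    return float(np.mean([mean_hits_per_annotation(table, c)
                          for c in scg.cog_ids]))


def normalize_gene_abundance_mg(table: ReadHitTable, ko_ids: Sequence[str],
                                scg: SingleCopyCOGSet) -> float:
    """Metagenomic key-gene abundance: gene mean hits / SCG-panel mean hits.

    Raises
    ------
    DegenerateDenominatorError
        If every single-copy COG has zero hits in the sample.
    """
    if table.assay is not Assay.METAGENOME:
        raise ValidationError("SCG normalization applies to metagenomes only")
    denom = scg_mean_hits(table, scg)
    if denom == 0.0:
        raise DegenerateDenominatorError(
            f"all single-copy COG hit counts are zero in sample "
            f"{table.sample_id!r}")
    return _mean_gene_hits(table, ko_ids) / denom


def normalize_transcript_abundance(table: ReadHitTable, ko_ids: Sequence[str],
                                   scale: float = 1.0) -> float:
    """Metatranscriptomic key-gene abundance: gene mean hits / total reads.

    ``scale`` is a cosmetic display factor (e.g. 1e6 for hits-per-million);
    the default keeps the raw ratio.
    """
    if table.assay is not Assay.METATRANSCRIPTOME:
        raise ValidationError(
            "library-size normalization applies to metatranscriptomes only")
    if table.total_reads <= 0:
        raise DegenerateDenominatorError(
            f"sample {table.sample_id!r} has no reads")
    return _mean_gene_hits(table, ko_ids) / table.total_reads * scale


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------

def build_abundance_matrix(tables: Sequence[ReadHitTable],
                           catalog: KeyGeneCatalog,
                           scg: SingleCopyCOGSet | None = None,
                           scale: float = 1.0) -> AbundanceMatrix:
    """Assemble the gene x sample abundance matrix for one assay.

    All tables must share one assay; the assay picks the normalization
    (metagenome: SCG mean; metatranscriptome: total reads).  Genes are
    ordered by catalog category then name; samples keep input order.
    """
    if not tables:
        raise ValidationError("no read-hit tables given")
    assays = {t.assay for t in tables}
    if len(assays) > 1:
        raise ValidationError(f"mixed assays in one matrix: {sorted(a.value for a in assays)}")
    assay = tables[0].assay
    if assay is Assay.METAGENOME and scg is None:
        raise ValidationError("metagenome normalization needs a single-copy COG set")

    entries = catalog.ordered()
    values = np.zeros((len(entries), len(tables)))
    for j, table in enumerate(tables):
        for i, row in entries.iterrows():
            if assay is Assay.METAGENOME:
                values[i, j] = normalize_gene_abundance_mg(table, row["ko_ids"], scg)
            else:
                values[i, j] = normalize_transcript_abundance(
                    table, row["ko_ids"], scale=scale)
    df = pd.DataFrame(values, index=list(entries["gene_name"]),
                      columns=[t.sample_id for t in tables])
    norm = (Normalization.SCG_MEAN if assay is Assay.METAGENOME
            else Normalization.TOTAL_READS)
    return AbundanceMatrix(df, assay=assay, normalization=norm)
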