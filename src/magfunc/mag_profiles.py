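"""MAG filtering, coverage normalization, z-scoring and clustering.

Draft genomes binned from metagenomes only count as MAGs when their
single-copy-gene completeness exceeds 70% and redundancy stays below 10%
(strict inequalities); lineages judged to be seawater contaminants —
by default Pseudomonadales and Sphingomonadales — are dropped regardless of
quality.  Per-MAG mean coverage is normalized by library size, each MAG's
profile is z-scored across samples, and MAGs/samples are clustered with
Euclidean distance and Ward linkage, the combination used by seaborn's
clustermap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .abundance import AbundanceMatrix, Assay, Normalization
from .errors import ValidationError
from .kegg import KOAnnotationTable

__all__ = [
    "MagRecord",
    "CoverageMatrix",
    "ZScoreMatrix",
    "ClusterResult",
    "DEFAULT_EXCLUDED_ORDERS",
    "filter_mags",
    "normalize_mag_coverage",
    "zscore_rows",
    "cluster_rows",
    "reorder_like",
    "ko_presence_query",
]

DEFAULT_EXCLUDED_ORDERS = ("Pseudomonadales", "Sphingomonadales")


@dataclass(frozen=True)
class MagRecord:
    """Quality and taxonomy metadata for one genome bin."""

    mag_id: str
    taxonomy: tuple  # ordered rank labels, domain ... order
    completeness: float  # percent
    redundancy: float    # percent
    length_bp: int | None = None

    def __post_init__(self):
        if not (0 <= self.completeness <= 100):
            raise ValidationError(
                f"{self.mag_id}: completeness {self.completeness} outside [0, 100]")
        if not (0 <= self.redundancy <= 100):
            raise ValidationError(
                f"{self.mag_id}: redundancy {self.redundancy} outside [0, 100]")


@dataclass
class CoverageMatrix:
    """Mean per-base coverage of each MAG in each sample, plus library sizes."""

    df: pd.DataFrame  # index: mag ids, columns: sample ids
    sample_total_reads: pd.Series  # index: sample ids
    assay: Assay

    def __post_init__(self):
        self.assay = Assay(self.assay)
        vals = self.df.to_numpy(dtype=float)
        if vals.size and (not np.isfinite(vals).all() or vals.min() < 0):
            raise ValidationError("coverage must be finite and non-negative")
        missing = [s for s in self.df.columns if s not in self.sample_total_reads.index]
        if missing:
            raise ValidationError(f"samples without total read counts: {missing}")


@dataclass
class ZScoreMatrix:
    """Row-wise z-scores; constant rows are emitted as zeros and flagged."""

    df: pd.DataFrame
    constant_rows: tuple = ()


@dataclass
class ClusterResult:
    """Agglomerative clustering of one axis of a matrix.

    ``linkage`` is the scipy linkage matrix; ``ids`` are the clustered item
    labels in input order and ``leaf_order`` the dendrogram's left-to-right
    permutation of them.
    """

    ids: tuple
    leaf_order: tuple
    linkage: np.ndarray
    method: str = "ward"
    metric: str = "euclidean"

    def cut(self, k: int) -> dict[str, int]:
        """Flat partition into ``k`` clusters (1-based labels)."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.ids, (int(x) for x in labels)))

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height deltas
        (leaves sit at height 0, so a leaf's branch is its parent height)."""
        tree = hierarchy.to_tree(self.linkage)

        def recurse(node, parent_height):
            if node.is_leaf():
                length = parent_height if parent_height is not None else 0.0
                return f"{self.ids[node.id]}:{length:.6g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            length = (parent_height - node.dist) if parent_height is not None else 0.0
            return f"({left},{right}):{max(length, 0.0):.6g}"

        return recurse(tree, None) + ";"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def filter_mags(records: Sequence[MagRecord],
                min_completeness: float = 70.0,
                max_redundancy: float = 10.0,
                excluded_orders: Sequence[str] = DEFAULT_EXCLUDED_ORDERS,
                ) -> list[MagRecord]:
    """Keep bins with completeness > threshold and redundancy < threshold
    whose taxonomy contains no excluded order.  Boundary values fail the
    strict inequalities.  Input order is preserved; the operation is
    idempotent."""
    excluded = set(excluded_orders or ())
    return [r for r in records
            if r.completeness > min_completeness
            and r.redundancy < max_redundancy
            and not (excluded & set(r.taxonomy))]


def normalize_mag_coverage(cov: CoverageMatrix) -> AbundanceMatrix:
    """Divide each MAG's mean coverage by the sample's total read count."""
    totals = cov.sample_total_reads.reindex(cov.df.columns)
    zero = [s for s, t in totals.items() if not t > 0]
    if zero:
        raise ValidationError(f"zero/invalid total reads for samples: {zero}")
    df = cov.df.div(totals.astype(float), axis=1)
    return AbundanceMatrix(df, assay=cov.assay,
                           normalization=Normalization.TOTAL_READS)


def zscore_rows(matrix: AbundanceMatrix | pd.DataFrame) -> ZScoreMatrix:
    """Per-row z-transformation: (x - row mean) / row sample sd (ddof=1).

    Rows with zero variance are emitted as zeros and flagged so the matrix
    keeps its shape for plotting.  Requires at least two columns.
    """
    df = matrix.df if isinstance(matrix, AbundanceMatrix) else matrix
    if df.shape[1] < 2:
        raise ValidationError("z-scoring needs at least 2 columns")
    values = df.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd_safe = np.where(constant[:, None], 1.0, sd)
    z = (values - mean) / sd_safe
    z[constant, :] = 0.0
    out = pd.DataFrame(z, index=df.index, columns=df.columns)
    return ZScoreMatrix(out, constant_rows=tuple(df.index[constant]))


def cluster_rows(matrix: ZScoreMatrix | AbundanceMatrix | pd.DataFrame,
                 axis: str = "rows") -> ClusterResult:
    """Hierarchical clustering with Euclidean distance and Ward linkage.

    ``axis`` selects rows or columns.  Deterministic for a given input.
    """
    df = matrix.df if hasattr(matrix, "df") else matrix
    if axis == "columns":
        df = df.T
    elif axis != "rows":
        raise ValidationError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if df.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 items")
    dist = pdist(df.to_numpy(dtype=float), metric="euclidean")
    linkage = hierarchy.linkage(dist, method="ward")
    leaves = hierarchy.leaves_list(linkage)
    ids = tuple(df.index)
    return ClusterResult(ids=ids, leaf_order=tuple(ids[i] for i in leaves),
                         linkage=linkage)


def reorder_like(matrix: AbundanceMatrix | ZScoreMatrix,
                 row_order: Sequence[str] | None = None,
                 column_order: Sequence[str] | None = None):
    """Reorder a matrix to match another clustering's leaf orders.

    Used to display the DNA-coverage heatmap in the ordering obtained from
    clustering the transcript matrix.  Ids absent from the matrix raise.
    """
    df = matrix.df
    if row_order is not None:
        missing = [r for r in row_order if r not in df.index]
        if missing:
            raise ValidationError(f"row ids not in matrix: {missing}")
        df = df.loc[list(row_order)]
    if column_order is not None:
        missing = [c for c in column_order if c not in df.columns]
        if missing:
            raise ValidationError(f"column ids not in matrix: {missing}")
        df = df[list(column_order)]
    if isinstance(matrix, ZScoreMatrix):
        return ZScoreMatrix(df, constant_rows=matrix.constant_rows)
    return AbundanceMatrix(df, assay=matrix.assay,
                           normalization=matrix.normalization)


def ko_presence_query(annotations: KOAnnotationTable,
                      ko_ids: Sequence[str],
                      mag_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Presence/absence of marker KOs per MAG, with supporting ORF ids.

    Supports marker-gene audits such as locating mcrA (K00399) carriers or
    checking which genomes lack a nitrite reductase.  Returns one row per
    (mag_id, ko_id) with ``present`` and the sorted list of ORF ids.
    """
    ko_ids = [k.upper() for k in ko_ids]
    if mag_ids is None:
        mag_ids = annotations.mag_ids()
    sub = annotations.df[annotations.df["ko_id"].isin(ko_ids)]
    grouped = {(m, k): sorted(g["orf_id"])
               for (m, k), g in sub.groupby(["mag_id", "ko_id"])}
    rows = []
    for mag in mag_ids:
        for ko in ko_ids:
            orfs = grouped.get((mag, ko), [])
            rows.append({"mag_id": mag, "ko_id": ko,
                         "present": bool(orfs), "orf_ids": orfs})
    return pd.DataFrame(rows, columns=["mag_id", "ko_id", "present", "orf_ids"])
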