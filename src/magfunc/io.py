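"""Readers and writers for the package's interchange formats.

Policy: tolerant reader, strict writer.  Readers require the documented
columns (missing ones raise :class:`FormatError` with the file and, where
known, the line), warn on unknown extras, and accept any column order.
Writers emit UTF-8 TSVs with fixed column order and stable float formatting
so identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .abundance import (AbundanceMatrix, Assay, KeyGeneCatalog, Normalization,
                        ReadHitTable, SingleCopyCOGSet)
from .errors import FormatError
from .kegg import (KOAnnotationTable, MCSMatrix, ModuleDefinition,
                   parse_module_definition)
from .mag_profiles import CoverageMatrix, MagRecord

__all__ = [
    "read_annotations", "write_annotations",
    "read_module_definitions_tsv", "write_module_definitions_tsv",
    "read_module_definitions_flat",
    "read_mag_metadata", "write_mag_metadata",
    "read_coverage", "write_coverage",
    "read_sample_table", "write_sample_table",
    "read_read_hits", "write_read_hits",
    "read_key_gene_catalog", "write_key_gene_catalog",
    "read_scg_set", "write_scg_set",
    "read_matrix_tsv", "write_matrix_tsv",
    "read_grouping", "write_grouping",
    "write_newick", "write_leaf_order",
    "write_manifest", "read_manifest",
]

_FLOAT_FMT = "%.10g"


def _read_tsv(path, required: Sequence[str], dtype=None,
              optional: Sequence[str] = ()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=dtype)
    except FileNotFoundError:
        raise FormatError("file not found", path=path)
    except Exception as exc:  # malformed TSV
        raise FormatError(f"could not parse TSV: {exc}", path=path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns {missing}", path=path, line=1)
    extra = [c for c in df.columns if c not in required and c not in optional]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}")
    return df


def _check_no_missing(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    for col in cols:
        na = df[col].isna()
        if na.any():
            # +2: header line plus 1-based indexing
            line = int(np.flatnonzero(na)[0]) + 2
            raise FormatError(f"missing value in column {col!r}", path=path,
                              line=line)


# --- annotations -----------------------------------------------------------

def read_annotations(path) -> KOAnnotationTable:
    df = _read_tsv(path, KOAnnotationTable.REQUIRED, dtype=str)
    _check_no_missing(df, KOAnnotationTable.REQUIRED, path)
    return KOAnnotationTable(df[list(KOAnnotationTable.REQUIRED)])


def write_annotations(table: KOAnnotationTable, path) -> None:
    table.df[list(KOAnnotationTable.REQUIRED)].to_csv(path, sep="\t", index=False)


# --- module definitions ----------------------------------------------------

def read_module_definitions_tsv(path) -> list[ModuleDefinition]:
    df = _read_tsv(path, ("module_id", "definition"), dtype=str,
                   optional=("name",))
    _check_no_missing(df, ("module_id", "definition"), path)
    name_col = df["name"] if "name" in df.columns else [""] * len(df)
    return [parse_module_definition(m, d, name=n or "")
            for m, d, n in zip(df["module_id"], df["definition"], name_col)]


def write_module_definitions_tsv(modules: Sequence[ModuleDefinition], path) -> None:
    pd.DataFrame({
        "module_id": [m.module_id for m in modules],
        "name": [m.name for m in modules],
        "definition": [m.source_text.strip() for m in modules],
    }).to_csv(path, sep="\t", index=False)


def read_module_definitions_flat(path) -> list[ModuleDefinition]:
    """KEGG-flat-file-style reader: ENTRY / NAME / DEFINITION lines,
    records separated by ``///``.  Continuation lines (leading whitespace)
    extend the previous field."""
    modules = []
    entry = name = definition = None
    last_field = None

    def flush(line_no):
        nonlocal entry, name, definition, last_field
        if entry is None and definition is None:
            return
        if entry is None or definition is None:
            raise FormatError("record missing ENTRY or DEFINITION",
                              path=path, line=line_no)
        modules.append(parse_module_definition(entry, definition,
                                               name=name or ""))
        entry = name = definition = None
        last_field = None

    line_no = 0
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("///"):
                flush(line_no)
                continue
            if line[0].isspace():
                if last_field == "DEFINITION":
                    definition = (definition or "") + " " + line.strip()
                elif last_field == "NAME":
                    name = (name or "") + " " + line.strip()
                continue
            parts = line.split(None, 1)
            key = parts[0]
            value = parts[1].strip() if len(parts) > 1 else ""
            if key == "ENTRY":
                entry = value.split()[0] if value else ""
                last_field = "ENTRY"
            elif key == "NAME":
                name = value
                last_field = "NAME"
            elif key == "DEFINITION":
                definition = value
                last_field = "DEFINITION"
            else:
                last_field = None  # unknown fields are tolerated
        flush(line_no)
    return modules


# --- MAG metadata ----------------------------------------------------------

_MAG_COLS = ("mag_id", "domain", "phylum", "class", "order",
             "completeness", "redundancy", "length_bp")


def read_mag_metadata(path) -> list[MagRecord]:
    df = _read_tsv(path, _MAG_COLS)
    _check_no_missing(df, ("mag_id", "completeness", "redundancy"), path)
    records = []
    for _, row in df.iterrows():
        length = row["length_bp"]
        records.append(MagRecord(
            mag_id=str(row["mag_id"]),
            taxonomy=(str(row["domain"]), str(row["phylum"]),
                      str(row["class"]), str(row["order"])),
            completeness=float(row["completeness"]),
            redundancy=float(row["redundancy"]),
            length_bp=None if pd.isna(length) else int(length)))
    return records


def write_mag_metadata(records: Sequence[MagRecord], path) -> None:
    pd.DataFrame([{
        "mag_id": r.mag_id,
        "domain": r.taxonomy[0] if len(r.taxonomy) > 0 else "",
        "phylum": r.taxonomy[1] if len(r.taxonomy) > 1 else "",
        "class": r.taxonomy[2] if len(r.taxonomy) > 2 else "",
        "order": r.taxonomy[3] if len(r.taxonomy) > 3 else "",
        "completeness": r.completeness,
        "redundancy": r.redundancy,
        "length_bp": "" if r.length_bp is None else r.length_bp,
    } for r in records]).to_csv(path, sep="\t", index=False)


# --- samples (totals, site/field, assay) -----------------------------------

_SAMPLE_COLS = ("sample_id", "assay", "total_reads")


def read_sample_table(path) -> pd.DataFrame:
    df = _read_tsv(path, _SAMPLE_COLS, optional=("site", "field"))
    _check_no_missing(df, _SAMPLE_COLS, path)
    keep = [c for c in ("sample_id", "assay", "total_reads", "site", "field")
            if c in df.columns]
    df = df[keep].copy()
    df["total_reads"] = df["total_reads"].astype(int)
    return df


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# --- coverage matrices -----------------------------------------------------

def read_coverage(path, samples: pd.DataFrame, assay: Assay) -> CoverageMatrix:
    """Coverage TSV: ``mag_id`` column plus one column per sample; totals and
    assay come from the sample table."""
    assay = Assay(assay)
    df = pd.read_csv(path, sep="\t")
    if "mag_id" not in df.columns:
        raise FormatError("missing required columns ['mag_id']", path=path, line=1)
    df = df.set_index("mag_id")
    sub = samples[samples["assay"] == assay.value]
    totals = pd.Series(sub["total_reads"].to_numpy(),
                       index=sub["sample_id"].to_numpy(), name="total_reads")
    missing = [s for s in df.columns if s not in totals.index]
    if missing:
        raise FormatError(f"coverage samples missing from sample table: {missing}",
                          path=path)
    return CoverageMatrix(df.astype(float), totals.reindex(df.columns),
                          assay=assay)


def write_coverage(cov: CoverageMatrix, path) -> None:
    cov.df.rename_axis("mag_id").to_csv(path, sep="\t",
                                        float_format=_FLOAT_FMT)


# --- read hits -------------------------------------------------------------

_HIT_COLS = ("sample_id", "orf_id", "annotation_id", "hits")


def read_read_hits(path, samples: pd.DataFrame) -> list[ReadHitTable]:
    """Long-form hit table covering one or more samples of one assay."""
    df = _read_tsv(path, _HIT_COLS)
    _check_no_missing(df, _HIT_COLS, path)
    meta = samples.set_index("sample_id")
    tables = []
    for sample_id, sub in df.groupby("sample_id", sort=False):
        if sample_id not in meta.index:
            raise FormatError(f"sample {sample_id!r} missing from sample table",
                              path=path)
        tables.append(ReadHitTable(
            sample_id=str(sample_id),
            df=sub[["orf_id", "annotation_id", "hits"]].reset_index(drop=True),
            total_reads=int(meta.loc[sample_id, "total_reads"]),
            assay=Assay(meta.loc[sample_id, "assay"])))
    return tables


def write_read_hits(tables: Sequence[ReadHitTable], path) -> None:
    frames = []
    for t in tables:
        df = t.df[["orf_id", "annotation_id", "hits"]].copy()
        df.insert(0, "sample_id", t.sample_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# --- key genes and SCG panel ----------------------------------------------

def read_key_gene_catalog(path) -> KeyGeneCatalog:
    df = _read_tsv(path, ("category", "gene_name", "ko_ids"), dtype=str)
    _check_no_missing(df, ("category", "gene_name", "ko_ids"), path)
    df = df[["category", "gene_name", "ko_ids"]].copy()
    df["ko_ids"] = df["ko_ids"].map(
        lambda s: [k.strip().upper() for k in s.split(",") if k.strip()])
    return KeyGeneCatalog(df)


def write_key_gene_catalog(catalog: KeyGeneCatalog, path) -> None:
    df = catalog.entries.copy()
    df["ko_ids"] = df["ko_ids"].map(",".join)
    df.to_csv(path, sep="\t", index=False)


def read_scg_set(path, expected_size: int | None = None) -> SingleCopyCOGSet:
    df = _read_tsv(path, ("cog_id",), dtype=str)
    _check_no_missing(df, ("cog_id",), path)
    ids = tuple(df["cog_id"])
    return SingleCopyCOGSet(ids, expected_size=expected_size
                            if expected_size is not None else len(ids))


def write_scg_set(scg: SingleCopyCOGSet, path) -> None:
    pd.DataFrame({"cog_id": list(scg.cog_ids)}).to_csv(path, sep="\t", index=False)


# --- generic matrices ------------------------------------------------------

def read_matrix_tsv(path, index_name: str = "id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("matrix needs an id column plus data columns",
                          path=path, line=1)
    return df.set_index(df.columns[0]).astype(float)


def write_matrix_tsv(df: pd.DataFrame, path, index_name: str = "id",
                     decimals: int | None = None, scale: float = 1.0) -> None:
    out = df * scale if scale != 1.0 else df
    fmt = f"%.{decimals}f" if decimals is not None else _FLOAT_FMT
    out.rename_axis(index_name).to_csv(path, sep="\t", float_format=fmt)


def write_mcs_matrix(mcs: MCSMatrix, path) -> None:
    """MAG x module completion scores, 4-decimal fixed point."""
    write_matrix_tsv(mcs.df, path, index_name="mag_id", decimals=4)


def read_mcs_matrix(path) -> MCSMatrix:
    return MCSMatrix(read_matrix_tsv(path, index_name="mag_id"))


# --- groupings -------------------------------------------------------------

def read_grouping(path):
    from .enrichment import MagGrouping
    df = _read_tsv(path, ("mag_id", "group"), dtype=str)
    _check_no_missing(df, ("mag_id", "group"), path)
    bad = sorted(set(df["group"]) - {"A", "B"})
    if bad:
        raise FormatError(f"group labels must be A or B, found {bad}", path=path)
    return MagGrouping(
        frozenset(df.loc[df["group"] == "A", "mag_id"]),
        frozenset(df.loc[df["group"] == "B", "mag_id"]),
        label=f"file:{Path(path).name}")


def write_grouping(grouping, path) -> None:
    rows = [{"mag_id": m, "group": "A"} for m in sorted(grouping.group_a)]
    rows += [{"mag_id": m, "group": "B"} for m in sorted(grouping.group_b)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- trees and manifests ---------------------------------------------------

def write_newick(cluster_result, path) -> None:
    Path(path).write_text(cluster_result.to_newick() + "\n", encoding="utf-8")


def write_leaf_order(cluster_result, path) -> None:
    Path(path).write_text("\n".join(cluster_result.leaf_order) + "\n",
                          encoding="utf-8")


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
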