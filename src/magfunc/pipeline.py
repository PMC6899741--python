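"""End-to-end orchestration: fixture bundle in, self-describing run out.

``run_pipeline`` executes the analysis sequence — filter MAGs, score module
completion, normalize gene/transcript abundances, profile MAG coverage
(normalize, z-score, cluster, reuse the transcript ordering for the DNA
heatmap), and test per-module enrichment between expression groups — and
writes every product plus a machine-readable manifest (config, input
checksums, package version, output checksums).  Runs are deterministic for
fixed inputs and seed: rerunning into a fresh directory reproduces
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .abundance import Assay, build_abundance_matrix
from .enrichment import (assign_expression_groups, enrich_modules,
                         results_to_frame)
from .errors import MagfuncError, ValidationError
from .kegg import compute_mcs_matrix
from .mag_profiles import (DEFAULT_EXCLUDED_ORDERS, cluster_rows, filter_mags,
                           normalize_mag_coverage, reorder_like, zscore_rows)
from .simulate import SyntheticDataset

__all__ = ["PipelineConfig", "write_bundle", "run_pipeline"]

BUNDLE_FILES = {
    "modules": "modules.tsv",
    "annotations": "annotations.tsv",
    "mag_metadata": "mag_metadata.tsv",
    "samples": "samples.tsv",
    "coverage_mg": "coverage_mg.tsv",
    "coverage_mt": "coverage_mt.tsv",
    "read_hits_mg": "read_hits_mg.tsv",
    "read_hits_mt": "read_hits_mt.tsv",
    "key_genes": "key_genes.tsv",
    "scg": "scg.tsv",
}


@dataclass
class PipelineConfig:
    """Run settings; the defaults reproduce the reference analysis choices
    (quality thresholds 70%/10%, seawater orders excluded, 35 single-copy
    COGs, Euclidean/Ward clustering, two-tailed Mann-Whitney)."""

    input_dir: str = "."
    min_completeness: float = 70.0
    max_redundancy: float = 10.0
    excluded_orders: tuple = DEFAULT_EXCLUDED_ORDERS
    n_scg: int = 35
    transcript_display_scale: float = 1e6
    clustering_metric: str = "euclidean"   # fixed; recorded for provenance
    clustering_linkage: str = "ward"
    enrichment_partition: str = "by_field"
    enrichment_focal: str = "Piccard"
    enrichment_alpha: float = 0.05
    enrichment_correction: str = "none"
    grouping_file: str | None = None       # bypasses expression grouping
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "excluded_orders" in data:
            data["excluded_orders"] = tuple(data["excluded_orders"])
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["excluded_orders"] = list(out["excluded_orders"])
        return out


def write_bundle(dataset: SyntheticDataset, outdir) -> Path:
    """Write a synthetic dataset as the full fixture bundle directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_module_definitions_tsv(dataset.modules, outdir / BUNDLE_FILES["modules"])
    mio.write_annotations(dataset.annotations, outdir / BUNDLE_FILES["annotations"])
    mio.write_mag_metadata(dataset.mag_records, outdir / BUNDLE_FILES["mag_metadata"])
    samples = _sample_table(dataset)
    mio.write_sample_table(samples, outdir / BUNDLE_FILES["samples"])
    mio.write_coverage(dataset.coverage_mg, outdir / BUNDLE_FILES["coverage_mg"])
    mio.write_coverage(dataset.coverage_mt, outdir / BUNDLE_FILES["coverage_mt"])
    mio.write_read_hits(dataset.read_hits_mg, outdir / BUNDLE_FILES["read_hits_mg"])
    mio.write_read_hits(dataset.read_hits_mt, outdir / BUNDLE_FILES["read_hits_mt"])
    mio.write_key_gene_catalog(dataset.catalog, outdir / BUNDLE_FILES["key_genes"])
    mio.write_scg_set(dataset.scg, outdir / BUNDLE_FILES["scg"])
    (outdir / "ground_truth.json").write_text(
        json.dumps(dataset.truth.to_jsonable(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return outdir


def _sample_table(dataset: SyntheticDataset) -> pd.DataFrame:
    truth = dataset.truth
    rows = []
    for cov, assay in ((dataset.coverage_mg, Assay.METAGENOME),
                       (dataset.coverage_mt, Assay.METATRANSCRIPTOME)):
        for s in cov.df.columns:
            rows.append({
                "sample_id": s, "assay": assay.value,
                "total_reads": int(cov.sample_total_reads[s]),
                "site": truth.sample_site.get(s, ""),
                "field": truth.site_field.get(truth.sample_site.get(s, ""), ""),
            })
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Stage:
    """Context that rewrites any failure with the stage name attached."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, Exception):
            raise MagfuncError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage on a bundle directory and write the run directory."""
    indir = Path(config.input_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {key: indir / name for key, name in BUNDLE_FILES.items()}
    for key, path in inputs.items():
        if not path.exists():
            raise ValidationError(f"missing input file for {key!r}: {path}")

    outputs: dict[str, Path] = {}

    def emit(name: str) -> Path:
        outputs[name] = outdir / name
        return outputs[name]

    with _Stage("read-inputs"):
        modules = mio.read_module_definitions_tsv(inputs["modules"])
        annotations = mio.read_annotations(inputs["annotations"])
        records = mio.read_mag_metadata(inputs["mag_metadata"])
        samples = mio.read_sample_table(inputs["samples"])
        cov_mg = mio.read_coverage(inputs["coverage_mg"], samples, Assay.METAGENOME)
        cov_mt = mio.read_coverage(inputs["coverage_mt"], samples,
                                   Assay.METATRANSCRIPTOME)
        hits_mg = mio.read_read_hits(inputs["read_hits_mg"], samples)
        hits_mt = mio.read_read_hits(inputs["read_hits_mt"], samples)
        catalog = mio.read_key_gene_catalog(inputs["key_genes"])
        scg = mio.read_scg_set(inputs["scg"], expected_size=config.n_scg)

    with _Stage("filter-mags"):
        mags = filter_mags(records, config.min_completeness,
                           config.max_redundancy, config.excluded_orders)
        mag_ids = [r.mag_id for r in mags]
        mio.write_mag_metadata(mags, emit("mags_retained.tsv"))

    with _Stage("mcs"):
        kept = annotations.df[annotations.df["mag_id"].isin(mag_ids)]
        from .kegg import KOAnnotationTable
        mcs = compute_mcs_matrix(KOAnnotationTable(kept), modules,
                                 mag_ids=sorted(mag_ids))
        mio.write_mcs_matrix(mcs, emit("mcs_matrix.tsv"))

    with _Stage("gene-abundance"):
        gene_mg = build_abundance_matrix(hits_mg, catalog, scg=scg)
        gene_mt = build_abundance_matrix(hits_mt, catalog)
        mio.write_matrix_tsv(gene_mg.df, emit("gene_abundance_mg.tsv"),
                             index_name="gene_name")
        mio.write_matrix_tsv(gene_mt.df, emit("gene_abundance_mt.tsv"),
                             index_name="gene_name",
                             scale=config.transcript_display_scale)

    with _Stage("mag-profile"):
        keep_cov_mg = cov_mg.df.index.isin(mag_ids)
        keep_cov_mt = cov_mt.df.index.isin(mag_ids)
        from .mag_profiles import CoverageMatrix
        cov_mg = CoverageMatrix(cov_mg.df.loc[keep_cov_mg],
                                cov_mg.sample_total_reads, cov_mg.assay)
        cov_mt = CoverageMatrix(cov_mt.df.loc[keep_cov_mt],
                                cov_mt.sample_total_reads, cov_mt.assay)
        mag_mg = normalize_mag_coverage(cov_mg)
        mag_mt = normalize_mag_coverage(cov_mt)
        z_mt = zscore_rows(mag_mt)
        z_mg = zscore_rows(mag_mg)
        rows_mt = cluster_rows(z_mt, axis="rows")
        cols_mt = cluster_rows(z_mt, axis="columns")
        # DNA heatmap reuses the transcript clustering's row ordering
        z_mg_ordered = reorder_like(z_mg, row_order=rows_mt.leaf_order)
        mio.write_matrix_tsv(mag_mg.df, emit("mag_abundance_mg.tsv"),
                             index_name="mag_id")
        mio.write_matrix_tsv(mag_mt.df, emit("mag_abundance_mt.tsv"),
                             index_name="mag_id")
        mio.write_matrix_tsv(z_mt.df, emit("mag_zscore_mt.tsv"),
                             index_name="mag_id")
        mio.write_matrix_tsv(z_mg_ordered.df, emit("mag_zscore_mg.tsv"),
                             index_name="mag_id")
        mio.write_newick(rows_mt, emit("mag_dendrogram_mt.nwk"))
        mio.write_newick(cols_mt, emit("sample_dendrogram_mt.nwk"))
        mio.write_leaf_order(rows_mt, emit("mag_leaf_order_mt.txt"))
        mio.write_leaf_order(cols_mt, emit("sample_leaf_order_mt.txt"))

    with _Stage("enrich"):
        if config.grouping_file:
            grouping = mio.read_grouping(config.grouping_file)
        else:
            sample_to_site = dict(zip(samples["sample_id"], samples.get("site", "")))
            site_to_field = dict(zip(samples.get("site", ""), samples.get("field", "")))
            grouping = assign_expression_groups(
                mag_mt, sample_to_site, partition=config.enrichment_partition,
                focal=config.enrichment_focal, site_to_field=site_to_field)
        results = enrich_modules(mcs, grouping,
                                 alpha=config.enrichment_alpha,
                                 correction=config.enrichment_correction)
        frame = results_to_frame(results)
        frame.to_csv(emit("enrichment.tsv"), sep="\t", index=False,
                     float_format="%.6g")
        mio.write_grouping(grouping, emit("grouping.tsv"))

    with _Stage("manifest"):
        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "inputs": {k: _sha256(p) for k, p in sorted(inputs.items())},
            "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
            "package": "magfunc",
            "version": _package_version(),
            "enrichment_grouping": {
                "label": grouping.label,
                "n_a": len(grouping.group_a), "n_b": len(grouping.group_b),
                "excluded": sorted(grouping.excluded),
            },
        }
        mio.write_manifest(manifest, outdir / "manifest.json")
    return outdir


def _package_version() -> str:
    from . import __version__
    return __version__
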