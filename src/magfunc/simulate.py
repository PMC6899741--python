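"""Synthetic fixture generation with planted ground truth.

The generator emulates the study design this package analyses: a few dozen
quality-filtered MAGs profiled across 15 metagenomes and 10
metatranscriptomes from two vent fields, scored against 56 KEGG-style
metabolic modules.  Every stage plants a known truth —

* module definitions covering the whole DEFINITION grammar;
* per-(MAG, module) completion targets realized constructively from KO
  placements (infeasible targets are snapped to the nearest achievable
  value, and the snapped value is recorded as the truth);
* block-structured coverage: each MAG is expressed in one sample block
  (site-restricted expression), with a configurable fraction of MAGs whose
  DNA block differs from their RNA block;
* a planted completion-score shift between expression groups for a chosen
  set of "enriched" modules;
* a MAG metadata table with known numbers of quality-failing and
  excluded-order (seawater-contaminant) bins.

All randomness flows from one seed through named substreams, so identical
configurations reproduce byte-identical fixture files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .abundance import (Assay, KeyGeneCatalog, ReadHitTable, SingleCopyCOGSet)
from .errors import ValidationError
from .kegg import (And, Atom, KOAnnotationTable, ModuleDefinition, Optional,
                   Or, Wildcard, parse_module_definition)
from .mag_profiles import (DEFAULT_EXCLUDED_ORDERS, CoverageMatrix, MagRecord)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_module_definitions",
    "generate_mag_metadata",
    "generate_coverage",
    "generate_annotations",
    "generate_key_gene_catalog",
    "generate_scg_set",
    "generate_read_hits",
    "generate_dataset",
]

_DEFAULT_TAXONOMY = (
    ("Bacteria", "Campylobacterota", "Campylobacteria", "Campylobacterales"),
    ("Archaea", "Euryarchaeota", "Methanococci", "Methanococcales"),
    ("Archaea", "Euryarchaeota", "Methanomicrobia", "Methanomicrobiales"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Thiotrichales"),
    ("Bacteria", "Aquificota", "Aquificae", "Aquificales"),
    ("Archaea", "Euryarchaeota", "Archaeoglobi", "Archaeoglobales"),
    ("Archaea", "Euryarchaeota", "Thermococci", "Thermococcales"),
    ("Bacteria", "Desulfobacterota", "Desulfobacteria", "Desulfobacterales"),
)

# named substreams off the master seed
_STREAMS = {"modules": 0, "metadata": 1, "blocks": 2, "coverage": 3,
            "annotations": 4, "read_hits": 5}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_mags: int = 64
    n_mg_samples: int = 15
    n_mt_samples: int = 10
    n_modules: int = 56
    n_groups: int = 3
    seed: int = 0
    noise_cv: float = 0.25        # lognormal CV of coverage noise
    planted_shift: float = 0.6    # between-group MCS difference
    n_enriched_modules: int = 6
    separation: float = 10.0      # in-block vs out-of-block coverage ratio
    base_coverage: float = 50.0
    decoupled_fraction: float = 0.2  # MAGs whose DNA block != RNA block
    n_excluded_order: int = 9
    n_quality_fail: int = 0
    taxonomy_labels: tuple = _DEFAULT_TAXONOMY
    excluded_orders: tuple = DEFAULT_EXCLUDED_ORDERS
    n_scg: int = 35

    def __post_init__(self):
        for name in ("n_mags", "n_mg_samples", "n_mt_samples", "n_modules",
                     "n_groups"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.n_groups > self.n_mt_samples:
            raise ValidationError("n_groups cannot exceed n_mt_samples")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """Planted truth recorded alongside every generated fixture."""

    planted_mcs: pd.DataFrame | None = None      # realized (snapped) targets
    requested_mcs: pd.DataFrame | None = None    # targets before snapping
    mag_mt_block: dict = field(default_factory=dict)
    mag_mg_block: dict = field(default_factory=dict)
    mt_sample_block: dict = field(default_factory=dict)
    mg_sample_block: dict = field(default_factory=dict)
    sample_site: dict = field(default_factory=dict)
    site_field: dict = field(default_factory=dict)
    decoupled_mags: list = field(default_factory=list)
    enriched_modules: list = field(default_factory=list)
    group_a: list = field(default_factory=list)
    group_b: list = field(default_factory=list)
    excluded_order_mags: list = field(default_factory=list)
    quality_fail_mags: list = field(default_factory=list)
    planted_gene_abundance_mg: pd.DataFrame | None = None
    planted_gene_abundance_mt: pd.DataFrame | None = None

    def to_jsonable(self) -> dict:
        out = {}
        for key, val in asdict(self).items():
            if isinstance(val, pd.DataFrame):
                val = getattr(self, key)
                out[key] = {"index": list(val.index),
                            "columns": list(val.columns),
                            "values": val.to_numpy().tolist()}
            else:
                out[key] = val
        return out

    @classmethod
    def from_jsonable(cls, data: dict) -> "GroundTruth":
        kwargs = {}
        for key, val in data.items():
            if isinstance(val, dict) and set(val) == {"index", "columns", "values"}:
                kwargs[key] = pd.DataFrame(val["values"], index=val["index"],
                                           columns=val["columns"])
            else:
                kwargs[key] = val
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Module definitions
# ---------------------------------------------------------------------------

class _KOFactory:
    """Sequential synthetic KO ids in the reserved K9xxxx range so generated
    modules never collide with real KOs (or each other)."""

    def __init__(self, start: int = 90000):
        self.counter = start

    def __call__(self) -> str:
        if self.counter > 99999:
            raise ValidationError("synthetic KO id range exhausted")
        ko = f"K{self.counter:05d}"
        self.counter += 1
        return ko


def _definition_text(kind: int, rng: np.random.Generator, ko: _KOFactory) -> str:
    """One definition string per grammar class; atoms are globally unique."""
    if kind == 0:       # plain serial steps
        n = int(rng.integers(3, 7))
        return " ".join(ko() for _ in range(n))
    if kind == 1:       # alternative slots
        steps = []
        for _ in range(int(rng.integers(3, 6))):
            if rng.random() < 0.6:
                steps.append(f"({ko()},{ko()})")
            else:
                steps.append(ko())
        return " ".join(steps)
    if kind == 2:       # enzyme complex + chain
        n = int(rng.integers(2, 5))
        complex_ = "+".join(ko() for _ in range(n))
        tail = " ".join(ko() for _ in range(int(rng.integers(1, 4))))
        return f"{complex_} {tail}"
    if kind == 3:       # nested grouping
        return f"(({ko()} {ko()}),{ko()}) {ko()} ({ko()},{ko()}+{ko()})"
    if kind == 4:       # optional components
        return f"{ko()}+{ko()}-{ko()} {ko()} -{ko()}"
    if kind == 5:       # unspecified component as its own step
        return f"{ko()} -- {ko()} {ko()}"
    # kind 6: mixed operators
    return f"({ko()}+{ko()},{ko()}+{ko()}) ({ko()},{ko()}) {ko()}-{ko()}"


def generate_module_definitions(config: SimulationConfig) -> list[ModuleDefinition]:
    """Seeded, grammar-covering corpus of parsed module definitions."""
    rng = config.rng("modules")
    ko = _KOFactory()
    modules = []
    for i in range(config.n_modules):
        text = _definition_text(i % 7, rng, ko)
        modules.append(parse_module_definition(
            f"M9{i:04d}", text, name=f"synthetic module {i}"))
    return modules


# ---------------------------------------------------------------------------
# MAG metadata
# ---------------------------------------------------------------------------

def generate_mag_metadata(config: SimulationConfig
                          ) -> tuple[list[MagRecord], GroundTruth]:
    """Passing MAGs plus configurable excluded-order and quality-fail bins."""
    rng = config.rng("metadata")
    records: list[MagRecord] = []
    idx = 0
    for _ in range(config.n_mags):
        idx += 1
        tax = config.taxonomy_labels[(idx - 1) % len(config.taxonomy_labels)]
        records.append(MagRecord(
            mag_id=f"MAG_{idx:03d}", taxonomy=tuple(tax),
            completeness=round(float(rng.uniform(70.5, 100.0)), 2),
            redundancy=round(float(rng.uniform(0.0, 9.5)), 2),
            length_bp=int(rng.integers(600_000, 6_000_000))))
    excluded_ids, fail_ids = [], []
    for j in range(config.n_excluded_order):
        idx += 1
        order = config.excluded_orders[j % len(config.excluded_orders)]
        records.append(MagRecord(
            mag_id=f"MAG_{idx:03d}",
            taxonomy=("Bacteria", "Proteobacteria", "Gammaproteobacteria", order),
            completeness=round(float(rng.uniform(70.5, 100.0)), 2),
            redundancy=round(float(rng.uniform(0.0, 9.5)), 2),
            length_bp=int(rng.integers(600_000, 6_000_000))))
        excluded_ids.append(f"MAG_{idx:03d}")
    for _ in range(config.n_quality_fail):
        idx += 1
        tax = config.taxonomy_labels[(idx - 1) % len(config.taxonomy_labels)]
        if rng.random() < 0.5:
            comp, red = float(rng.uniform(20.0, 70.0)), float(rng.uniform(0.0, 9.5))
        else:
            comp, red = float(rng.uniform(70.5, 100.0)), float(rng.uniform(10.0, 30.0))
        records.append(MagRecord(
            mag_id=f"MAG_{idx:03d}", taxonomy=tuple(tax),
            completeness=round(comp, 2), redundancy=round(red, 2),
            length_bp=int(rng.integers(600_000, 6_000_000))))
        fail_ids.append(f"MAG_{idx:03d}")
    order_perm = rng.permutation(len(records))
    records = [records[i] for i in order_perm]
    truth = GroundTruth(excluded_order_mags=excluded_ids,
                        quality_fail_mags=fail_ids)
    return records, truth


def passing_mag_ids(config: SimulationConfig) -> list[str]:
    """Ids of the quality-passing, non-excluded MAGs (fixed naming scheme)."""
    return [f"MAG_{i:03d}" for i in range(1, config.n_mags + 1)]


# ---------------------------------------------------------------------------
# Block structure (shared by coverage and annotations)
# ---------------------------------------------------------------------------

def derive_blocks(config: SimulationConfig) -> GroundTruth:
    """Planted block memberships of MAGs and samples, plus site/field maps."""
    rng = config.rng("blocks")
    k = config.n_groups
    mags = passing_mag_ids(config)
    mt_samples = [f"MT_{i:02d}" for i in range(1, config.n_mt_samples + 1)]
    mg_samples = [f"MG_{i:02d}" for i in range(1, config.n_mg_samples + 1)]
    mt_blocks = {s: (i * k) // len(mt_samples) for i, s in enumerate(mt_samples)}
    mg_blocks = {s: (i * k) // len(mg_samples) for i, s in enumerate(mg_samples)}
    assignment = np.array([i % k for i in range(len(mags))])
    rng.shuffle(assignment)
    mag_mt = {m: int(b) for m, b in zip(mags, assignment)}
    n_dec = math.ceil(config.decoupled_fraction * len(mags))
    decoupled = sorted(rng.choice(len(mags), size=n_dec, replace=False).tolist())
    mag_mg = dict(mag_mt)
    for i in decoupled:
        mag_mg[mags[i]] = (mag_mt[mags[i]] + 1) % k
    sample_site = {s: f"Site{b + 1}" for s, b in {**mt_blocks, **mg_blocks}.items()}
    site_field = {f"Site{b + 1}": ("Piccard" if b == 0 else "VonDamm")
                  for b in range(k)}
    group_a = sorted(m for m in mags if mag_mt[m] == 0)
    group_b = sorted(m for m in mags if mag_mt[m] != 0)
    return GroundTruth(mag_mt_block=mag_mt, mag_mg_block=mag_mg,
                       mt_sample_block=mt_blocks, mg_sample_block=mg_blocks,
                       sample_site=sample_site, site_field=site_field,
                       decoupled_mags=[mags[i] for i in decoupled],
                       group_a=group_a, group_b=group_b)


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def _noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Mean-preserving multiplicative lognormal noise; exactly 1 at cv=0."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=shape)


def generate_coverage(config: SimulationConfig,
                      blocks: GroundTruth | None = None
                      ) -> tuple[CoverageMatrix, CoverageMatrix, GroundTruth]:
    """Block-model MAG coverage for both assays.

    Coverage is high (``base_coverage``) inside a MAG's block and
    ``separation`` times lower outside, with lognormal noise of coefficient
    of variation ``noise_cv``.
    """
    truth = blocks if blocks is not None else derive_blocks(config)
    rng = config.rng("coverage")
    mags = passing_mag_ids(config)
    lo = config.base_coverage / config.separation

    def build(sample_block: dict, mag_block: dict) -> pd.DataFrame:
        samples = list(sample_block)
        means = np.full((len(mags), len(samples)), lo)
        for i, m in enumerate(mags):
            for j, s in enumerate(samples):
                if mag_block[m] == sample_block[s]:
                    means[i, j] = config.base_coverage
        return pd.DataFrame(means * _noise(rng, config.noise_cv, means.shape),
                            index=mags, columns=samples)

    mg_df = build(truth.mg_sample_block, truth.mag_mg_block)
    mt_df = build(truth.mt_sample_block, truth.mag_mt_block)
    # library sizes span 3x so block contrast (separation, default 10x)
    # dominates normalization and planted expression maxima stay unambiguous
    mg_totals = pd.Series(
        rng.integers(10, 31, size=mg_df.shape[1]) * 1_000_000,
        index=mg_df.columns, name="total_reads")
    mt_totals = pd.Series(
        rng.integers(10, 31, size=mt_df.shape[1]) * 1_000_000,
        index=mt_df.columns, name="total_reads")
    mg = CoverageMatrix(mg_df, mg_totals, assay=Assay.METAGENOME)
    mt = CoverageMatrix(mt_df, mt_totals, assay=Assay.METATRANSCRIPTOME)
    return mg, mt, truth


# ---------------------------------------------------------------------------
# Constructive KO placement for planted completion scores
# ---------------------------------------------------------------------------

def _zero_weight(node) -> bool:
    if isinstance(node, Optional):
        return True
    if isinstance(node, (And, Or)):
        return all(_zero_weight(c) for c in node.children)
    return False


def _resolved_atoms(node, w: float) -> tuple[float, list[tuple[str, float]]]:
    """Resolve every OR to its first branch and return (wildcard weight,
    [(ko, weight)]) with structured weights summing to ``w``."""
    if isinstance(node, Atom):
        return 0.0, [(node.ko, w)]
    if isinstance(node, Wildcard):
        return w, []
    if isinstance(node, Optional):
        return 0.0, []
    if isinstance(node, Or):
        for child in node.children:
            if not _zero_weight(child):
                return _resolved_atoms(child, w)
        return 0.0, []
    if isinstance(node, And):
        eff = [c for c in node.children if not _zero_weight(c)]
        wild, atoms = 0.0, []
        for child in eff:
            cw, ca = _resolved_atoms(child, w / len(eff))
            wild += cw
            atoms.extend(ca)
        return wild, atoms
    raise TypeError(f"unknown node {node!r}")


def plant_kos(module: ModuleDefinition, target: float
              ) -> tuple[set[str], float]:
    """Choose a KO set whose completion score approximates ``target``.

    Fills whole steps first, then partially fills one step by greedily
    adding its heaviest components.  Returns (KO set, realized score); the
    realized score is exact under the scorer as long as the module's KO ids
    are unique (the generated corpus guarantees this).
    """
    steps = [s for s in module.steps if not _zero_weight(s)]
    if not steps:
        return set(), 0.0
    resolved = [_resolved_atoms(s, 1.0) for s in steps]
    chosen: set[str] = set()
    step_scores = []
    remaining = target * len(steps)
    # baseline from wildcard-only weight
    for wild, atoms in resolved:
        remaining -= wild
    for wild, atoms in resolved:
        attainable = sum(w for _, w in atoms)
        if remaining >= attainable - 1e-9:
            chosen.update(k for k, _ in atoms)
            step_scores.append(wild + attainable)
            remaining -= attainable
        elif remaining > 1e-9:
            got = 0.0
            atoms_sorted = sorted(atoms, key=lambda kw: -kw[1])
            picked = []
            for k, w in atoms_sorted:
                if got + w <= remaining + 1e-9:
                    picked.append((k, w))
                    got += w
            # adding one more may land closer to the leftover target
            leftover = [kw for kw in atoms_sorted if kw not in picked]
            if leftover:
                k, w = max(leftover, key=lambda kw: kw[1])
                if abs(got + w - remaining) < abs(got - remaining):
                    picked.append((k, w))
                    got += w
            chosen.update(k for k, _ in picked)
            step_scores.append(wild + got)
            remaining -= got
        else:
            step_scores.append(wild)
    realized = float(np.mean(step_scores))
    return chosen, realized


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def generate_annotations(config: SimulationConfig,
                         modules: Sequence[ModuleDefinition],
                         blocks: GroundTruth | None = None
                         ) -> tuple[KOAnnotationTable, GroundTruth]:
    """KO annotation table realizing planted per-(MAG, module) targets.

    Modules chosen as "enriched" carry a planted completion shift between
    the two expression groups (group A, expressed in the focal block, draws
    targets around 0.9; group B around ``0.9 - planted_shift``); all other
    (MAG, module) pairs draw from a sparse baseline grid.  Realized
    (snapped) scores are recorded as the planted truth.
    """
    truth = blocks if blocks is not None else derive_blocks(config)
    rng = config.rng("annotations")
    mags = passing_mag_ids(config)
    group_a = set(truth.group_a)
    # enriched modules: prefer many-step modules (finer score granularity)
    ranked = sorted(modules, key=lambda m: -len(
        [s for s in m.steps if not _zero_weight(s)]))
    enriched = sorted(m.module_id
                      for m in ranked[:config.n_enriched_modules])
    grid = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    grid_p = np.array([0.30, 0.15, 0.20, 0.15, 0.20])

    requested = pd.DataFrame(0.0, index=mags,
                             columns=[m.module_id for m in modules])
    realized = requested.copy()
    rows = []
    for mag in mags:
        orf_counter = 0
        mag_kos: set[str] = set()
        for mod in modules:
            if mod.module_id in enriched:
                centre = 0.9 if mag in group_a else 0.9 - config.planted_shift
                target = float(np.clip(rng.normal(centre, 0.05), 0.0, 1.0))
            else:
                target = float(rng.choice(grid, p=grid_p))
            requested.loc[mag, mod.module_id] = target
            kos, score = plant_kos(mod, target)
            realized.loc[mag, mod.module_id] = score
            mag_kos.update(kos)
        for ko in sorted(mag_kos):
            orf_counter += 1
            rows.append((f"{mag}_orf{orf_counter:05d}", mag, ko))
    df = pd.DataFrame(rows, columns=["orf_id", "mag_id", "ko_id"])
    truth.planted_mcs = realized
    truth.requested_mcs = requested
    truth.enriched_modules = list(enriched)
    return KOAnnotationTable(df), truth


# ---------------------------------------------------------------------------
# Key genes, single-copy COGs, read hits
# ---------------------------------------------------------------------------

_CATEGORIES = ("sulphur", "methane", "hydrogen", "nitrogen", "oxygen", "iron")


def generate_key_gene_catalog(config: SimulationConfig) -> KeyGeneCatalog:
    """Synthetic key-gene catalog: 6 categories x 3 genes, 1-3 KOs each,
    in the reserved K8xxxx range."""
    counter = 80000
    rows = []
    for ci, cat in enumerate(_CATEGORIES):
        for gi in range(3):
            n_kos = 1 + (ci + gi) % 3
            kos = [f"K{counter + j:05d}" for j in range(n_kos)]
            counter += n_kos
            rows.append({"category": cat, "gene_name": f"{cat}_gene{gi + 1}",
                         "ko_ids": kos})
    return KeyGeneCatalog(pd.DataFrame(rows))


def generate_scg_set(config: SimulationConfig) -> SingleCopyCOGSet:
    """Synthetic single-copy COG panel (ids COG9001..)."""
    ids = tuple(f"COG9{i:03d}" for i in range(1, config.n_scg + 1))
    return SingleCopyCOGSet(ids, expected_size=config.n_scg)


def generate_read_hits(config: SimulationConfig,
                       catalog: KeyGeneCatalog | None = None,
                       scg: SingleCopyCOGSet | None = None,
                       mg_totals: pd.Series | None = None,
                       mt_totals: pd.Series | None = None
                       ) -> tuple[list[ReadHitTable], list[ReadHitTable], GroundTruth]:
    """Per-gene read-hit tables with exactly recoverable planted abundances.

    Metagenomes: planted SCG-relative abundances on a 0.25 grid; every SCG
    ORF receives the same per-sample baseline count so the planted ratio is
    exact.  Metatranscriptomes: planted hits-per-million on an integer grid
    with library sizes that are multiples of 1e6, so counts stay integral.

    ``mg_totals``/``mt_totals`` let callers reuse library sizes drawn
    elsewhere (e.g. by :func:`generate_coverage`) so each sample carries one
    total across all fixture files; they must be multiples of 1e6.
    """
    catalog = catalog if catalog is not None else generate_key_gene_catalog(config)
    scg = scg if scg is not None else generate_scg_set(config)
    rng = config.rng("read_hits")
    genes = catalog.ordered()
    truth = GroundTruth()
    mg_grid = np.arange(0, 17) * 0.25
    mg_p = np.concatenate([[0.2], np.full(16, 0.05)])

    mg_tables: list[ReadHitTable] = []
    mg_planted = {}
    for i in range(config.n_mg_samples):
        sample = f"MG_{i + 1:02d}"
        scale = int(rng.integers(1, 6))
        total = (int(mg_totals[sample]) if mg_totals is not None
                 else int(rng.integers(5, 51)) * 1_000_000)
        base = 400 * scale  # per-SCG hit count
        rows = [(f"{sample}_{cog}_orf", cog, base) for cog in scg.cog_ids]
        planted = {}
        for _, g in genes.iterrows():
            value = float(rng.choice(mg_grid, p=mg_p))
            planted[g["gene_name"]] = value
            for ko in g["ko_ids"]:
                rows.append((f"{sample}_{ko}_orf", ko, int(round(value * base))))
        mg_planted[sample] = planted
        df = pd.DataFrame(rows, columns=["orf_id", "annotation_id", "hits"])
        mg_tables.append(ReadHitTable(sample, df, total, Assay.METAGENOME))

    mt_tables: list[ReadHitTable] = []
    mt_planted = {}
    for i in range(config.n_mt_samples):
        sample = f"MT_{i + 1:02d}"
        total = (int(mt_totals[sample]) if mt_totals is not None
                 else int(rng.integers(5, 51)) * 1_000_000)
        rows = []
        planted = {}
        for _, g in genes.iterrows():
            hpm = int(rng.integers(0, 21))  # hits per million reads
            planted[g["gene_name"]] = hpm / 1e6
            for ko in g["ko_ids"]:
                rows.append((f"{sample}_{ko}_orf", ko, hpm * total // 1_000_000))
        mt_planted[sample] = planted
        df = pd.DataFrame(rows, columns=["orf_id", "annotation_id", "hits"])
        mt_tables.append(ReadHitTable(sample, df, total, Assay.METATRANSCRIPTOME))

    gene_names = list(genes["gene_name"])
    truth.planted_gene_abundance_mg = pd.DataFrame(
        {s: [mg_planted[s][g] for g in gene_names] for s in mg_planted},
        index=gene_names)
    truth.planted_gene_abundance_mt = pd.DataFrame(
        {s: [mt_planted[s][g] for g in gene_names] for s in mt_planted},
        index=gene_names)
    return mg_tables, mt_tables, truth


# ---------------------------------------------------------------------------
# Whole-dataset bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything one run of the pipeline consumes, plus the planted truth."""

    config: SimulationConfig
    modules: list
    mag_records: list
    annotations: KOAnnotationTable
    coverage_mg: CoverageMatrix
    coverage_mt: CoverageMatrix
    read_hits_mg: list
    read_hits_mt: list
    catalog: KeyGeneCatalog
    scg: SingleCopyCOGSet
    truth: GroundTruth


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a fully consistent fixture bundle from one configuration."""
    modules = generate_module_definitions(config)
    blocks = derive_blocks(config)
    records, meta_truth = generate_mag_metadata(config)
    cov_mg, cov_mt, blocks = generate_coverage(config, blocks)
    annotations, truth = generate_annotations(config, modules, blocks)
    catalog = generate_key_gene_catalog(config)
    scg = generate_scg_set(config)
    hits_mg, hits_mt, hits_truth = generate_read_hits(
        config, catalog, scg,
        mg_totals=cov_mg.sample_total_reads,
        mt_totals=cov_mt.sample_total_reads)
    truth.excluded_order_mags = meta_truth.excluded_order_mags
    truth.quality_fail_mags = meta_truth.quality_fail_mags
    truth.planted_gene_abundance_mg = hits_truth.planted_gene_abundance_mg
    truth.planted_gene_abundance_mt = hits_truth.planted_gene_abundance_mt
    return SyntheticDataset(
        config=config, modules=modules, mag_records=records,
        annotations=annotations, coverage_mg=cov_mg, coverage_mt=cov_mt,
        read_hits_mg=hits_mg, read_hits_mt=hits_mt,
        catalog=catalog, scg=scg, truth=truth)
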