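# Methods

This note documents the models and procedures magfunc implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not demonstrate.

## Module completion scoring

Module definitions follow the public KEGG DEFINITION conventions. The
parser is a small recursive-descent grammar with precedence (tightest to
loosest) `+`/`-`, then `,`, then space; parentheses override. Top-level
space-separated units are the reaction steps; spaces nested inside
parentheses contribute to their enclosing group's mean, not to the step
count. Parse errors (empty input, malformed KO tokens, unbalanced
parentheses) report the character offset. Trees serialize back to
canonical definition syntax, and `parse(serialize(parse(d)))` is
structurally identical to `parse(d)` — a property enforced by a
hypothesis test over randomly generated trees.

Scoring semantics and the reasoning behind them:

- **AND = mean** of its non-optional children. Completion is a
  proportion: a genome with half the subunits of a complex gets half
  credit. Each AND child carries equal weight, so a parenthesized group
  counts as one unit regardless of how many KOs it contains.
- **OR = max** over children. Alternatives are each sufficient; the
  genome's best-supported route determines the slot's completeness.
- **Optional (`-X`) components carry no weight**: they never appear in a
  numerator or denominator, so annotating or omitting them cannot change
  a score. KEGG marks these as non-essential.
- **`--` scores 1.** It denotes an enzyme that exists but cannot be
  specified; scoring it 0 would cap complete genomes below 1.
- A module absent from a genome scores 0, never missing: the MAG × module
  matrix is dense.
- KO identifiers are case-normalized; duplicate annotations on one ORF
  collapse under set semantics.

Two known limitations of the statistic itself: a score of 0.5 cannot
distinguish "half of every step" from "all of half the steps", and
pathways that share their full gene complement (methanogenesis vs
anaerobic methane oxidation) are indistinguishable at the module level —
resolving those requires marker-gene phylogenetics, which is out of
scope; `ko_presence_query` supports extracting the marker carriers
(e.g. mcrA, K00399).

The test suite checks the recursive scorer against an independent
brute-force oracle that enumerates every OR-branch assignment explicitly
and takes, per step, the best assignment's structured fraction of present
components, exhaustively over all KO subsets of every corpus module.
The two agree exactly; with a *pooled* (leaf-count) fraction instead of
the structured one they provably would not on nested mixed expressions,
which is why the oracle weights each AND child equally.

## Abundance normalization

- Same-annotation averaging: when several ORFs carry one annotation, hit
  counts are averaged, including zero-hit ORFs (they are observations).
- Metagenome scale: gene mean hits ÷ mean over the single-copy-COG panel
  of per-COG mean hits. We average per-COG means rather than pooling all
  SCG ORFs; with one ORF per COG (the expected single-copy case) the two
  coincide. The panel size defaults to 35 and is configurable.
- A key "gene" mapping to several KOs aggregates by averaging per-KO
  means, mirroring the same-annotation rule.
- Transcript scale: gene mean hits ÷ library size. A cosmetic display
  factor (default 10⁶ in the pipeline output, i.e. hits-per-million) can
  be applied at write time; matrices keep the raw ratio internally.
- Degenerate denominators (all-zero SCG panel, zero library size) raise
  typed errors rather than propagating NaN/Inf.

## MAG profiles

Bins qualify as MAGs when completeness > 70% and redundancy < 10% —
strict inequalities, boundary values fail — and their taxonomy contains
no excluded order (default: Pseudomonadales and Sphingomonadales,
treated as seawater admixture). Coverage is normalized by library size,
rows are z-scored with sample sd (n−1; a three-point row [1,2,3] maps to
[−1,0,1]); zero-variance rows are emitted as zeros and flagged so the
matrix keeps its shape for plotting. Clustering uses Euclidean distance
with Ward linkage via scipy; results are deterministic for a given input
(scipy's nearest-neighbor-chain order resolves exact cost ties; we do
not impose a bespoke tie rule). The transcript clustering's leaf order
can be applied to the DNA matrix (`reorder_like`) so both heatmaps share
one ordering. Dendrograms serialize to Newick with merge-height-delta
branch lengths.

## Enrichment

The Mann–Whitney implementation wraps scipy with a fixed policy chosen
to mirror R's `wilcox.test` defaults: exact enumeration when both groups
have ≤ 8 observations and the pooled values are untied; otherwise
midranks with the normal approximation, tie correction, and continuity
correction. The policy is recorded per result. Calibration and power are
verified against an independent enumeration oracle; note the normal
approximation only tracks the exact tail within 0.02 once both groups
have ≥ 5 observations — below that the discrete null is too coarse.

Expression grouping assigns each MAG to the site or vent field where its
summed normalized transcript abundance peaks (ties to the first label in
column order); all-zero MAGs are excluded and reported. Groupings can
instead be supplied as a TSV to bypass this rule. No multiple-testing
correction is applied by default; Benjamini–Hochberg is available.

## Synthetic data

The generator emulates the study design at its native scale — 64
quality-passing MAGs (plus, by default, 9 excluded-order bins, giving
the 73→64 filtering composition), 15 metagenomes, 10 metatranscriptomes,
56 modules — with planted truth at every stage:

- **Modules** cycle through seven grammar templates covering every
  operator class, with 2–12 synthetic KOs each, drawn from a reserved
  K9xxxx range and globally unique so scores never leak across modules.
  Wildcards appear only as standalone steps, which keeps the generator's
  constructive bookkeeping exact.
- **Completion targets** per (MAG, module) are realized by filling whole
  steps and then greedily part-filling one step along its first OR
  branch. Infeasible targets (e.g. 0.25 on a 3-step chain) are snapped
  to the nearest greedily achievable value and the snapped value is
  recorded as the truth — the generator never lies about its own output;
  the recorded matrix is recovered exactly by the scorer. Six
  many-step modules carry a planted between-group shift (0.9 vs
  0.9 − shift, sd 0.05, default shift 0.6) keyed to the expression
  groups.
- **Coverage** follows a block model: each MAG belongs to one sample
  block with coverage 50× inside and 5× outside (separation 10×),
  under mean-preserving multiplicative lognormal noise (cv 0.25 by
  default — a realistic spread for mapping-based coverage, which is
  positive and right-skewed). A configurable fraction (default 0.2) of
  MAGs have a DNA block differing from their RNA block, emulating
  populations that are abundant in one place but active in another.
  Library sizes are drawn as multiples of 10⁶ in 10–30 M so the block
  contrast dominates normalization.
- **Read hits** are constructed on exact grids (SCG-relative values in
  0.25 steps; transcript hits-per-million integers) so planted
  abundances are recovered to machine precision.
- All randomness flows from one seed through named substreams; identical
  configurations yield byte-identical fixture files.

What passing on these fixtures does *not* show: real annotation
pipelines miss and mislabel ORFs, real modules share KOs across modules,
real coverage is not block-structured nor lognormal, and incomplete
genome bins truncate KO sets in ways correlated with assembly quality.
The fixtures validate the arithmetic and the contracts, not robustness
to those upstream errors.

## Problem sizes and numerical choices

The default test suite exercises the full 64 × 56 scale for score
recovery; oracle-equivalence enumerates all ~5 000 KO subsets of the
corpus; rank-test calibration uses 2 000 null simulations (n = 8 + 8,
exact branch) and 200 power replicates (n = 10 + 10); clustering
recovery uses 100 seeds at 30 MAGs × 9 samples × 3 blocks, separation
10×, cv 0.1, scored by adjusted Rand index after cutting the tree at
k = 3. Score comparisons against the planted matrix use the 0.05
elementwise tolerance that the planting procedure guarantees;
normalization invariances are asserted at 1e-9; z-score identities at
1e-9. Ties in clustering merges and in grouping argmaxes resolve by
input order, making every pipeline product a pure function of the input
files and the seed.
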