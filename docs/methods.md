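# Methods

This note documents the models and procedures implemented in focuslib, the
parameters that matter, the synthetic fixtures the tests run on, and the
design choices made where the design was genuinely open.

## Transformation rules

A transformation rule is a single medicinal-chemistry rewrite encoded as
SMIRKS — a reactant-side SMARTS query and a product-side template joined by
`>>`, with atom-map classes (`:1`, `:2`, …) identifying which reactant atoms
persist into the product. Rules carry metadata used throughout the
workflow: the functional-group family they act on (`group`), a
transformation-type category (ring substitution / ring modification / ring
addition / linker modification / functional group change / addition /
removal / cyclization / other), semicolon-separated rationale tags
(bioisosteric replacement, metabolic stability, …), and a free-text
reference.

Parsing normalizes what printed rule tables actually contain: whitespace
inside the SMIRKS is insignificant and removed; a trailing ChemAxon
extension block (`|s:0:1|`, `|rb:…|`) encodes drawing/stereo hints, not
graph-rewriting semantics, and is stripped and stored as metadata. Product
atom maps with no reactant-side counterpart are treated as newly introduced
atoms (standard reaction-SMARTS semantics); `strict_mapping=True` turns them
into errors for users who want the stricter contract. Rules are interpreted
at the pH 7.4 protonation convention in which they were drawn — one rule in
the packaged set deliberately produces an ionized (thiazolidinedione anion)
product — and no additional protonation model is applied afterwards.

Application semantics are **single-site**: the reactant pattern is matched
at every site of the molecule and the rewrite applied once per match, so a
molecule with two phenyl rings yields (up to) two single-swap products,
never the double-swap. Multi-site chemistry emerges through iteration
instead, which keeps the combinatorics controlled and the provenance exact.
Products failing valence sanitization are counted and dropped; the
surviving products are deduplicated on the stereo-stripped canonical SMILES
and emitted in lexicographic key order, so rule application is
deterministic. The input molecule is never its own product.

Compendium audits (`validate_compendium`) classify every rule as
`parsed` / `parse-error` / `no-probe-match` / `produced-invalid-product`
by firing it at motif probes (auto-generated from the fixtures module when
not supplied) and report group/type histograms; malformed rows are retained
with their error, never silently dropped.

## Curation

Every structure entering or produced by the workflow passes a fixed-order
standardization cascade:

1. parse + sanitize (valence failures reject with reason `valence`,
   unparseable input with `parse`);
2. split multi-component records, keeping the largest component — most
   heavy atoms, ties broken by molecular weight then canonical SMILES;
3. reject structures containing elements outside
   {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I} (reason `element`);
4. neutralize (uncharger), then reionize — reionization only repositions
   charges between acidic sites, it does not re-deprotonate;
5. canonical tautomer via the deterministic rule-based canonicalizer of the
   underlying toolkit (the specific canonical form is a convention of that
   canonicalizer's version, recorded in the run manifest via the toolkit
   version);
6. stereo-stripped canonical SMILES as the deduplication key — dedup is
   deliberately stereo-blind, and duplicate resolution keeps the first-seen
   record to preserve input provenance.

Each record reports flags (`multi-component-split`, `neutralized`,
`tautomer-canonicalized`) and every rejection carries exactly one
first-failing reason. Curation is idempotent: re-curating a curated library
reproduces the same keys in the same order.

## Enumeration

`enumerate_library` expands a seed set through a compendium for
`n_iterations` rounds (default 2). Candidates produced in an iteration are
re-curated, then gated: **MW < 630 Da (strict)** and **40 ≤ TPSA ≤ 150 Å²
(inclusive)** by default — bounds chosen from the extreme property values of
known multi-target reference compounds, so enumeration stays inside the
property envelope of the compound class being emulated. Three frontier
rules control growth:

* gated-out products do not seed the next iteration;
* only molecules new to the accumulated library are expanded further
  (prevents rewrite cycles A → B → A from looping);
* seeds are excluded from the output by default (`include_seeds_in_output`).

Each product carries a provenance tag — seed id, ordered rule chain,
iteration born, with `len(rule_chain) == iteration_born` — and
`replay_provenance` re-derives any record from its seed as an audit. Output
ordering is `(iteration_born, canonical_key)`, making runs byte-identical.

## Drug-likeness and synthetic accessibility

**Descriptors.** The seven-descriptor profile (MW, logP, HBA, HBD, TPSA,
RotB, stereocenter count) uses the standard published definitions:
atomic-contribution logP, fragment-contribution TPSA, amide-excluded
rotatable bonds. Stereocenter counting includes unassigned potential
centers, since enumeration products are generated without stereochemistry.
Profiles are computed on the canonical-order structure so equal molecules
give bitwise-equal profiles.

**QED.** Drug-likeness is the weighted geometric mean of eight desirability
values, each an asymmetric double sigmoid
`d(x) = (a + b/(1+exp(-(x-c+d/2)/e)) · (1 - 1/(1+exp(-(x-c-d/2)/f)))) / d_max`
evaluated on MW, ALOGP, HBA, HBD, PSA, ROTB, aromatic-ring count, and
structural-alert count, with the published parameter and weight sets
(weights overridable). The conventional cutpoints quoted in reports — ≥ 0.67
attractive, 0.49–0.67 unattractive, < 0.49 too complex — come from the same
published parameterization. The implementation's transform + aggregation is
cross-checked in the test suite against the toolkit's independent QED
implementation to within ±0.01.

**SAScore.** Synthetic accessibility follows the original published
formulation: a per-atom fragment-commonness term (circular fragments of
radius ≤ 2, occurrence-weighted) minus complexity penalties —
`size = nAtoms^1.005 − nAtoms`, `stereo = log10(nStereo+1)`,
`spiro = log10(nSpiro+1)`, `bridge = log10(nBridgehead+1)` (together the
ring-complexity term), `macrocycle = log10(nMacrocycles+1)` for rings larger
than 8 — with the raw value mapped onto [1, 10] through the published fixed
window (raw −4…2.5 → 10…1, log-smoothed above 8). Later contrib-script
additions (the fingerprint-density "symmetry" correction and the constant
macrocycle term) are intentionally not included.

The packaged fragment table is **synthetic**: built by
`scripts/build_fragment_table.py` from the deterministic fixture corpus
(`fixtures.fragment_corpus(seed=0, n=300)`: property-steered decorated
scaffolds, the motif carriers, the two seed stand-ins, and a set of
reagent-scale building blocks). Scores follow the published frequency
procedure — log10 of a fragment's occurrence count relative to the fragment
at 80% cumulative coverage — then are rescaled linearly so the most common
fragment maps to +4, restoring the dynamic range the fixed [1, 10] window
presumes (the raw log-ratio spread shrinks with corpus size). All observed
fragments are kept (the corpus is curated, not sampled, so singletons are
signal); unknown fragments score −4. The table's provenance header is
stamped into every cascade report because near-threshold attrition counts
depend on it. Absolute values from this table differ from tables built on
large public catalogs; rank behavior on clearly-easy vs clearly-hard
molecules is verified against an independent reference implementation in
the tests. A user-supplied table (plain or gzipped key-value text) can be
passed to `sa_score` directly.

**Synthetic feasibility.** Retrosynthesis-based feasibility scores are
pluggable (`SynthScorer`, a callable returning [0, 1]); no default scorer is
shipped, and the corresponding cascade stage is skipped unless a threshold
and scorer are configured.

## Filter cascade

Stages run in a configurable order (default SAScore → synthetic feasibility
→ QED → alerts) with per-stage surviving counts, per-compound first-failing
stage, and alert-hit details. Threshold semantics are exact: SAScore ≤ 6
passes at the boundary, QED > 0.67 fails at the boundary, synthetic
feasibility > 0.5 is strict, alerts ≤ 0 by default. Alert catalogs are
explicit configuration — PAINS A+B+C plus a published unwanted-functionality
(reactive/toxicophore) set by default — and are stamped into the report.
Because the stages are independent predicates the final survivor set is
stage-order-invariant even though per-stage attrition is not; both
properties are tested.

## Chemical-space analysis

The "chemical multiverse" view compares the same libraries in several
descriptor spaces:

* **Property space.** Six pharmacologically motivated properties (HBD, HBA,
  logP, MW, RotB, TPSA), column-standardized to zero mean / unit variance
  before any embedding (constant columns are centered only). PCA reports
  explained-variance fractions and fixes signs so each component's
  largest-magnitude loading is positive, making embeddings reproducible and
  row-order-invariant. t-SNE (perplexity 30 by default, must be < n) takes a
  mandatory seed.
* **Fingerprint space.** Circular substructure fingerprints (radius 2,
  2048 bits, ECFP4-like) under Tanimoto distance, summarized as a minimum
  spanning tree. Up to 512 compounds the MST is computed exactly on the
  complete distance graph (the pairwise Tanimoto matrix is cheap at that
  size); larger collections use a k-nearest-neighbour graph (default k = 10)
  augmented with bridging edges to stay connected. The tree is laid out with
  a deterministic force-directed algorithm; the edge list is part of the
  output. The published tree-map algorithm (LSH forest) can be slotted in by
  callers, but the analytical content — a tree over fingerprint space — is
  what downstream comparisons use.
* **Shape space.** `n_conformers` (default 50) distance-geometry conformers
  per molecule under a fixed seed, force-field minimized (MMFF94, falling
  back to UFF where parameters are missing); the lowest-energy conformer's
  principal moments of inertia I1 ≤ I2 ≤ I3 give npr1 = I1/I3 and
  npr2 = I2/I3. npr2 is I2/I3 by the standard construction (ratios are
  otherwise degenerate with npr1), placing molecules in the rod (0,1) /
  disc (0.5, 0.5) / sphere (1,1) triangle with
  npr1 + npr2 ≥ 1 and npr1 ≤ npr2 as rigid-body constraints. Embedding
  failures are logged and skipped in batch mode.

Per-library summary tables (mean, median, quartiles, t-based 95% CI of the
mean — the statistics rain-cloud plots display) are exported as plain CSV;
plotting is left to the consumer, the tables are the contract.

## Synthetic fixtures: what they emulate and what they do not

The fixtures module stands in for external inputs so the full workflow runs
and is tested offline:

* `builtin_rules()` — a seven-rule compendium covering the published example
  rewrites (aminophenyl → bicyclopentyl, 1,4-diaminophenyl → diaminopyridazinyl,
  carboxyl → ionized thiazolidinedione, benzoylphenyl → phenyloxetanylphenyl,
  phenyl → cyclohexyl / propoxyiminomethyl / 2-oxopyridinyl), with the
  printed extension blocks and whitespace retained to exercise the parser.
* `make_seed_set` — deterministic carriers of the motifs those rules act on
  (carboxylic-acid, phenyl, amide, aminophenyl, benzoylphenyl,
  1,4-diaminophenyl), decorated with small substituents at seeded random
  C–H positions.
* `make_reference_library` — decorated-scaffold libraries whose MW/TPSA/logP
  means are steered toward targets by greedy selection from a seeded
  candidate pool (best effort, warning when a target is unreachable). These
  emulate reference collections (approved drugs, natural products,
  literature compounds) for chemical-space comparisons.
* `compound3_like` / `compound4_like` — thiazolidinedione-bearing aryl
  scaffolds standing in for two literature multi-target antihyperglycemic
  seeds whose structures are only depicted graphically; they are labeled
  stand-ins and real SMILES can be substituted wherever seeds are accepted.

What passing tests on these fixtures shows: the rule engine, curation,
enumeration bookkeeping, scoring formulas, cascade accounting, and embedding
machinery are correct and deterministic. What they do not show: behavior on
the scale (10⁴–10⁵ compounds) and structural diversity of real enumerated
libraries, real reference-set property distributions, or absolute SAScore
calibration against catalog-derived fragment tables — the
reference-data-dependent checks in `tests/test_acceptance.py` cover those
when the external collections are supplied.

## Numerical choices and degenerate inputs

* MW gate strict (<), TPSA gates inclusive (≤, ≥), matching the stated
  bounds literally; boundary tests pin both.
* Zero-substructure-match rule application returns the empty set, never an
  error; empty seed sets are an error.
* MST epsilon: zero Tanimoto distances (duplicate fingerprints) are offset
  by 1e-9 for the sparse-graph representation and restored to 0 in the
  reported edge weights, so duplicates join first.
* PCA requires ≥ 3 rows; t-SNE requires perplexity < n; tree embedding
  requires ≥ 2 compounds; shape profiling requires ≥ 2 heavy atoms and
  retries embedding with random coordinates before giving up.
* Desirability values are floored at 1e-6 before the geometric-mean log.
* Conformer energies come from the same force field that minimized them;
  comparisons across force-field fallbacks are not meaningful and only the
  per-molecule minimum is used.
* All stochastic stages (t-SNE, conformer embedding, fixture decoration)
  take explicit seeds; the pipeline manifest records them together with
  package versions and output checksums.

## Problem sizes used by the bundled analyses

The acceptance script and test suite run the workflow end to end at fixture
scale — a 7-rule compendium over ~14 seeds enumerating to ~10²
gate-passing products, 10–20-compound panels for scoring cross-checks, and
≤ 25-node instances where brute-force oracles (exhaustive rewriting,
complete-graph MSTs, eigendecompositions) verify the implementations.
These sizes were chosen so every oracle can be exact; the implementation
itself has no fixture-scale assumptions and the same entry points drive
catalog-scale runs.

## Known limitations

* The curated canonical tautomer (and hence dedup keys and counts) follows
  the toolkit's canonicalizer version; different versions can shift
  near-duplicate counts.
* SAScore absolute values depend on the fragment table's corpus; only
  threshold semantics and ranking are table-robust, which is why the table
  provenance is stamped into every report.
* Plain macrocycles illustrate a known weakness of frequency-based
  synthetic-accessibility scoring: ring-CH₂ environments are among the most
  common fragments anywhere, so the fragment term can outweigh the
  macrocycle penalty and rate large plain rings easier than their acyclic
  isomers.
* The tree map is an MST summary, not the published LSH-forest layout;
  topology (which compounds join which branch) is comparable, pixel-level
  geometry is not.
* No protonation/pKa model beyond the curation cascade's
  neutralize/reionize step; rules drawn for ionized species produce ionized
  products as drawn.
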