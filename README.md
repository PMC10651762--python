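# focuslib

Ligand-based design of **multi-target focused compound libraries**, built for
computational and medicinal chemists who want to expand the chemical space
around known multi-target hit compounds (e.g. antidiabetic leads acting on
PTP1B, aldose reductase, and PPAR isoforms) and triage the result down to a
drug-like, synthetically plausible screening set.

## What it does

The workflow chains five stages, each usable on its own:

1. **Transformation rules** (`focuslib.rules`) — medicinal-chemistry rewrites
   (bioisosteric replacements, ring modifications, linker changes) encoded as
   SMIRKS, `reactant_pattern >> product_template`, with atom maps tying the
   two sides together. Rule tables (TSV/CSV with columns
   `rule_id, group, name, transformation_type, smirks, notes, reference`) are
   loaded, audited against motif probes, and applied with single-site
   semantics: one rewrite per product, every matching site, products
   sanitized and deduplicated on a stereo-agnostic canonical SMILES.
   ChemAxon extension blocks (`|s:0:1|` …) found in printed rule tables are
   stripped and kept as metadata. A seven-rule example compendium ships with
   the package.
2. **Curation** (`focuslib.curation`) — the standardization cascade applied
   to every structure entering or leaving enumeration: parse → keep largest
   component → reject valence errors and elements outside
   {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I} → neutralize → reionize →
   canonical tautomer → stereo-stripped canonical SMILES as the dedup key.
3. **Enumeration** (`focuslib.enumeration`) — iterative expansion of seed
   compounds through the whole compendium (two iterations by default), with
   per-iteration property gates MW < 630 Da and 40 ≤ TPSA ≤ 150 Å². Every
   product carries provenance (seed, ordered rule chain, iteration born) and
   can be replayed from its seed.
4. **Filtering** (`focuslib.filtering`) — the medicinal-chemistry cascade
   with per-stage attrition reporting: SAScore ≤ 6 (inclusive), optional
   pluggable synthetic-feasibility score > 0.5, QED > 0.67 (strict), and zero
   structural alerts (PAINS A/B/C plus an unwanted-functionality catalog).
   QED is the weighted geometric mean of eight property desirabilities
   (asymmetric double sigmoids over MW, ALOGP, HBA, HBD, PSA, ROTB, aromatic
   rings, structural alerts); SAScore is the fragment-contribution synthetic
   accessibility score on the 1 (easy) – 10 (hard) scale,
   `sa = f(fragment commonness − size/stereo/spiro/bridge/macrocycle penalties)`.
5. **Chemical multiverse** (`focuslib.chemspace`) — the same libraries viewed
   in complementary descriptor spaces: PCA and t-SNE over the six-property
   space (HBD, HBA, logP, MW, RotB, TPSA, column-standardized), a
   minimum-spanning-tree "tree map" over ECFP4-like fingerprints under
   Tanimoto distance, and PMI shape profiling — normalized principal moments
   of inertia npr1 = I1/I3, npr2 = I2/I3 placing each lowest-energy conformer
   in the rod–disc–sphere triangle with vertices (0,1), (0.5,0.5), (1,1).

`focuslib.fixtures` generates deterministic motif-bearing seed molecules and
reference-library emulators so the whole workflow is testable offline, and
`focuslib run` orchestrates everything into a manifest-stamped run directory.

## Worked example

```bash
focuslib fixtures --motifs carboxylic-acid,phenyl,aminophenyl,benzoylphenyl \
    --n 2 --seed 1 --out seeds.smi
focuslib run --seeds seeds.smi --out-dir run_out --seed 1
```

prints the per-stage counts of the run:

```json
{
  "enumerated": 27,
  "filter_rejections": {"alerts": 4, "qed": 10, "sa": 0},
  "gate_rejections": 30,
  "pca_explained_variance": [0.4491932703085166, 0.25158415390637046],
  "rules": 7,
  "rules_parsed": 7,
  "seeds_curated": 8,
  "seeds_in": 8,
  "survivors": 13
}
```

Reading: the 8 curated seeds expanded to 27 unique gate-passing products in
two iterations (30 candidates fell to the MW/TPSA gates); the filter cascade
then removed 0 molecules on SAScore, 10 on QED and 4 on structural alerts,
leaving a 13-compound focused set. `run_out/` holds the library with
provenance (`library.csv`), per-compound descriptors and scores
(`profiles.csv`), the attrition report (`cascade_report.json`), chemical-space
coordinates, and a manifest with versions, seeds, and file checksums. The
first library rows show the provenance notation — for example
`Cc1ccc(C(=O)c2ccc(=O)n(O)c2)cc1` born in iteration 1 from seed
`benzoylphenyl-1` through rule `R007` (phenyl → 2-oxopyridin-1-yl).

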