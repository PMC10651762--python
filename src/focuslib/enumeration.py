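"""Iterative library enumeration with per-iteration property gates.

Seed compounds are expanded through a rule compendium for a configurable
number of iterations (two by default).  After each iteration, candidate
products must pass molecular-weight and TPSA gates (MW < 630 Da strict;
40 <= TPSA <= 150 A^2 inclusive — bounds taken from the extreme values of
the multi-target reference compounds) to enter the library and seed the next
round.  Every product carries a provenance tag: its seed, the ordered rule
chain that produced it, and the iteration in which it was born, so any
emitted structure can be replayed from its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .curation import MoleculeRecord, Rejection, standardize_record
from .molprops import compute_profile
from .rules import RuleCompendium, apply_rule

logger = logging.getLogger("focuslib.enumeration")


@dataclass(frozen=True)
class EnumerationConfig:
    n_iterations: int = 2
    mw_max: float = 630.0  # daltons, exclusive
    tpsa_min: float = 40.0  # A^2, inclusive
    tpsa_max: float = 150.0  # A^2, inclusive
    include_seeds_in_output: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.tpsa_min > self.tpsa_max:
            raise ValueError("tpsa_min must be <= tpsa_max")
        if self.mw_max <= 0:
            raise ValueError("mw_max must be positive")


@dataclass(frozen=True)
class ProvenanceTag:
    seed_id: str
    rule_chain: tuple[str, ...]
    iteration_born: int


@dataclass(frozen=True)
class EnumeratedRecord:
    record: MoleculeRecord
    provenance: ProvenanceTag

    @property
    def canonical_key(self) -> str:
        return self.record.canonical_key


@dataclass
class EnumeratedLibrary:
    records: list[EnumeratedRecord]
    per_iteration_counts: dict[int, int] = field(default_factory=dict)
    gate_rejections: dict[int, int] = field(default_factory=dict)
    n_curation_rejections: int = 0
    config: EnumerationConfig = field(default_factory=EnumerationConfig)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for er in self.records:
            profile = compute_profile(er.record)
            rows.append(
                {
                    "canonical_key": er.canonical_key,
                    "seed_id": er.provenance.seed_id,
                    "rule_chain": ";".join(er.provenance.rule_chain),
                    "iteration_born": er.provenance.iteration_born,
                    "MW": round(profile.MW, 3),
                    "TPSA": round(profile.TPSA, 2),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["canonical_key", "seed_id", "rule_chain", "iteration_born", "MW", "TPSA"],
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def property_gate(mol: MoleculeRecord, config: EnumerationConfig) -> bool:
    """True iff MW < mw_max (strict) and tpsa_min <= TPSA <= tpsa_max."""
    profile = compute_profile(mol)
    return profile.MW < config.mw_max and config.tpsa_min <= profile.TPSA <= config.tpsa_max


def expand_once(
    mols: Sequence[MoleculeRecord | EnumeratedRecord],
    compendium: RuleCompendium,
) -> tuple[list[EnumeratedRecord], int]:
    """One expansion step: every compiling rule applied to every molecule.

    Each raw product is re-standardized through the curation cascade and
    tagged with its parent's provenance extended by the firing rule.
    Duplicates (by canonical key) keep the first provenance encountered;
    rules and molecules are visited in their given order, so the result is
    deterministic.  Returns the products and the count of products the
    curation cascade rejected.
    """
    products: dict[str, EnumeratedRecord] = {}
    n_rejected = 0
    for item in mols:
        if isinstance(item, EnumeratedRecord):
            parent, parent_tag = item.record, item.provenance
        else:
            parent = item
            parent_tag = ProvenanceTag(seed_id=item.source_id, rule_chain=(), iteration_born=0)
        for rule in compendium:
            if not rule.compiles():
                continue
            for raw in apply_rule(rule, parent):
                curated = standardize_record(raw.canonical_key, source_id=parent_tag.seed_id)
                if isinstance(curated, Rejection):
                    n_rejected += 1
                    continue
                key = curated.canonical_key
                if key in products:
                    continue
                tag = ProvenanceTag(
                    seed_id=parent_tag.seed_id,
                    rule_chain=parent_tag.rule_chain + (rule.rule_id,),
                    iteration_born=parent_tag.iteration_born + 1,
                )
                products[key] = EnumeratedRecord(record=curated, provenance=tag)
    return list(products.values()), n_rejected


def enumerate_library(
    seeds: Sequence[MoleculeRecord],
    compendium: RuleCompendium,
    config: EnumerationConfig | None = None,
) -> EnumeratedLibrary:
    """Iteratively expand seeds through the compendium with property gates.

    Gated-out candidates do not seed the next iteration, and only molecules
    new to the accumulated library are expanded further (this keeps rewrite
    cycles such as A -> B -> A from looping).  Output ordering is
    deterministic: (iteration_born, canonical_key).
    """
    if not seeds:
        raise ValueError("seed set must be non-empty")
    config = config or EnumerationConfig()
    library = EnumeratedLibrary(records=[], config=config)
    known_keys = {s.canonical_key for s in seeds}
    accepted: dict[str, EnumeratedRecord] = {}
    frontier: list[EnumeratedRecord] = [
        EnumeratedRecord(
            record=s,
            provenance=ProvenanceTag(seed_id=s.source_id, rule_chain=(), iteration_born=0),
        )
        for s in sorted(seeds, key=lambda s: s.canonical_key)
    ]
    for iteration in range(1, config.n_iterations + 1):
        candidates, n_rej = expand_once(frontier, compendium)
        library.n_curation_rejections += n_rej
        new_frontier: list[EnumeratedRecord] = []
        n_gated = 0
        for cand in candidates:
            if cand.canonical_key in known_keys:
                continue
            if not property_gate(cand.record, config):
                n_gated += 1
                continue
            # provenance says this iteration, which equals parent iteration + 1
            tagged = replace(cand, provenance=replace(cand.provenance, iteration_born=iteration))
            known_keys.add(tagged.canonical_key)
            accepted[tagged.canonical_key] = tagged
            new_frontier.append(tagged)
        library.per_iteration_counts[iteration] = len(new_frontier)
        library.gate_rejections[iteration] = n_gated
        logger.info(
            "iteration %d: %d new molecules, %d gated out, %d curation-rejected",
            iteration, len(new_frontier), n_gated, n_rej,
        )
        frontier = sorted(new_frontier, key=lambda er: er.canonical_key)
        if not frontier:
            break
    records = sorted(
        accepted.values(), key=lambda er: (er.provenance.iteration_born, er.canonical_key)
    )
    if config.include_seeds_in_output:
        seed_records = [
            EnumeratedRecord(
                record=s,
                provenance=ProvenanceTag(seed_id=s.source_id, rule_chain=(), iteration_born=0),
            )
            for s in sorted(seeds, key=lambda s: s.canonical_key)
        ]
        records = seed_records + records
    library.records = records
    return library


def replay_provenance(
    library: EnumeratedLibrary, seeds: Sequence[MoleculeRecord], compendium: RuleCompendium
) -> dict[str, bool]:
    """Re-derive each record from its seed through its rule chain.

    Returns a map canonical_key -> True if the chain regenerates the key.
    Used as a structural audit of enumeration provenance.
    """
    seed_by_id = {s.source_id: s for s in seeds}
    out: dict[str, bool] = {}
    for er in library.records:
        if not er.provenance.rule_chain:
            out[er.canonical_key] = er.canonical_key in {s.canonical_key for s in seeds}
            continue
        current = {seed_by_id[er.provenance.seed_id].canonical_key}
        for rule_id in er.provenance.rule_chain:
            rule = compendium[rule_id]
            next_keys: set[str] = set()
            for key in current:
                curated = standardize_record(key)
                if isinstance(curated, Rejection):
                    continue
                for product in apply_rule(rule, curated):
                    final = standardize_record(product.canonical_key)
                    if not isinstance(final, Rejection):
                        next_keys.add(final.canonical_key)
            current = next_keys
        out[er.canonical_key] = er.canonical_key in current
    return out
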