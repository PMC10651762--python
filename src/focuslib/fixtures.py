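"""Synthetic fixtures: probe molecules, seed sets, and reference libraries.

Everything in the workflow is testable without downloads.  This module
provides (a) the built-in compendium of the seven published example rules,
(b) deterministic seed/probe molecules carrying the functional-group motifs
those rules act on, and (c) reference-library emulators that sample
decorated scaffolds so library-level property means land near requested
targets — stand-ins for external reference collections (approved drugs,
natural products, literature multi-target compounds) in chemical-space
analyses.

``compound3_like``/``compound4_like`` are synthetic stand-ins for two
literature multi-target antihyperglycemic seeds whose structures are only
depicted graphically: thiazolidinedione-bearing aryl scaffolds with the same
motif content, clearly labeled as stand-ins.  Workflows accept real SMILES
for these seeds whenever the user supplies them.
"""

from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path
from typing import Mapping, Sequence

from rdkit import Chem

from .curation import MoleculeRecord, Rejection, standardize_record
from .rules import RuleCompendium, load_compendium

logger = logging.getLogger("focuslib.fixtures")


class FixtureConfigError(ValueError):
    pass


_RULES_RESOURCE = "transformation_rules.tsv"


def builtin_rules_path() -> Path:
    return Path(str(files("focuslib.data").joinpath(_RULES_RESOURCE)))


def builtin_rules() -> RuleCompendium:
    """The seven published example transformation rules, packaged as TSV."""
    return load_compendium(builtin_rules_path())


# ---------------------------------------------------------------------------
# motif pools
# ---------------------------------------------------------------------------

#: per-motif verification SMARTS and a pool of hand-written carrier molecules
MOTIFS: dict[str, dict] = {
    "carboxylic-acid": {
        "smarts": "[#6;A;!R;X3](=O)[OX2H1]",
        "pool": [
            "CC(=O)O",
            "CCC(=O)O",
            "OC(=O)Cc1ccccc1",
            "OC(=O)CCc1ccccc1",
            "OC(=O)COc1ccccc1",
            "CC(C)CC(=O)O",
            "OC(=O)CCl",
            "OC(=O)Cc1ccc(F)cc1",
            "CCOC(=O)CC(=O)O",
            "OC(=O)CCN1CCCCC1",
        ],
    },
    "phenyl": {
        "smarts": "[cX3]1[cX3H][cX3H][cX3H][cX3H][cX3H]1",
        "pool": [
            "Cc1ccccc1",
            "CCc1ccccc1",
            "COc1ccccc1",
            "CCCc1ccccc1",
            "OCCc1ccccc1",
            "CC(C)c1ccccc1",
            "NCCc1ccccc1",
            "CN(C)Cc1ccccc1",
            "O=C(C)Nc1ccccc1",
            "c1ccc(CC2CCCC2)cc1",
        ],
    },
    "amide": {
        "smarts": "[CX3](=O)[NX3]",
        "pool": [
            "CC(=O)NC",
            "CC(=O)NCC",
            "CCC(=O)NC1CCCC1",
            "CC(=O)Nc1ccccc1",
            "O=C(NC)c1ccccc1",
            "CN(C)C(=O)CC",
            "O=C(NCCO)C1CCC1",
            "CC(=O)NCCc1ccccc1",
        ],
    },
    "aminophenyl": {
        "smarts": "[NX3]([#6])([#6])c1ccccc1",
        "pool": [
            "CN(C)c1ccccc1",
            "CCN(C)c1ccccc1",
            "CCN(CC)c1ccccc1",
            "CN(CCO)c1ccccc1",
            "C1CCN(c2ccccc2)CC1",
            "CN(Cc1ccccc1)c1ccccc1",
            "O1CCN(c2ccccc2)CC1",
        ],
    },
    "benzoylphenyl": {
        "smarts": "c1ccccc1C(=O)c1ccccc1",
        "pool": [
            "O=C(c1ccccc1)c1ccccc1",
            "Cc1ccc(C(=O)c2ccccc2)cc1",
            "COc1ccc(C(=O)c2ccccc2)cc1",
            "O=C(c1ccccc1)c1ccc(F)cc1",
            "CCc1ccc(C(=O)c2ccccc2)cc1",
            "O=C(c1ccccc1)c1ccc(O)cc1",
        ],
    },
    "1,4-diaminophenyl": {
        "smarts": "[NX3H2]c1ccc([NX3H2])cc1",
        "pool": [
            "Nc1ccc(N)cc1",
            "Cc1cc(N)ccc1N",
            "Nc1ccc(N)c(F)c1",
            "Nc1ccc(N)c(OC)c1",
            "CCc1cc(N)ccc1N",
        ],
    },
}

#: maps rule-table group names (lower-cased) onto motif names
GROUP_TO_MOTIF = {
    "carboxyl": "carboxylic-acid",
    "carboxylic-acid": "carboxylic-acid",
    "phenyl": "phenyl",
    "amide": "amide",
    "aminophenyl": "aminophenyl",
    "benzoylphenyl": "benzoylphenyl",
    "1,4-diaminophenyl": "1,4-diaminophenyl",
}

#: substituents used by the decorator: (SMILES fragment, attachment atom idx)
_DECORATIONS = (
    "C", "CC", "CCC", "OC", "F", "Cl", "N", "O", "CO", "C(F)(F)F", "C#N",
    "c1ccccc1", "Cc1ccccc1", "C1CCCCC1", "N1CCOCC1", "OC(C)=O", "S(C)(=O)=O",
    "C(=O)NC", "OCCO",
)


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: how many carriers of each motif, how decorated."""

    motifs: Mapping[str, int] = field(default_factory=dict)
    decoration_depth: int = 1
    seed: int = 0


def _decorate(mol: Chem.Mol, rng: random.Random, depth: int) -> Chem.Mol:
    """Attach up to ``depth`` small substituents at random C-H positions."""
    current = mol
    for _ in range(depth):
        if rng.random() < 0.4:
            continue
        candidate = _attach_random_group(current, rng)
        if candidate is not None:
            current = candidate
    return current


def _attach_random_group(mol: Chem.Mol, rng: random.Random) -> Chem.Mol | None:
    sites = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() > 0
    ]
    if not sites:
        return None
    site = rng.choice(sites)
    group = rng.choice(_DECORATIONS)
    fragment = Chem.MolFromSmiles(group)
    if fragment is None:
        return None
    combined = Chem.RWMol(Chem.CombineMols(mol, fragment))
    combined.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        product = combined.GetMol()
        Chem.SanitizeMol(product)
    except Exception:
        return None
    return product


def make_seed_set(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Deterministic curated molecules, each carrying a requested motif."""
    rng = random.Random(spec.seed)
    out: list[MoleculeRecord] = []
    seen: set[str] = set()
    for motif, count in spec.motifs.items():
        if motif not in MOTIFS:
            raise FixtureConfigError(
                f"unknown motif {motif!r}; known: {sorted(MOTIFS)}"
            )
        pattern = Chem.MolFromSmarts(MOTIFS[motif]["smarts"])
        pool = MOTIFS[motif]["pool"]
        produced = 0
        attempts = 0
        while produced < count and attempts < count * 50 + 50:
            base = Chem.MolFromSmiles(pool[attempts % len(pool)])
            attempts += 1
            mol = _decorate(base, rng, spec.decoration_depth) if spec.decoration_depth else base
            if not mol.HasSubstructMatch(pattern):
                continue
            record = standardize_record(
                Chem.MolToSmiles(mol), source_id=f"{motif}-{produced}"
            )
            if isinstance(record, Rejection):
                continue
            if record.canonical_key in seen or not record.structure.HasSubstructMatch(pattern):
                continue
            seen.add(record.canonical_key)
            out.append(record)
            produced += 1
        if produced < count:
            raise FixtureConfigError(
                f"could not generate {count} distinct carriers of motif {motif!r}"
            )
    return out


def default_probes() -> dict[str, list[MoleculeRecord]]:
    """Motif probes for compendium validation, keyed by group name."""
    probes: dict[str, list[MoleculeRecord]] = {}
    spec = FixtureSpec(motifs={m: 2 for m in MOTIFS}, decoration_depth=0, seed=0)
    records = make_seed_set(spec)
    by_motif: dict[str, list[MoleculeRecord]] = {}
    for rec in records:
        motif = rec.source_id.rsplit("-", 1)[0]
        by_motif.setdefault(motif, []).append(rec)
    for group, motif in GROUP_TO_MOTIF.items():
        probes[group] = by_motif.get(motif, [])
    return probes


# ---------------------------------------------------------------------------
# reference-library emulation
# ---------------------------------------------------------------------------

_SCAFFOLDS = (
    "c1ccccc1",
    "c1ccncc1",
    "c1ccc2ccccc2c1",
    "C1CCNCC1",
    "C1CCOC1",
    "c1ccc(-c2ccccc2)cc1",
    "O=C1NC(=O)CS1",          # thiazolidinedione
    "c1ccc2[nH]ccc2c1",
    "O=C(Nc1ccccc1)C1CC1",
    "O=S(=O)(N)c1ccccc1",
)


def make_reference_library(
    n: int,
    property_targets: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    label: str = "ref",
    scaffolds: Sequence[str] | None = None,
) -> list[MoleculeRecord]:
    """Sample decorated scaffolds so library property means approach targets.

    ``property_targets`` maps descriptor names among MW/TPSA/logP to
    ``(target, tolerance)``.  A candidate pool is generated deterministically
    and members are picked greedily to steer the running means toward the
    targets; if a target mean remains outside its tolerance a warning is
    emitted and the best-effort selection returned.
    """
    from .molprops import compute_profile  # local: molprops is heavier

    if n < 1:
        raise FixtureConfigError("n must be >= 1")
    rng = random.Random(seed)
    targets = dict(property_targets or {})
    bad = set(targets) - {"MW", "TPSA", "logP"}
    if bad:
        raise FixtureConfigError(f"unsupported property targets: {sorted(bad)}")
    bases = tuple(scaffolds) if scaffolds else _SCAFFOLDS

    pool: list[tuple[MoleculeRecord, dict[str, float]]] = []
    seen: set[str] = set()
    pool_goal = max(200, 8 * n)
    attempts = 0
    while len(pool) < pool_goal and attempts < pool_goal * 20:
        attempts += 1
        base = Chem.MolFromSmiles(rng.choice(bases))
        mol = _decorate(base, rng, depth=rng.randint(0, 4))
        record = standardize_record(Chem.MolToSmiles(mol), source_id="")
        if isinstance(record, Rejection) or record.canonical_key in seen:
            continue
        seen.add(record.canonical_key)
        profile = compute_profile(record)
        pool.append(
            (record, {"MW": profile.MW, "TPSA": profile.TPSA, "logP": profile.logP})
        )
    if len(pool) < n:
        raise FixtureConfigError("could not generate a large enough candidate pool")

    chosen: list[tuple[MoleculeRecord, dict[str, float]]] = []

    def cost_with(extra: dict[str, float]) -> float:
        if not targets:
            return 0.0
        k = len(chosen) + 1
        cost = 0.0
        for prop, (target, tol) in targets.items():
            mean = (sum(p[1][prop] for p in chosen) + extra[prop]) / k
            cost += ((mean - target) / max(tol, 1e-9)) ** 2
        return cost

    available = list(pool)
    for _ in range(n):
        if targets:
            best = min(available, key=lambda item: cost_with(item[1]))
        else:
            best = available[0]
        available.remove(best)
        chosen.append(best)

    for prop, (target, tol) in targets.items():
        mean = sum(p[1][prop] for p in chosen) / len(chosen)
        if abs(mean - target) > tol:
            warnings.warn(
                f"reference library {label!r}: {prop} mean {mean:.1f} outside "
                f"target {target}±{tol} (best effort)",
                stacklevel=2,
            )
    return [
        MoleculeRecord(
            source_id=f"{label}-{i}",
            smiles_in=rec.smiles_in,
            canonical_key=rec.canonical_key,
            structure=rec.structure,
            flags=rec.flags,
        )
        for i, (rec, _) in enumerate(chosen)
    ]


# ---------------------------------------------------------------------------
# seed-compound stand-ins
# ---------------------------------------------------------------------------


def compound3_like() -> MoleculeRecord:
    """Synthetic stand-in for literature seed compound 3.

    A thiazolidinedione-bearing aryl ether scaffold with the motif content
    (acidic TZD head group, phenyl rings, flexible linker) that the
    transformation rules act on.  Not the literature structure.
    """
    record = standardize_record(
        "O=C1NC(=O)C(Cc2ccc(OCc3ccccc3)cc2)S1", source_id="compound3-like"
    )
    assert isinstance(record, MoleculeRecord)
    return record


def compound4_like() -> MoleculeRecord:
    """Synthetic stand-in for literature seed compound 4 (see compound3_like)."""
    record = standardize_record(
        "O=C1NC(=O)C(Cc2ccc(C(=O)c3ccccc3)cc2)S1", source_id="compound4-like"
    )
    assert isinstance(record, MoleculeRecord)
    return record


#: common reagent-scale molecules; a frequency reference needs the simple
#: alkyl/alcohol/amine/acid environments that drug-like scaffolds alone miss
_BUILDING_BLOCKS = (
    "CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCCC", "CCCCCCCCCC",
    "CC(C)C", "CC(C)(C)C", "C1CCCCC1", "C1CCCC1",
    "CO", "CCO", "CCCO", "CC(C)O", "OCCO", "CCOCC", "COC",
    "CN", "CCN", "CCCN", "CNC", "CN(C)C", "NCCN", "NCCO",
    "CC(=O)O", "CCC(=O)O", "CCCC(=O)O", "CC(=O)OC", "CC(=O)OCC",
    "CC(=O)N", "CC(=O)NC", "CC(=O)NCC", "CC#N", "CS", "CSC", "CS(C)(=O)=O",
    "Cc1ccccc1", "CCc1ccccc1", "COc1ccccc1", "Oc1ccccc1", "Nc1ccccc1",
    "Clc1ccccc1", "Fc1ccccc1", "c1ccncc1", "c1cc[nH]c1", "c1ccsc1", "c1ccoc1",
    "OCc1ccccc1", "NCc1ccccc1", "O=Cc1ccccc1", "CC(=O)c1ccccc1",
)


def fragment_corpus(seed: int = 0, n: int = 300) -> list[MoleculeRecord]:
    """Deterministic drug-like corpus backing the packaged fragment table."""
    corpus = make_reference_library(
        n,
        property_targets={"MW": (350.0, 60.0), "TPSA": (80.0, 30.0), "logP": (3.0, 1.5)},
        seed=seed,
        label="corpus",
    )
    corpus += make_seed_set(
        FixtureSpec(motifs={m: 3 for m in MOTIFS}, decoration_depth=1, seed=seed + 1)
    )
    corpus += [compound3_like(), compound4_like()]
    for i, smiles in enumerate(_BUILDING_BLOCKS):
        record = standardize_record(smiles, source_id=f"block-{i}")
        if isinstance(record, MoleculeRecord):
            corpus.append(record)
    return corpus


def write_seed_file(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    lines = [f"{rec.canonical_key}\t{rec.source_id}" for rec in records]
    Path(path).write_text("\n".join(lines) + "\n")
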