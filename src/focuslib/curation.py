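"""Standardization and curation of raw compound inputs.

Raw SMILES are pushed through a fixed-order cascade: parse/sanitize, split
multi-component records keeping the largest fragment, reject disallowed
elements or valence errors, neutralize then reionize, canonicalize the
tautomer, and finally emit a stereo-agnostic canonical SMILES used as the
deduplication key.  Every failure is logged with its first-failing reason;
nothing is dropped silently.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.rdchem import AtomKekulizeException, AtomValenceException, KekulizeException

logger = logging.getLogger("focuslib.curation")

RDLogger.DisableLog("rdApp.*")

#: Elements retained by the curation cascade; anything else rejects the record.
ELEMENT_WHITELIST = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

FLAG_MULTI_COMPONENT = "multi-component-split"
FLAG_NEUTRALIZED = "neutralized"
FLAG_TAUTOMER = "tautomer-canonicalized"

# standardizer singletons are lazy: constructing a TautomerEnumerator is not free
_uncharger: rdMolStandardize.Uncharger | None = None
_reionizer: rdMolStandardize.Reionizer | None = None
_tautomerizer: rdMolStandardize.TautomerEnumerator | None = None


def _standardizers() -> tuple[
    rdMolStandardize.Uncharger, rdMolStandardize.Reionizer, rdMolStandardize.TautomerEnumerator
]:
    global _uncharger, _reionizer, _tautomerizer
    if _uncharger is None:
        _uncharger = rdMolStandardize.Uncharger()
        _reionizer = rdMolStandardize.Reionizer()
        _tautomerizer = rdMolStandardize.TautomerEnumerator()
    return _uncharger, _reionizer, _tautomerizer


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized structure plus its stereo-agnostic canonical key."""

    source_id: str
    smiles_in: str
    canonical_key: str
    structure: Chem.Mol
    flags: frozenset[str] = frozenset()

    def __repr__(self) -> str:  # Mol objects render uselessly
        return (
            f"MoleculeRecord(source_id={self.source_id!r}, "
            f"canonical_key={self.canonical_key!r}, flags={sorted(self.flags)})"
        )


@dataclass(frozen=True)
class Rejection:
    source_id: str
    smiles_in: str
    reason: str  # one of: parse, element, valence


@dataclass
class CurationReport:
    n_input: int = 0
    n_after_split: int = 0
    n_removed_element_or_valence: int = 0
    n_after_dedup: int = 0
    rejections: list[Rejection] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_split": self.n_after_split,
            "n_removed_element_or_valence": self.n_removed_element_or_valence,
            "n_after_dedup": self.n_after_dedup,
            "rejections": [
                {"source_id": r.source_id, "smiles_in": r.smiles_in, "reason": r.reason}
                for r in self.rejections
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def stereo_stripped_key(mol: Chem.Mol) -> str:
    """Canonical SMILES with all stereo descriptors removed."""
    flat = Chem.Mol(mol)
    Chem.RemoveStereochemistry(flat)
    return Chem.MolToSmiles(flat)


def record_from_mol(mol: Chem.Mol, source_id: str = "", smiles_in: str | None = None,
                    flags: Iterable[str] = ()) -> MoleculeRecord:
    """Light-weight record constructor for molecules already sanitized."""
    return MoleculeRecord(
        source_id=source_id,
        smiles_in=smiles_in if smiles_in is not None else Chem.MolToSmiles(mol),
        canonical_key=stereo_stripped_key(mol),
        structure=mol,
        flags=frozenset(flags),
    )


def _largest_fragment(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol, False
    # most heavy atoms, tie-broken by molecular weight then canonical key
    def rank(f: Chem.Mol) -> tuple[int, float, str]:
        return (f.GetNumHeavyAtoms(), Descriptors.MolWt(f), Chem.MolToSmiles(f))

    return max(frags, key=rank), True


def standardize_record(smiles: str, source_id: str = "") -> MoleculeRecord | Rejection:
    """Run one raw SMILES through the full standardization cascade.

    Order is fixed: parse/sanitize, largest component, element/valence check,
    neutralize, reionize, canonical tautomer, stereo-stripped canonical key.
    """
    if not smiles or not smiles.strip():
        return Rejection(source_id, smiles, "parse")
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        return Rejection(source_id, smiles, "parse")
    try:
        Chem.SanitizeMol(mol)
    except (AtomValenceException, AtomKekulizeException) as exc:
        logger.debug("valence/kekulize failure for %s: %s", source_id, exc)
        return Rejection(source_id, smiles, "valence")
    except Exception as exc:  # other sanitization problems read as parse failures
        logger.debug("sanitize failure for %s: %s", source_id, exc)
        return Rejection(source_id, smiles, "parse")

    flags: set[str] = set()
    mol, was_split = _largest_fragment(mol)
    if was_split:
        flags.add(FLAG_MULTI_COMPONENT)
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            return Rejection(source_id, smiles, "valence")

    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ELEMENT_WHITELIST:
            return Rejection(source_id, smiles, "element")

    uncharger, reionizer, tautomerizer = _standardizers()
    charges_before = sum(abs(a.GetFormalCharge()) for a in mol.GetAtoms())
    mol = uncharger.uncharge(mol)
    if sum(abs(a.GetFormalCharge()) for a in mol.GetAtoms()) != charges_before:
        flags.add(FLAG_NEUTRALIZED)
    mol = reionizer.reionize(mol)
    before_taut = Chem.MolToSmiles(mol)
    try:
        mol = tautomerizer.Canonicalize(mol)
    except Exception as exc:  # pathological inputs: keep the pre-tautomer form
        logger.debug("tautomer canonicalization failed for %s: %s", source_id, exc)
    if Chem.MolToSmiles(mol) != before_taut:
        flags.add(FLAG_TAUTOMER)

    return MoleculeRecord(
        source_id=source_id,
        smiles_in=smiles,
        canonical_key=stereo_stripped_key(mol),
        structure=mol,
        flags=frozenset(flags),
    )


def curate_library(
    records: Iterable[str | tuple[str, str] | MoleculeRecord],
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Standardize every input and deduplicate by canonical key (first wins).

    Accepts raw SMILES strings, ``(source_id, smiles)`` pairs, or existing
    :class:`MoleculeRecord` objects (whose input SMILES are re-standardized,
    making the operation idempotent).
    """
    report = CurationReport()
    out: list[MoleculeRecord] = []
    seen: set[str] = set()
    for i, item in enumerate(records):
        if isinstance(item, MoleculeRecord):
            source_id, smiles = item.source_id, Chem.MolToSmiles(item.structure)
        elif isinstance(item, tuple):
            source_id, smiles = item
        else:
            source_id, smiles = f"mol-{i}", item
        report.n_input += 1
        result = standardize_record(smiles, source_id=source_id)
        if isinstance(result, Rejection):
            report.rejections.append(result)
            if result.reason in ("element", "valence"):
                report.n_removed_element_or_valence += 1
            continue
        report.n_after_split += 1
        if result.canonical_key in seen:
            continue
        seen.add(result.canonical_key)
        out.append(result)
    report.n_after_dedup = len(out)
    return out, report


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SMILES_COLUMN_CANDIDATES = ("smiles", "canonical_smiles", "canonical_key", "smiles_in")


def read_compounds(path: str | Path, smiles_column: str | None = None) -> list[tuple[str, str]]:
    """Read ``(source_id, smiles)`` pairs from .smi, .csv/.tsv, or .sdf files."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".smi", ".txt"):
        return list(_read_smi(path))
    if suffix in (".csv", ".tsv"):
        return list(_read_table(path, "\t" if suffix == ".tsv" else ",", smiles_column))
    if suffix == ".sdf":
        return list(_read_sdf(path))
    raise ValueError(f"unsupported compound file format: {path.name}")


def _read_smi(path: Path) -> Iterator[tuple[str, str]]:
    for i, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        ident = parts[1].strip() if len(parts) > 1 else f"{path.stem}-{i}"
        yield ident, smiles


def _read_table(path: Path, sep: str, smiles_column: str | None) -> Iterator[tuple[str, str]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        if reader.fieldnames is None:
            return
        lowered = {c.lower(): c for c in reader.fieldnames}
        if smiles_column is not None:
            if smiles_column not in reader.fieldnames:
                raise ValueError(f"column {smiles_column!r} not found in {path.name}")
            col = smiles_column
        else:
            col = next(
                (lowered[c] for c in _SMILES_COLUMN_CANDIDATES if c in lowered), None
            )
            if col is None:
                raise ValueError(f"no SMILES column found in {path.name}")
        id_col = next(
            (lowered[c] for c in ("id", "source_id", "name", "rule_id") if c in lowered),
            None,
        )
        for i, row in enumerate(reader):
            ident = row[id_col] if id_col else f"{path.stem}-{i}"
            yield ident, row[col]


def _read_sdf(path: Path) -> Iterator[tuple[str, str]]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            yield f"{path.stem}-{i}", ""  # recorded downstream as a parse rejection
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"{path.stem}-{i}"
        yield name or f"{path.stem}-{i}", Chem.MolToSmiles(mol)


def write_curated_csv(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "input_smiles", "canonical_key", "flags"])
        for rec in records:
            writer.writerow(
                [rec.source_id, rec.smiles_in, rec.canonical_key, ";".join(sorted(rec.flags))]
            )
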