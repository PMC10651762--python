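"""SMIRKS transformation-rule engine.

Medicinal-chemistry transformation rules (phenyl -> cyclohexyl and friends)
are encoded as SMIRKS rewrites with metadata: the functional-group family
they act on, a transformation-type category, rationale tags, and a literature
reference.  This module parses rule tables, compiles the SMIRKS into RDKit
reactions, audits whole compendia against motif probes, and applies single
rules to molecules with single-site semantics.

Printed rule tables often carry ChemAxon extension blocks (``|s:0:1|``,
``|rb:...|``) after the SMIRKS proper; these encode drawing/stereo hints, are
stripped before compilation, and are kept as metadata.  Whitespace inside the
printed SMIRKS is insignificant and removed wholesale.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem

from .curation import MoleculeRecord, record_from_mol, stereo_stripped_key

logger = logging.getLogger("focuslib.rules")

#: columns required in a rule-compendium table, in canonical order
COMPENDIUM_COLUMNS = (
    "rule_id",
    "group",
    "name",
    "transformation_type",
    "smirks",
    "notes",
    "reference",
)

# statuses used by compendium validation
STATUS_PARSED = "parsed"
STATUS_PARSE_ERROR = "parse-error"
STATUS_NO_PROBE_MATCH = "no-probe-match"
STATUS_INVALID_PRODUCT = "produced-invalid-product"


class MalformedSmirksError(ValueError):
    """The SMIRKS string cannot be split or compiled into a rewrite."""


class InconsistentMappingError(ValueError):
    """A product-side atom-map class has no reactant-side counterpart."""


class SchemaError(ValueError):
    """A rule table is missing required columns."""


class DuplicateIdError(ValueError):
    """Two rules in one table share a rule_id."""


class InvalidInputError(ValueError):
    """The molecule handed to apply_rule cannot be sanitized."""


class TransformationType(Enum):
    RING_SUBSTITUTION = "ring substitution"
    RING_MODIFICATION = "ring modification"
    RING_ADDITION = "ring addition"
    LINKER_MODIFICATION = "linker modification"
    FUNCTIONAL_GROUP_CHANGE = "functional group change"
    ADDITION = "addition"
    REMOVAL = "removal"
    CYCLIZATION = "cyclization"
    OTHER = "other"

    @classmethod
    def from_text(cls, text: str) -> "TransformationType":
        key = re.sub(r"[\s_-]+", " ", (text or "").strip().lower())
        for member in cls:
            if member.value == key:
                return member
        return cls.OTHER


_EXTENSION_RE = re.compile(r"\|[^|]*\|\s*$")


@dataclass(frozen=True)
class CompiledSmirks:
    """A compiled rewrite: reactant-side query plus product-side template."""

    reaction: AllChem.ChemicalReaction
    smirks: str  # cleaned form actually compiled
    extension: str | None  # stripped ChemAxon block, verbatim, or None
    mapped_atoms: frozenset[int]  # reactant-side atom-map classes
    unmapped_product_maps: frozenset[int]  # product maps absent from reactants

    @property
    def reactant_query(self) -> Chem.Mol:
        return self.reaction.GetReactantTemplate(0)


def parse_smirks(text: str, strict_mapping: bool = False) -> CompiledSmirks:
    """Compile a SMIRKS string into an applicable rewrite pattern.

    Any trailing ``|...|`` extension block is stripped and recorded; all
    whitespace is insignificant and removed.  Product atom maps with no
    reactant-side counterpart denote newly introduced atoms; with
    ``strict_mapping=True`` they raise :class:`InconsistentMappingError`
    instead.
    """
    if not text or not text.strip():
        raise MalformedSmirksError("empty SMIRKS string")
    cleaned = text.strip()
    extension = None
    m = _EXTENSION_RE.search(cleaned)
    if m:
        extension = m.group(0).strip()
        cleaned = cleaned[: m.start()]
    cleaned = re.sub(r"\s+", "", cleaned)
    if ">>" not in cleaned:
        raise MalformedSmirksError(f"missing '>>' separator in {text!r}")
    sides = cleaned.split(">>")
    if len(sides) != 2 or not sides[0] or not sides[1]:
        raise MalformedSmirksError(
            f"SMIRKS must have exactly one reactant and one product side: {text!r}"
        )
    try:
        reaction = AllChem.ReactionFromSmarts(cleaned)
    except Exception as exc:
        raise MalformedSmirksError(f"SMIRKS failed to compile: {text!r} ({exc})") from exc
    if reaction is None or reaction.GetNumReactantTemplates() != 1 or \
            reaction.GetNumProductTemplates() < 1:
        raise MalformedSmirksError(f"SMIRKS is not a single-reactant rewrite: {text!r}")
    reaction.Initialize()
    _, n_errors = reaction.Validate(silent=True)
    if n_errors:
        raise MalformedSmirksError(f"SMIRKS failed reaction validation: {text!r}")

    reactant_maps = {
        atom.GetAtomMapNum()
        for i in range(reaction.GetNumReactantTemplates())
        for atom in reaction.GetReactantTemplate(i).GetAtoms()
        if atom.GetAtomMapNum()
    }
    product_maps = {
        atom.GetAtomMapNum()
        for i in range(reaction.GetNumProductTemplates())
        for atom in reaction.GetProductTemplate(i).GetAtoms()
        if atom.GetAtomMapNum()
    }
    unmapped = frozenset(product_maps - reactant_maps)
    if unmapped and strict_mapping:
        raise InconsistentMappingError(
            f"product atom-map classes {sorted(unmapped)} missing on reactant side: {text!r}"
        )
    return CompiledSmirks(
        reaction=reaction,
        smirks=cleaned,
        extension=extension,
        mapped_atoms=frozenset(reactant_maps),
        unmapped_product_maps=unmapped,
    )


@dataclass
class TransformationRule:
    """One SMIRKS rewrite plus its medicinal-chemistry metadata."""

    rule_id: str
    group: str
    name: str
    transformation_type: TransformationType
    smirks: str
    notes: tuple[str, ...] = ()
    reference: str = ""
    _compiled: CompiledSmirks | None = field(default=None, repr=False, compare=False)
    parse_error: str | None = field(default=None, repr=False, compare=False)

    @property
    def compiled(self) -> CompiledSmirks:
        if self._compiled is None:
            self._compiled = parse_smirks(self.smirks)  # may raise
        return self._compiled

    def compiles(self) -> bool:
        if self.parse_error is not None:
            return False
        try:
            self.compiled
            return True
        except (MalformedSmirksError, InconsistentMappingError) as exc:
            self.parse_error = str(exc)
            return False


@dataclass
class RuleCompendium:
    """Ordered collection of transformation rules keyed by rule_id."""

    rules: dict[str, TransformationRule]
    source: str = ""

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self) -> Iterator[TransformationRule]:
        return iter(self.rules.values())

    def __getitem__(self, rule_id: str) -> TransformationRule:
        return self.rules[rule_id]

    def get_by_name(self, name: str) -> TransformationRule:
        for rule in self:
            if rule.name == name:
                return rule
        raise KeyError(name)

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rule in self:
            counts[rule.group] = counts.get(rule.group, 0) + 1
        return counts

    def type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rule in self:
            key = rule.transformation_type.value
            counts[key] = counts.get(key, 0) + 1
        return counts

    @classmethod
    def from_rules(cls, rules: Iterable[TransformationRule], source: str = "") -> "RuleCompendium":
        table: dict[str, TransformationRule] = {}
        for rule in rules:
            if rule.rule_id in table:
                raise DuplicateIdError(f"duplicate rule_id {rule.rule_id!r}")
            table[rule.rule_id] = rule
        return cls(rules=table, source=source)


def load_compendium(path: str | Path) -> RuleCompendium:
    """Load a delimited rule table (CSV or TSV, header row required).

    Rows whose SMIRKS fail to compile are retained with a parse-error status
    so compendium audits can report them; they are never silently dropped.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines:
        raise SchemaError(f"{path.name}: empty file, header row required")
    sep = "\t" if "\t" in lines[0] else ","
    reader = csv.DictReader(lines, delimiter=sep)
    fieldnames = [c.strip() for c in (reader.fieldnames or [])]
    missing = [c for c in COMPENDIUM_COLUMNS if c not in fieldnames]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    rules: list[TransformationRule] = []
    for row in reader:
        rule = TransformationRule(
            rule_id=(row.get("rule_id") or "").strip(),
            group=(row.get("group") or "").strip(),
            name=(row.get("name") or "").strip(),
            transformation_type=TransformationType.from_text(row.get("transformation_type") or ""),
            smirks=(row.get("smirks") or "").strip(),
            notes=tuple(t.strip() for t in (row.get("notes") or "").split(";") if t.strip()),
            reference=(row.get("reference") or "").strip(),
        )
        rule.compiles()  # eagerly record parse errors, keep the row either way
        rules.append(rule)
    return RuleCompendium.from_rules(rules, source=str(path))


def write_compendium(compendium: RuleCompendium, path: str | Path) -> None:
    """Write a compendium back to TSV in the canonical column order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COMPENDIUM_COLUMNS)
        for rule in compendium:
            writer.writerow(
                [
                    rule.rule_id,
                    rule.group,
                    rule.name,
                    rule.transformation_type.value,
                    rule.smirks,
                    ";".join(rule.notes),
                    rule.reference,
                ]
            )


def apply_rule(
    rule: TransformationRule | CompiledSmirks,
    mol: MoleculeRecord | Chem.Mol,
    max_products: int = 1000,
) -> list[MoleculeRecord]:
    """Apply one rule at every matching site, one rewrite per product.

    Products are valence-sanitized (failures dropped and logged), deduplicated
    by stereo-stripped canonical key, and returned in lexicographic key order.
    The input molecule itself is never in the output.
    """
    compiled = rule.compiled if isinstance(rule, TransformationRule) else rule
    if isinstance(mol, MoleculeRecord):
        structure, source_id = mol.structure, mol.source_id
    else:
        structure, source_id = mol, ""
    work = Chem.Mol(structure)
    try:
        Chem.SanitizeMol(work)
    except Exception as exc:
        raise InvalidInputError(f"input molecule cannot be sanitized: {exc}") from exc
    input_key = stereo_stripped_key(work)

    seen: dict[str, Chem.Mol] = {}
    n_unsanitizable = 0
    for product_set in compiled.reaction.RunReactants((work,), maxProducts=max_products):
        for product in product_set:
            try:
                Chem.SanitizeMol(product)
            except Exception:
                n_unsanitizable += 1
                continue
            key = stereo_stripped_key(product)
            if key == input_key or key in seen:
                continue
            seen[key] = product
    if n_unsanitizable:
        logger.debug(
            "apply_rule: dropped %d unsanitizable product(s) of %s",
            n_unsanitizable,
            getattr(rule, "rule_id", "<compiled>"),
        )
    return [
        record_from_mol(seen[key], source_id=source_id)
        for key in sorted(seen)
    ]


@dataclass
class RuleValidationReport:
    """Per-rule audit of a compendium against motif probes."""

    statuses: dict[str, str]
    n_products: dict[str, int]
    errors: dict[str, str]
    group_counts: dict[str, int]
    type_counts: dict[str, int]

    @property
    def status_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for status in self.statuses.values():
            counts[status] = counts.get(status, 0) + 1
        return counts

    def to_dict(self) -> dict:
        return {
            "statuses": self.statuses,
            "n_products": self.n_products,
            "errors": self.errors,
            "group_counts": self.group_counts,
            "type_counts": self.type_counts,
            "status_counts": self.status_counts,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def validate_compendium(
    compendium: RuleCompendium,
    probes: Sequence[MoleculeRecord] | Mapping[str, Sequence[MoleculeRecord]] | None = None,
) -> RuleValidationReport:
    """Audit every rule: does it compile, match a probe, and yield a product?

    ``probes`` may be a flat molecule list (every rule is tried against all of
    them) or a mapping from group name (lower-cased) to molecules.  When
    omitted, motif probes are generated from the fixtures module.
    """
    if probes is None:
        from .fixtures import default_probes  # deferred: fixtures imports this module

        probes = default_probes()

    def probes_for(rule: TransformationRule) -> Sequence[MoleculeRecord]:
        if isinstance(probes, Mapping):
            specific = probes.get(rule.group.strip().lower())
            if specific:
                return specific
            return [m for group in probes.values() for m in group]
        return probes

    statuses: dict[str, str] = {}
    n_products: dict[str, int] = {}
    errors: dict[str, str] = {}
    for rule in compendium:
        if not rule.compiles():
            statuses[rule.rule_id] = STATUS_PARSE_ERROR
            errors[rule.rule_id] = rule.parse_error or "unknown parse error"
            n_products[rule.rule_id] = 0
            continue
        query = rule.compiled.reactant_query
        matched = [
            p for p in probes_for(rule) if p.structure.HasSubstructMatch(query)
        ]
        if not matched:
            statuses[rule.rule_id] = STATUS_NO_PROBE_MATCH
            n_products[rule.rule_id] = 0
            continue
        total = 0
        for probe in matched:
            total += len(apply_rule(rule, probe))
        n_products[rule.rule_id] = total
        statuses[rule.rule_id] = STATUS_PARSED if total else STATUS_INVALID_PRODUCT
    return RuleValidationReport(
        statuses=statuses,
        n_products=n_products,
        errors=errors,
        group_counts=compendium.group_counts(),
        type_counts=compendium.type_counts(),
    )
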