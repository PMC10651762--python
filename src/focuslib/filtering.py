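"""Medicinal-chemistry filter cascade with per-stage attrition reporting.

The cascade mirrors common library-triage practice: synthetic accessibility
(SAScore <= 6, inclusive), an optional pluggable synthetic-feasibility score
(> 0.5, strict; skipped unless a scorer is configured), drug-likeness
(QED > 0.67, strict), and zero structural alerts from explicit SMARTS
catalogs (PAINS A/B/C plus an unwanted-functionality set).  Stages are
independent predicates, so the final survivor set does not depend on stage
order even though per-stage attrition does; the report records both.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from rdkit import Chem
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from .curation import MoleculeRecord
from .molprops import SynthScorer, default_fragment_table, qed, sa_score

logger = logging.getLogger("focuslib.filtering")


class ConfigError(ValueError):
    """Invalid cascade configuration (unknown catalog, missing scorer...)."""


_CATALOG_SPECS: dict[str, tuple] = {
    "pains": (
        FilterCatalogParams.FilterCatalogs.PAINS_A,
        FilterCatalogParams.FilterCatalogs.PAINS_B,
        FilterCatalogParams.FilterCatalogs.PAINS_C,
    ),
    "pains_a": (FilterCatalogParams.FilterCatalogs.PAINS_A,),
    "pains_b": (FilterCatalogParams.FilterCatalogs.PAINS_B,),
    "pains_c": (FilterCatalogParams.FilterCatalogs.PAINS_C,),
    # published unwanted-functionality set (reactive / toxicophoric groups)
    "unwanted": (FilterCatalogParams.FilterCatalogs.BRENK,),
}

_catalog_cache: dict[tuple[str, ...], FilterCatalog] = {}


def _catalog_for(names: Sequence[str]) -> FilterCatalog:
    key = tuple(sorted(names))
    if key not in _catalog_cache:
        params = FilterCatalogParams()
        for name in key:
            if name not in _CATALOG_SPECS:
                raise ConfigError(
                    f"unknown alert catalog {name!r}; known: {sorted(_CATALOG_SPECS)}"
                )
            for spec in _CATALOG_SPECS[name]:
                params.AddCatalog(spec)
        _catalog_cache[key] = FilterCatalog(params)
    return _catalog_cache[key]


@dataclass(frozen=True)
class AlertHit:
    catalog: str
    pattern: str


def structural_alerts(
    mol: MoleculeRecord | Chem.Mol, catalogs: Sequence[str] = ("pains", "unwanted")
) -> list[AlertHit]:
    """All alert-catalog hits for a molecule; an empty list means clean."""
    m = mol.structure if isinstance(mol, MoleculeRecord) else mol
    hits: list[AlertHit] = []
    for name in catalogs:
        catalog = _catalog_for([name])
        for entry in catalog.GetMatches(m):
            hits.append(AlertHit(catalog=name, pattern=entry.GetDescription()))
    return hits


@dataclass(frozen=True)
class FilterSpec:
    qed_min: float = 0.67  # strict >
    sa_max: float = 6.0  # inclusive <=
    synth_min: float | None = None  # strict >; requires a pluggable scorer
    max_alerts: int = 0
    alert_catalogs: tuple[str, ...] = ("pains", "unwanted")
    stage_order: tuple[str, ...] = ("sa", "synth", "qed", "alerts")

    def enabled_stages(self) -> tuple[str, ...]:
        stages = []
        for stage in self.stage_order:
            if stage == "synth" and self.synth_min is None:
                continue  # pluggable scorer absent: stage skipped by convention
            stages.append(stage)
        return tuple(stages)


@dataclass
class CompoundScores:
    qed: float
    sa: float
    synth: float | None = None
    n_alerts: int | None = None


@dataclass
class FilterCascadeReport:
    n_input: int
    stage_order: tuple[str, ...]
    survivors_after: dict[str, int]
    rejected_at: dict[str, int]
    first_fail: dict[str, str]  # canonical_key -> stage name
    alert_hits: dict[str, list[AlertHit]]
    provenance: dict[str, object] = field(default_factory=dict)

    @property
    def n_survivors(self) -> int:
        if not self.stage_order:
            return self.n_input
        return self.survivors_after[self.stage_order[-1]]

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "stage_order": list(self.stage_order),
            "survivors_after": self.survivors_after,
            "rejected_at": self.rejected_at,
            "n_survivors": self.n_survivors,
            "first_fail": self.first_fail,
            "alert_hits": {
                key: [{"catalog": h.catalog, "pattern": h.pattern} for h in hits]
                for key, hits in self.alert_hits.items()
            },
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _score_records(
    records: Sequence[MoleculeRecord],
    spec: FilterSpec,
    synth_scorer: SynthScorer | None,
    stages: Sequence[str],
) -> dict[str, CompoundScores]:
    scores: dict[str, CompoundScores] = {}
    for rec in records:
        if rec.canonical_key in scores:
            continue
        entry = CompoundScores(
            qed=qed(rec) if "qed" in stages else float("nan"),
            sa=sa_score(rec) if "sa" in stages else float("nan"),
        )
        if "synth" in stages:
            entry.synth = synth_scorer(rec.structure)  # type: ignore[misc]
        scores[rec.canonical_key] = entry
    return scores


def run_cascade(
    records: Sequence[MoleculeRecord],
    spec: FilterSpec | None = None,
    synth_scorer: SynthScorer | None = None,
    scores: Mapping[str, CompoundScores] | None = None,
) -> tuple[list[MoleculeRecord], FilterCascadeReport]:
    """Apply the filter stages in order and report per-stage attrition.

    ``scores`` may supply precomputed per-compound scores (keyed by canonical
    key) — used for threshold studies; otherwise QED/SAScore are computed
    here.  The synth stage runs only when ``spec.synth_min`` is set, and then
    requires ``synth_scorer`` (or synth values inside ``scores``).
    """
    spec = spec or FilterSpec()
    stages = spec.enabled_stages()
    if "synth" in stages and synth_scorer is None and scores is None:
        raise ConfigError("synth stage enabled but no synthetic-feasibility scorer configured")
    _catalog_for(spec.alert_catalogs)  # fail fast on unknown catalog names

    if scores is None:
        scores = _score_records(records, spec, synth_scorer, stages)

    _, table_provenance = default_fragment_table()
    report = FilterCascadeReport(
        n_input=len(records),
        stage_order=stages,
        survivors_after={},
        rejected_at={stage: 0 for stage in stages},
        first_fail={},
        alert_hits={},
        provenance={
            "filter_spec": {
                "qed_min": spec.qed_min,
                "sa_max": spec.sa_max,
                "synth_min": spec.synth_min,
                "max_alerts": spec.max_alerts,
                "alert_catalogs": list(spec.alert_catalogs),
            },
            "sa_fragment_table": table_provenance,
        },
    )

    surviving = list(records)
    for stage in stages:
        kept: list[MoleculeRecord] = []
        for rec in surviving:
            if _passes(rec, stage, spec, scores, report):
                kept.append(rec)
            else:
                report.rejected_at[stage] += 1
                report.first_fail[rec.canonical_key] = stage
        surviving = kept
        report.survivors_after[stage] = len(surviving)
    return surviving, report


def _passes(
    rec: MoleculeRecord,
    stage: str,
    spec: FilterSpec,
    scores: Mapping[str, CompoundScores],
    report: FilterCascadeReport,
) -> bool:
    entry = scores[rec.canonical_key]
    if stage == "sa":
        return entry.sa <= spec.sa_max
    if stage == "qed":
        return entry.qed > spec.qed_min
    if stage == "synth":
        if entry.synth is None:
            raise ConfigError(f"no synth score available for {rec.canonical_key}")
        return entry.synth > spec.synth_min  # type: ignore[operator]
    if stage == "alerts":
        if entry.n_alerts is None:
            hits = structural_alerts(rec, spec.alert_catalogs)
            entry.n_alerts = len(hits)
            if hits:
                report.alert_hits[rec.canonical_key] = hits
        return entry.n_alerts <= spec.max_alerts
    raise ConfigError(f"unknown cascade stage {stage!r}")
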