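"""End-to-end orchestration: curate -> enumerate -> profile -> filter -> chemspace.

A :class:`RunConfig` fixes every input, parameter, and seed; ``run_pipeline``
executes the stages in order, writes every intermediate table, and emits a
manifest with tool versions, seeds, per-stage counts, and file checksums so a
run is fully reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .chemspace import (
    build_descriptor_matrix,
    diversity_summary,
    fingerprint,
    pca_embed,
    shape_profile,
    tree_embed,
    tsne_embed,
)
from .curation import curate_library, read_compounds, write_curated_csv
from .enumeration import EnumerationConfig, enumerate_library
from .filtering import ConfigError, FilterSpec, run_cascade
from .fixtures import builtin_rules
from .molprops import profile_table
from .rules import load_compendium, validate_compendium

logger = logging.getLogger("focuslib.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ChemspaceSettings:
    methods: tuple[str, ...] = ("pca",)
    perplexity: float = 30.0
    k_neighbors: int = 10
    n_conformers: int = 50
    shape_sample: int = 0  # 0 disables PMI profiling in the pipeline


@dataclass
class RunConfig:
    seeds_path: str | None = None
    seed_smiles: tuple[str, ...] = ()
    rules_path: str | None = None  # None: packaged builtin rules
    out_dir: str = "focuslib_run"
    enumeration: EnumerationConfig = field(default_factory=EnumerationConfig)
    filters: FilterSpec = field(default_factory=FilterSpec)
    chemspace: ChemspaceSettings = field(default_factory=ChemspaceSettings)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        enum_cfg = EnumerationConfig(**raw.pop("enumeration", {}))
        filt_raw = raw.pop("filters", {})
        for key in ("alert_catalogs", "stage_order"):
            if key in filt_raw:
                filt_raw[key] = tuple(filt_raw[key])
        filt = FilterSpec(**filt_raw)
        cs_raw = raw.pop("chemspace", {})
        if "methods" in cs_raw:
            cs_raw["methods"] = tuple(cs_raw["methods"])
        chem = ChemspaceSettings(**cs_raw)
        if "seed_smiles" in raw:
            raw["seed_smiles"] = tuple(raw["seed_smiles"])
        return cls(enumeration=enum_cfg, filters=filt, chemspace=chem, **raw)


def validate_config(config: RunConfig) -> None:
    if not config.seeds_path and not config.seed_smiles:
        raise ConfigError("no seed compounds configured (seeds_path or seed_smiles)")
    for path_attr in ("seeds_path", "rules_path"):
        value = getattr(config, path_attr)
        if value is not None and not Path(value).exists():
            raise ConfigError(f"{path_attr} does not exist: {value}")
    unknown = set(config.chemspace.methods) - {"pca", "tsne", "tree"}
    if unknown:
        raise ConfigError(f"unknown chemspace methods: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full workflow; returns (and writes) the run manifest."""
    validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "versions": {
            "focuslib": __version__,
            "python": platform.python_version(),
            "rdkit": _rdkit_version(),
        },
        "seed": config.seed,
        "config": config.to_dict(),
        "counts": {},
        "outputs": {},
    }
    stage = "curate"
    try:
        raw: list[tuple[str, str]] = []
        if config.seeds_path:
            raw.extend(read_compounds(config.seeds_path))
        raw.extend((f"cli-seed-{i}", s) for i, s in enumerate(config.seed_smiles))
        seeds, curation_report = curate_library(raw)
        logger.info("[curate] %d/%d seeds curated", len(seeds), len(raw))
        write_curated_csv(seeds, out / "curated_seeds.csv")
        curation_report.to_json(out / "curation_report.json")
        manifest["counts"]["seeds_in"] = curation_report.n_input
        manifest["counts"]["seeds_curated"] = len(seeds)
        if not seeds:
            raise ValueError("no seed compounds survived curation")

        stage = "rules"
        compendium = (
            load_compendium(config.rules_path) if config.rules_path else builtin_rules()
        )
        rule_report = validate_compendium(compendium)
        rule_report.to_json(out / "rule_validation.json")
        manifest["counts"]["rules"] = len(compendium)
        manifest["counts"]["rules_parsed"] = rule_report.status_counts.get("parsed", 0)
        logger.info("[rules] %d rules (%d usable)", len(compendium),
                    manifest["counts"]["rules_parsed"])

        stage = "enumerate"
        library = enumerate_library(seeds, compendium, config.enumeration)
        library.write_csv(out / "library.csv")
        (out / "enumeration_report.json").write_text(
            json.dumps(
                {
                    "per_iteration_counts": library.per_iteration_counts,
                    "gate_rejections": library.gate_rejections,
                    "n_curation_rejections": library.n_curation_rejections,
                    "n_library": len(library),
                },
                indent=2,
            )
        )
        manifest["counts"]["enumerated"] = len(library)
        manifest["counts"]["gate_rejections"] = sum(library.gate_rejections.values())
        logger.info("[enumerate] %d molecules", len(library))

        stage = "profile"
        records = [er.record for er in library.records]
        profiles = profile_table(records)
        profiles.to_csv(out / "profiles.csv", index=False)

        stage = "filter"
        survivors, cascade = run_cascade(records, config.filters)
        cascade.to_json(out / "cascade_report.json")
        write_curated_csv(survivors, out / "survivors.csv")
        manifest["counts"]["survivors"] = len(survivors)
        manifest["counts"]["filter_rejections"] = dict(cascade.rejected_at)
        logger.info("[filter] %d survivors of %d", len(survivors), cascade.n_input)

        stage = "chemspace"
        if len(records) >= 3 and config.chemspace.methods:
            matrix = build_descriptor_matrix({"enumerated": records})
            if "pca" in config.chemspace.methods:
                emb = pca_embed(matrix)
                emb.to_dataframe().to_csv(out / "pca.csv", index=False)
                manifest["counts"]["pca_explained_variance"] = list(
                    emb.explained_variance or ()
                )
            if "tsne" in config.chemspace.methods and len(records) > config.chemspace.perplexity:
                emb = tsne_embed(matrix, config.chemspace.perplexity, seed=config.seed)
                emb.to_dataframe().to_csv(out / "tsne.csv", index=False)
            if "tree" in config.chemspace.methods and len(records) >= 2:
                fps = [fingerprint(r) for r in records]
                emb = tree_embed(fps, config.chemspace.k_neighbors, seed=config.seed)
                emb.to_dataframe().to_csv(out / "tree.csv", index=False)
            summary = diversity_summary(
                {
                    "enumerated": {
                        col: profiles[col].tolist()
                        for col in ("MW", "TPSA", "logP", "HBA", "HBD", "RotB")
                    }
                }
            )
            summary.to_csv(out / "diversity_summary.csv", index=False)
        if config.chemspace.shape_sample > 0:
            sample = records[: config.chemspace.shape_sample]
            shapes = shape_profile(
                sample, n_conformers=config.chemspace.n_conformers, seed=config.seed
            )
            shapes.to_csv(out / "pmi.csv", index=False)
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _rdkit_version() -> str:
    import rdkit

    return rdkit.__version__
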