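"""Physicochemical descriptors, QED drug-likeness, and synthetic accessibility.

Three layers live here:

* ``compute_profile`` — the seven standard descriptors used throughout the
  library-design workflow (MW, logP, HBA, HBD, TPSA, RotB, stereocenter
  count), computed with their standard published definitions
  (atomic-contribution logP, fragment-contribution TPSA, amide-excluded
  rotatable bonds).

* ``qed`` — the quantitative estimate of drug-likeness: eight property
  desirabilities, each an asymmetric double sigmoid with published
  parameters, aggregated as a weighted geometric mean.  Values near 1 are
  drug-like; >= 0.67 is conventionally "attractive", < 0.49 "too complex".

* ``sa_score`` — fragment-contribution synthetic accessibility on the 1
  (easy) to 10 (hard) scale: a per-atom circular-fragment commonness term
  minus complexity penalties for size, stereocenters, spiro/bridgehead
  atoms, and macrocycles, plus a fingerprint-density symmetry correction.
  The packaged fragment-score table is built from a deterministic synthetic
  drug-like corpus with the standard frequency-scoring procedure (see
  ``build_fragment_scores``); its provenance header is surfaced in every
  report because near-threshold counts depend on the table.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, QED, rdFingerprintGenerator, rdMolDescriptors

from .curation import MoleculeRecord

logger = logging.getLogger("focuslib.molprops")

#: pluggable synthetic-feasibility scorer signature (returns a value in [0, 1])
SynthScorer = Callable[[Chem.Mol], float]


class ResourceError(RuntimeError):
    """A required packaged resource (e.g. the fragment table) is missing."""


# ---------------------------------------------------------------------------
# descriptor profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PropertyProfile:
    MW: float
    logP: float
    HBA: int
    HBD: int
    TPSA: float
    RotB: int
    n_chiral: int


def _as_mol(mol: MoleculeRecord | Chem.Mol) -> Chem.Mol:
    return mol.structure if isinstance(mol, MoleculeRecord) else mol


def count_stereocenters(mol: MoleculeRecord | Chem.Mol) -> int:
    """Stereocenters, counting unassigned potential centers as well."""
    m = _as_mol(mol)
    return len(
        Chem.FindMolChiralCenters(m, includeUnassigned=True, useLegacyImplementation=False)
    )


def compute_profile(mol: MoleculeRecord | Chem.Mol) -> PropertyProfile:
    m = _as_mol(mol)
    # atom order affects float summation order in additive descriptors;
    # reparse in canonical order so equal structures give bitwise-equal profiles
    m = Chem.MolFromSmiles(Chem.MolToSmiles(m)) or m
    return PropertyProfile(
        MW=Descriptors.MolWt(m),
        logP=Crippen.MolLogP(m),
        HBA=Descriptors.NumHAcceptors(m),
        HBD=Descriptors.NumHDonors(m),
        TPSA=rdMolDescriptors.CalcTPSA(m),
        RotB=Descriptors.NumRotatableBonds(m),
        n_chiral=count_stereocenters(m),
    )


# ---------------------------------------------------------------------------
# QED
# ---------------------------------------------------------------------------

#: the eight QED property channels, in canonical order
QED_CHANNELS = ("MW", "ALOGP", "HBA", "HBD", "PSA", "ROTB", "AROM", "ALERTS")

#: default channel weights (the "mean-weight" variant whose 0.67/0.49
#: attractiveness cutpoints are quoted throughout the workflow)
QED_DEFAULT_WEIGHTS = tuple(QED.WEIGHT_MEAN)

_D_FLOOR = 1e-6  # desirabilities are clamped away from zero before the log


def _ads(x: float, p) -> float:
    """Asymmetric double sigmoid desirability with published parameters."""
    exp1 = 1.0 + math.exp(-(x - p.C + p.D / 2.0) / p.E)
    exp2 = 1.0 + math.exp(-(x - p.C - p.D / 2.0) / p.F)
    return (p.A + p.B / exp1 * (1.0 - 1.0 / exp2)) / p.DMAX


def qed_desirabilities(mol: MoleculeRecord | Chem.Mol) -> tuple[float, ...]:
    """The eight per-channel desirability values, each in (0, 1]."""
    props = QED.properties(_as_mol(mol))
    return tuple(
        max(_ads(value, QED.adsParameters[channel]), _D_FLOOR)
        for channel, value in zip(QED_CHANNELS, props)
    )


def qed_from_desirabilities(
    desirabilities: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Weighted geometric mean of desirability values.

    If all desirabilities equal ``d`` the result is ``d`` for any weights.
    """
    w = list(weights) if weights is not None else list(QED_DEFAULT_WEIGHTS)
    if len(w) != len(desirabilities):
        raise ValueError("weights and desirabilities must have equal length")
    total = sum(w)
    return math.exp(
        sum(wi * math.log(max(di, _D_FLOOR)) for wi, di in zip(w, desirabilities)) / total
    )


def qed(mol: MoleculeRecord | Chem.Mol, weights: Sequence[float] | None = None) -> float:
    return qed_from_desirabilities(qed_desirabilities(mol), weights)


# ---------------------------------------------------------------------------
# synthetic accessibility
# ---------------------------------------------------------------------------

_DEFAULT_TABLE_PATH = Path(__file__).parent / "data" / "sa_fragment_scores.tsv"
_morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2)

_fragment_cache: tuple[Path, dict[int, float], str] | None = None

#: score assigned to fragments absent from the table (rare => hard)
SA_UNKNOWN_FRAGMENT_SCORE = -4.0
# raw-score range used to rescale onto [1, 10]
_SA_RAW_MIN, _SA_RAW_MAX = -4.0, 2.5


def build_fragment_scores(
    mols: Iterable[MoleculeRecord | Chem.Mol],
    coverage: float = 0.8,
    min_count: int = 1,
    clip: float = 4.0,
) -> dict[int, float]:
    """Derive fragment commonness scores from a molecule corpus.

    Circular fragments of radius <= 2 are counted over the corpus; each
    fragment scores ``log10(count / ref)`` where ``ref`` is the count of the
    fragment at which the cumulative occurrence total first covers
    ``coverage`` of all occurrences.  Because the log-ratio spread shrinks
    with corpus size, scores are then rescaled linearly so the most common
    fragment maps to ``+clip`` — the dynamic range the downstream [1, 10]
    rescaling window was designed around — and clipped to ``[-clip, clip]``.
    With a curated (non-sampled) corpus every observed fragment is signal,
    so ``min_count`` defaults to 1; fragments never observed fall back to
    the unknown-fragment default at scoring time.
    """
    counts: dict[int, int] = {}
    for mol in mols:
        fp = _morgan.GetSparseCountFingerprint(_as_mol(mol))
        for bit, n in fp.GetNonzeroElements().items():
            counts[bit] = counts.get(bit, 0) + n
    if not counts:
        raise ValueError("empty corpus")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(counts.values())
    cumulative = 0
    ref = ordered[-1][1]
    for _, n in ordered:
        cumulative += n
        if cumulative >= coverage * total:
            ref = n
            break
    max_positive = math.log10(ordered[0][1] / ref)
    scale = clip / max_positive if max_positive > 0 else 1.0
    scores = {
        bit: max(-clip, min(clip, scale * math.log10(n / ref)))
        for bit, n in ordered
        if n >= min_count
    }
    return scores


def write_fragment_table(
    scores: Mapping[int, float], path: str | Path, provenance: str = ""
) -> None:
    lines = [f"# sa-fragment-table v1: {provenance}" if provenance else "# sa-fragment-table v1"]
    lines += [f"{bit}\t{score:.4f}" for bit, score in sorted(scores.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def load_fragment_table(path: str | Path) -> tuple[dict[int, float], str]:
    """Read a fragment-score table (plain or gzipped key-value text)."""
    path = Path(path)
    if not path.exists():
        raise ResourceError(f"fragment table not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    scores: dict[int, float] = {}
    provenance = str(path)
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                provenance = line.lstrip("# ").strip()
                continue
            bit, score = line.split("\t")
            scores[int(bit)] = float(score)
    return scores, provenance


def default_fragment_table() -> tuple[dict[int, float], str]:
    global _fragment_cache
    if _fragment_cache is None or _fragment_cache[0] != _DEFAULT_TABLE_PATH:
        scores, provenance = load_fragment_table(_DEFAULT_TABLE_PATH)
        _fragment_cache = (_DEFAULT_TABLE_PATH, scores, provenance)
    return _fragment_cache[1], _fragment_cache[2]


@dataclass(frozen=True)
class SaComponents:
    """Pre-scaling terms of the synthetic-accessibility score.

    ``spiro_penalty + bridge_penalty`` together form the ring-complexity
    penalty of the published formulation.
    """

    fragment_score: float
    size_penalty: float
    stereo_penalty: float
    spiro_penalty: float
    bridge_penalty: float
    macrocycle_penalty: float

    @property
    def raw(self) -> float:
        return (
            self.fragment_score
            - self.size_penalty
            - self.stereo_penalty
            - self.spiro_penalty
            - self.bridge_penalty
            - self.macrocycle_penalty
        )


def sa_components(
    mol: MoleculeRecord | Chem.Mol, fragment_table: Mapping[int, float] | None = None
) -> SaComponents:
    m = _as_mol(mol)
    if fragment_table is None:
        fragment_table, _ = default_fragment_table()
    fp = _morgan.GetSparseCountFingerprint(m)
    bits = fp.GetNonzeroElements()
    n_frag = sum(bits.values())
    frag_score = (
        sum(fragment_table.get(bit, SA_UNKNOWN_FRAGMENT_SCORE) * n for bit, n in bits.items())
        / n_frag
        if n_frag
        else 0.0
    )
    n_atoms = m.GetNumAtoms()
    ring_info = m.GetRingInfo()
    n_macro = sum(1 for ring in ring_info.AtomRings() if len(ring) > 8)
    components = SaComponents(
        fragment_score=frag_score,
        size_penalty=n_atoms**1.005 - n_atoms,
        stereo_penalty=math.log10(count_stereocenters(m) + 1),
        spiro_penalty=math.log10(rdMolDescriptors.CalcNumSpiroAtoms(m) + 1),
        bridge_penalty=math.log10(rdMolDescriptors.CalcNumBridgeheadAtoms(m) + 1),
        macrocycle_penalty=math.log10(n_macro + 1),
    )
    return components


def sa_score(
    mol: MoleculeRecord | Chem.Mol, fragment_table: Mapping[int, float] | None = None
) -> float:
    """Synthetic-accessibility score on [1, 10]; lower is easier to make."""
    raw = sa_components(mol, fragment_table).raw
    score = 11.0 - (raw - _SA_RAW_MIN + 1.0) / (_SA_RAW_MAX - _SA_RAW_MIN) * 9.0
    if score > 8.0:  # smooth the hard end
        score = 8.0 + math.log(score + 1.0 - 9.0)
    return min(10.0, max(1.0, score))


# ---------------------------------------------------------------------------
# combined scoring / batch interface
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DruglikenessScores:
    qed: float
    sa_score: float
    synth_feasibility: float | None = None


def compute_scores(
    mol: MoleculeRecord | Chem.Mol,
    fragment_table: Mapping[int, float] | None = None,
    synth_scorer: SynthScorer | None = None,
) -> DruglikenessScores:
    m = _as_mol(mol)
    return DruglikenessScores(
        qed=qed(m),
        sa_score=sa_score(m, fragment_table),
        synth_feasibility=synth_scorer(m) if synth_scorer is not None else None,
    )


def profile_table(
    records: Sequence[MoleculeRecord],
    fragment_table: Mapping[int, float] | None = None,
    synth_scorer: SynthScorer | None = None,
) -> pd.DataFrame:
    """Batch profile: one row per record with descriptors and scores."""
    rows = []
    for rec in records:
        profile = compute_profile(rec)
        scores = compute_scores(rec, fragment_table, synth_scorer)
        rows.append(
            {
                "id": rec.source_id,
                "canonical_key": rec.canonical_key,
                "MW": profile.MW,
                "logP": profile.logP,
                "HBA": profile.HBA,
                "HBD": profile.HBD,
                "TPSA": profile.TPSA,
                "RotB": profile.RotB,
                "n_chiral": profile.n_chiral,
                "qed": scores.qed,
                "sa_score": scores.sa_score,
                "synth_feasibility": scores.synth_feasibility,
            }
        )
    columns = [
        "id", "canonical_key", "MW", "logP", "HBA", "HBD", "TPSA", "RotB",
        "n_chiral", "qed", "sa_score", "synth_feasibility",
    ]
    return pd.DataFrame(rows, columns=columns)
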