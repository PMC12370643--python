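"""Bioactivity record ingestion and reference-library curation.

Raw ligand-target bioactivity measurements (IC50 / Ki / Kd / EC50, possibly
from several sources) are pooled per (ligand, target) pair and curated with
three rules:

1. concordance — the pair is kept only if all its measurements agree to
   within one order of magnitude (max/min <= 10);
2. consolidation — the median of the concordant measurements is the
   definitive activity;
3. potency — only pairs with median activity below 1 uM (1000 nM) enter the
   reference library.

The result is an immutable :class:`ReferenceLibrary` with standardized
structures and a per-target ligand index.
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .chem import standardize_smiles

logger = logging.getLogger(__name__)

#: Potency cutoff: interactions at or above 1 uM are discarded.
POTENCY_CUTOFF_NM = 1000.0
#: Concordance: measurements for one pair may span at most one order of
#: magnitude (inclusive).
MAX_FOLD_SPREAD = 10.0

ACTIVITY_TYPES = ("IC50", "Ki", "Kd", "EC50")

#: Conversion factors to nanomolar.
_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "M": 1e9}


class CurationDecision(str, Enum):
    KEEP = "keep"
    DISCARD_DISCORDANT = "discard_discordant"
    DISCARD_WEAK = "discard_weak"


@dataclass(frozen=True)
class BioactivityRecord:
    """One raw activity measurement for a ligand-target pair."""

    ligand_id: str
    smiles: str
    target_id: str
    activity_type: str  # IC50 | Ki | Kd | EC50
    value: float
    unit: str  # nM | uM | M
    source: str = ""
    target_class: str | None = None

    def __post_init__(self) -> None:
        if self.activity_type not in ACTIVITY_TYPES:
            raise ValueError(f"unknown activity type: {self.activity_type!r}")
        if self.value <= 0:
            raise ValueError(f"activity value must be positive: {self.value}")


@dataclass(frozen=True)
class CuratedInteraction:
    """A kept ligand-target interaction with consolidated activity."""

    ligand_id: str
    target_id: str
    activity_nM: float
    n_measurements: int

    def __post_init__(self) -> None:
        if not 0 < self.activity_nM < POTENCY_CUTOFF_NM:
            raise ValueError(
                f"curated activity must lie in (0, {POTENCY_CUTOFF_NM}) nM, "
                f"got {self.activity_nM}"
            )
        if self.n_measurements < 1:
            raise ValueError("n_measurements must be >= 1")


def normalize_activity(record: BioactivityRecord) -> float:
    """Express a record's activity value in nM."""
    try:
        factor = _UNIT_TO_NM[record.unit]
    except KeyError:
        raise ValueError(f"unknown activity unit: {record.unit!r}") from None
    return record.value * factor


@dataclass(frozen=True)
class PairCuration:
    decision: CurationDecision
    activity_nM: float | None  # median; set only for KEEP
    n_measurements: int


def curate_pair(measurements_nM: list[float]) -> PairCuration:
    """Apply concordance, median consolidation, and the potency cutoff.

    ``measurements_nM`` pools every measurement for one (ligand, target)
    pair across activity types and sources.  Discordant pairs (spread
    beyond 10x) are discarded outright; concordant pairs are consolidated
    to their median and kept only below 1 uM.
    """
    if not measurements_nM:
        raise ValueError("cannot curate an empty measurement set")
    if any(v <= 0 for v in measurements_nM):
        raise ValueError("measurements must be positive")
    if max(measurements_nM) / min(measurements_nM) > MAX_FOLD_SPREAD:
        return PairCuration(CurationDecision.DISCARD_DISCORDANT, None,
                            len(measurements_nM))
    med = statistics.median(measurements_nM)
    if med >= POTENCY_CUTOFF_NM:
        return PairCuration(CurationDecision.DISCARD_WEAK, None,
                            len(measurements_nM))
    return PairCuration(CurationDecision.KEEP, med, len(measurements_nM))


@dataclass
class CurationLog:
    """Counts of what was kept and what was dropped, with reasons."""

    n_records: int = 0
    n_pairs: int = 0
    kept: int = 0
    discard_discordant: int = 0
    discard_weak: int = 0
    bad_unit_records: int = 0
    unparseable_ligands: int = 0
    unpredictable_targets: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_pairs": self.n_pairs,
            "kept": self.kept,
            "discard_discordant": self.discard_discordant,
            "discard_weak": self.discard_weak,
            "bad_unit_records": self.bad_unit_records,
            "unparseable_ligands": self.unparseable_ligands,
            "unpredictable_targets": sorted(self.unpredictable_targets),
        }


@dataclass(frozen=True)
class ReferenceLibrary:
    """Immutable curated ligand/target/interaction store.

    ``ligands`` maps ligand_id -> standardized canonical SMILES;
    ``targets`` maps target_id -> optional class label; ``target_index``
    maps target_id -> sorted tuple of ligand ids with a kept interaction.
    """

    ligands: dict[str, str]
    targets: dict[str, str | None]
    interactions: tuple[CuratedInteraction, ...]
    target_index: dict[str, tuple[str, ...]]
    curation_log: CurationLog | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for it in self.interactions:
            key = (it.ligand_id, it.target_id)
            if key in seen:
                raise ValueError(f"duplicate interaction {key}")
            seen.add(key)
            if it.ligand_id not in self.ligands:
                raise ValueError(f"interaction references unknown ligand {it.ligand_id}")
            if it.target_id not in self.targets:
                raise ValueError(f"interaction references unknown target {it.target_id}")
        # index consistency
        derived: dict[str, set[str]] = {}
        for it in self.interactions:
            derived.setdefault(it.target_id, set()).add(it.ligand_id)
        for tid, lids in self.target_index.items():
            if set(lids) != derived.get(tid, set()):
                raise ValueError(f"per-target index inconsistent for {tid}")

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def predictable_targets(self) -> list[str]:
        """Targets that have at least one reference ligand."""
        return sorted(t for t, lids in self.target_index.items() if lids)

    def known_targets_of(self, ligand_id: str) -> frozenset[str]:
        return frozenset(
            it.target_id for it in self.interactions if it.ligand_id == ligand_id
        )

    def as_records(self) -> list[BioactivityRecord]:
        """Re-emit the library as one IC50 record per kept interaction."""
        return [
            BioactivityRecord(
                ligand_id=it.ligand_id,
                smiles=self.ligands[it.ligand_id],
                target_id=it.target_id,
                activity_type="IC50",
                value=it.activity_nM,
                unit="nM",
                source="library",
                target_class=self.targets[it.target_id],
            )
            for it in self.interactions
        ]

    # -- serialization ------------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        """Write ligands.tsv / targets.tsv / interactions.tsv + manifest.

        Rows are written in sorted order so that serialization is a pure
        function of library content (record input order never leaks).
        """
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        lig = pd.DataFrame(
            sorted(self.ligands.items()), columns=["ligand_id", "smiles"]
        )
        lig.to_csv(path / "ligands.tsv", sep="\t", index=False)
        tgt = pd.DataFrame(
            sorted((t, c if c is not None else "") for t, c in self.targets.items()),
            columns=["target_id", "target_class"],
        )
        tgt.to_csv(path / "targets.tsv", sep="\t", index=False)
        ints = pd.DataFrame(
            sorted(
                (it.ligand_id, it.target_id, it.activity_nM, it.n_measurements)
                for it in self.interactions
            ),
            columns=["ligand_id", "target_id", "activity_nM", "n_measurements"],
        )
        ints.to_csv(path / "interactions.tsv", sep="\t", index=False)
        manifest = {
            "n_ligands": self.n_ligands,
            "n_targets": self.n_targets,
            "n_interactions": len(self.interactions),
            "curation": self.curation_log.as_dict() if self.curation_log else None,
        }
        (path / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_dir(cls, path: str | Path) -> "ReferenceLibrary":
        path = Path(path)
        lig = pd.read_csv(path / "ligands.tsv", sep="\t", dtype=str)
        tgt = pd.read_csv(
            path / "targets.tsv", sep="\t", dtype=str, keep_default_na=False
        )
        ints = pd.read_csv(path / "interactions.tsv", sep="\t", dtype=str)
        ligands = dict(zip(lig["ligand_id"], lig["smiles"]))
        targets = {
            r.target_id: (r.target_class or None) for r in tgt.itertuples()
        }
        interactions = tuple(
            CuratedInteraction(
                ligand_id=r.ligand_id,
                target_id=r.target_id,
                activity_nM=float(r.activity_nM),
                n_measurements=int(r.n_measurements),
            )
            for r in ints.itertuples()
        )
        index: dict[str, set[str]] = {t: set() for t in targets}
        for it in interactions:
            index[it.target_id].add(it.ligand_id)
        target_index = {t: tuple(sorted(s)) for t, s in index.items()}
        return cls(ligands, targets, interactions, target_index)


def build_library(records: list[BioactivityRecord]) -> ReferenceLibrary:
    """Curate raw records into a reference library.

    Groups measurements by (ligand_id, target_id), applies
    :func:`curate_pair`, standardizes structures, and indexes ligands per
    target.  The result is independent of record input order.  Ligands with
    unparseable SMILES are dropped (counted in the log); targets whose every
    pair was discarded stay in the target set but are flagged unpredictable.
    """
    log = CurationLog(n_records=len(records))

    # Standardize each ligand once; first parseable SMILES per id wins.
    smiles_by_ligand: dict[str, str] = {}
    bad_ligands: set[str] = set()
    for rec in sorted(records, key=lambda r: (r.ligand_id, r.smiles)):
        if rec.ligand_id in smiles_by_ligand or rec.ligand_id in bad_ligands:
            continue
        std = standardize_smiles(rec.smiles)
        if std is None:
            bad_ligands.add(rec.ligand_id)
        else:
            smiles_by_ligand[rec.ligand_id] = std
    log.unparseable_ligands = len(bad_ligands)
    if bad_ligands:
        logger.warning("dropped %d ligands with unparseable SMILES", len(bad_ligands))

    targets: dict[str, str | None] = {}
    pairs: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        targets.setdefault(rec.target_id, rec.target_class)
        if rec.target_class is not None and targets[rec.target_id] is None:
            targets[rec.target_id] = rec.target_class
        if rec.ligand_id in bad_ligands:
            continue
        try:
            nm = normalize_activity(rec)
        except ValueError as exc:
            log.bad_unit_records += 1
            logger.warning("rejected record %s/%s: %s", rec.ligand_id, rec.target_id, exc)
            continue
        pairs.setdefault((rec.ligand_id, rec.target_id), []).append(nm)

    log.n_pairs = len(pairs)
    interactions: list[CuratedInteraction] = []
    for (lid, tid), values in sorted(pairs.items()):
        result = curate_pair(values)
        if result.decision is CurationDecision.KEEP:
            log.kept += 1
            interactions.append(
                CuratedInteraction(lid, tid, result.activity_nM, result.n_measurements)
            )
        elif result.decision is CurationDecision.DISCARD_DISCORDANT:
            log.discard_discordant += 1
        else:
            log.discard_weak += 1

    kept_ligands = {it.ligand_id for it in interactions}
    ligands = {lid: smiles_by_ligand[lid] for lid in sorted(kept_ligands)}

    index: dict[str, set[str]] = {t: set() for t in targets}
    for it in interactions:
        index[it.target_id].add(it.ligand_id)
    target_index = {t: tuple(sorted(s)) for t, s in index.items()}
    log.unpredictable_targets = sorted(t for t, s in index.items() if not s)
    if log.unpredictable_targets:
        logger.warning(
            "%d targets retained with zero ligands (unpredictable)",
            len(log.unpredictable_targets),
        )

    return ReferenceLibrary(
        ligands=ligands,
        targets=dict(sorted(targets.items())),
        interactions=tuple(interactions),
        target_index=target_index,
        curation_log=log,
    )


# ---------------------------------------------------------------------------
# Raw record I/O
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "ligand_id", "smiles", "target_id", "activity_type", "value", "unit", "source",
]


def read_records(path: str | Path) -> list[BioactivityRecord]:
    """Read raw bioactivity records from a delimited text file.

    Tab- or comma-separated with a header; required columns are
    ``ligand_id, smiles, target_id, activity_type, value, unit, source``
    and ``target_class`` is optional.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")
    has_class = "target_class" in df.columns
    records = []
    for row in df.itertuples():
        records.append(
            BioactivityRecord(
                ligand_id=row.ligand_id,
                smiles=row.smiles,
                target_id=row.target_id,
                activity_type=row.activity_type,
                value=float(row.value),
                unit=row.unit,
                source=row.source,
                target_class=(row.target_class or None) if has_class else None,
            )
        )
    return records


def write_records(records: list[BioactivityRecord], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.DataFrame(
        [
            {
                "ligand_id": r.ligand_id,
                "smiles": r.smiles,
                "target_id": r.target_id,
                "activity_type": r.activity_type,
                "value": repr(r.value),
                "unit": r.unit,
                "source": r.source,
                "target_class": r.target_class or "",
            }
            for r in records
        ]
    )
    df.to_csv(path, sep=sep, index=False)


def read_sdf_structures(path: str | Path, id_prop: str = "ligand_id") -> dict[str, str]:
    """Read ligand structures from an SDF; returns ligand_id -> SMILES."""
    out: dict[str, str] = {}
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            continue
        if mol.HasProp(id_prop):
            lid = mol.GetProp(id_prop)
        elif mol.HasProp("_Name") and mol.GetProp("_Name"):
            lid = mol.GetProp("_Name")
        else:
            continue
        out[lid] = Chem.MolToSmiles(mol)
    return out
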