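"""Seeded synthetic bioactivity libraries for testing and validation.

Real target-fishing reference libraries cluster chemically: each target's
ligand set is dominated by a few chemotypes (shared Murcko scaffolds), a
minority of ligands bind several targets, and activity values arrive as
replicate measurements from multiple sources, some discordant and some too
weak to keep.  The generator reproduces exactly that structure at desk
scale:

* each target family is built from a distinct parent ring system; its
  scaffolds are ring-substituted variants of that parent and its ligands
  are acyclic substituent decorations of those scaffolds, so within-family
  fingerprint similarity is high and cross-family similarity low by
  construction;
* a controlled fraction of ligands is promiscuous (assigned to extra
  targets);
* replicate activity values are drawn multiplicatively (log-normal) with a
  spread safely inside the 10x concordance rule; discordant pairs are
  forced by injecting one outlier replicate beyond 10x, and weak pairs are
  sampled above the 1 uM cutoff, so every pair's curation outcome is known
  at generation time.

Everything is driven by one integer seed; the same spec and seed produce
bit-identical fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import scaffold_key
from .curation import ACTIVITY_TYPES, BioactivityRecord, CurationDecision
from .evaluation import ValidationQuery

#: Parent ring systems, one per target family, ordered so that the leading
#: cores (used first) are mutually dissimilar chemotypes.
PARENT_CORES: tuple[str, ...] = (
    "c1ccc2ccccc2c1",        # naphthalene
    "c1ccc2c(c1)OCO2",       # benzodioxole
    "C1CCC(N2CCCC2)CC1",     # 1-cyclohexylpyrrolidine
    "c1ccc2sccc2c1",         # benzothiophene
    "c1ccc2c(c1)CCC2",       # indane
    "c1ccc(-c2ccccc2)cc1",   # biphenyl
    "c1ccc2[nH]cnc2c1",      # benzimidazole
    "c1ccc2occc2c1",         # benzofuran
    "c1ccc2ncccc2c1",        # quinoline
    "c1ccc2[nH]ccc2c1",      # indole
    "c1ccc2nccnc2c1",        # quinoxaline
    "c1ccc2cnccc2c1",        # isoquinoline
)

#: Ring substituents that create distinct in-family scaffolds
#: (attachment atom written first); each family uses its own fragment.
RING_FRAGMENTS: tuple[str, ...] = (
    "C1CC1", "C1CCCC1", "N1CCOCC1", "c1ccncc1", "C1CCNCC1", "c1ccsc1",
)

#: Acyclic decorations: these never change the Murcko scaffold.  Each
#: family draws from its own 3-substituent slice (families have their own
#: substituent preferences, like real congeneric series), which keeps
#: cross-family similarity low.
DECORATIONS: tuple[str, ...] = (
    "C", "CC", "O", "N", "F", "Cl", "Br", "OC", "C(C)C", "C#N",
    "[N+](=O)[O-]", "C(F)(F)F", "OCC", "CCC", "C(C)=O",
)

#: Width of the per-family decoration slice.
DECOR_SLICE = 3


def family_decorations(family: int) -> tuple[str, ...]:
    """The decoration sub-alphabet of one target family."""
    n_slices = len(DECORATIONS) // DECOR_SLICE
    start = (family % n_slices) * DECOR_SLICE
    return DECORATIONS[start : start + DECOR_SLICE]

TARGET_CLASSES: tuple[str, ...] = ("enzyme", "gpcr", "ion_channel", "transporter")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic library."""

    n_targets: int = 5
    scaffolds_per_target: int = 4
    ligands_per_scaffold: int = 5
    promiscuous_fraction: float = 0.10
    targets_per_promiscuous: int = 2
    replicate_counts: tuple[int, ...] = (1, 2, 3)
    replicate_probs: tuple[float, ...] = (0.5, 0.3, 0.2)
    discordant_fraction: float = 0.05
    weak_fraction: float = 0.05
    activity_log10_mean: float = 1.7   # ~50 nM typical potency
    activity_log10_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.n_targets > len(PARENT_CORES):
            raise ValueError(
                f"n_targets must be in [1, {len(PARENT_CORES)}]"
            )
        if not 1 <= self.scaffolds_per_target <= len(RING_FRAGMENTS) + 1:
            raise ValueError("too many scaffolds per target")
        if self.ligands_per_scaffold < 1:
            raise ValueError("need at least one ligand per scaffold")
        for frac in (self.promiscuous_fraction, self.discordant_fraction,
                     self.weak_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.discordant_fraction + self.weak_fraction > 1:
            raise ValueError("discordant + weak fractions exceed 1")
        if self.targets_per_promiscuous > self.n_targets:
            raise ValueError(
                "promiscuous ligands cannot bind more targets than exist"
            )
        if len(self.replicate_counts) != len(self.replicate_probs):
            raise ValueError("replicate distribution lengths differ")
        if abs(sum(self.replicate_probs) - 1.0) > 1e-9:
            raise ValueError("replicate probabilities must sum to 1")


@dataclass
class FixtureGroundTruth:
    """Generator bookkeeping: what the curated library must look like."""

    spec: FixtureSpec
    ligand_smiles: dict[str, str]
    ligand_family: dict[str, int]            # ligand -> parent family index
    ligand_scaffold: dict[str, str]          # ligand -> scaffold key
    family_target: dict[int, str]            # family index -> target id
    family_scaffolds: dict[int, list[str]]   # family index -> scaffold SMILES
    target_classes: dict[str, str]
    pair_outcome: dict[tuple[str, str], CurationDecision]
    pair_targets: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n_keep(self) -> int:
        return sum(
            1 for d in self.pair_outcome.values() if d is CurationDecision.KEEP
        )

    @property
    def n_discordant(self) -> int:
        return sum(
            1 for d in self.pair_outcome.values()
            if d is CurationDecision.DISCARD_DISCORDANT
        )

    @property
    def n_weak(self) -> int:
        return sum(
            1 for d in self.pair_outcome.values()
            if d is CurationDecision.DISCARD_WEAK
        )


def _attach(mol: Chem.Mol, atom_idx: int, frag_smiles: str) -> Chem.Mol:
    """Bond a fragment (attachment atom first in its SMILES) to an atom."""
    frag = Chem.MolFromSmiles(frag_smiles)
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(atom_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


def _open_positions(mol: Chem.Mol) -> list[int]:
    """Carbon atoms with at least one hydrogen to substitute."""
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]


def _family_scaffolds(family: int, n_scaffolds: int) -> list[str]:
    """Scaffold variants of one parent core: the bare core plus ring adducts.

    Each family attaches its own ring fragment at different core positions
    (position changes the Murcko framework), mimicking a congeneric series:
    scaffolds within a family stay similar to each other while families
    share no ring chemistry beyond their decorations.
    """
    core = Chem.MolFromSmiles(PARENT_CORES[family])
    out = [Chem.MolToSmiles(core)]
    frag = RING_FRAGMENTS[family % len(RING_FRAGMENTS)]
    seen = set(out)
    positions = _open_positions(core)
    # mono-substituted variants first, then di-substituted ones; symmetric
    # positions collapse to one canonical scaffold and are skipped
    candidates = [(p,) for p in positions]
    candidates += [
        (positions[i], positions[j])
        for i in range(len(positions))
        for j in range(i + 1, len(positions))
    ]
    for combo in candidates:
        if len(out) == n_scaffolds:
            break
        mol = core
        for pos in combo:
            mol = _attach(mol, pos, frag)
        smi = Chem.MolToSmiles(mol)
        if smi not in seen:
            seen.add(smi)
            out.append(smi)
    if len(out) < n_scaffolds:
        raise ValueError(
            f"core {PARENT_CORES[family]} supports only {len(out)} distinct scaffolds"
        )
    return out


def _decorate(
    scaffold_smiles: str,
    rng: np.random.Generator,
    taken: set[str],
    alphabet: tuple[str, ...] = DECORATIONS,
) -> str | None:
    """One new decorated analog of a scaffold, distinct from ``taken``."""
    base = Chem.MolFromSmiles(scaffold_smiles)
    for _ in range(200):
        mol = base
        positions = _open_positions(mol)
        n_dec = int(rng.integers(1, min(2, len(positions)) + 1))
        pos_choice = rng.choice(len(positions), size=n_dec, replace=False)
        ok = True
        for j in sorted((int(p) for p in pos_choice), reverse=True):
            frag = alphabet[int(rng.integers(len(alphabet)))]
            try:
                mol = _attach(mol, positions[j], frag)
            except Exception:
                ok = False
                break
        if not ok:
            continue
        smi = Chem.MolToSmiles(mol)
        if smi not in taken:
            taken.add(smi)
            return smi
    return None


def _sample_replicates(
    base_nM: float, n_rep: int, rng: np.random.Generator
) -> list[float]:
    """Replicates within +-0.15 log units of the base (spread << 10x)."""
    return [
        float(base_nM * 10 ** rng.uniform(-0.15, 0.15)) for _ in range(n_rep)
    ]


def generate_library(
    spec: FixtureSpec,
) -> tuple[list[BioactivityRecord], FixtureGroundTruth]:
    """Generate raw bioactivity records plus their ground truth.

    The discordant and weak pair counts equal ``round(fraction * n_pairs)``
    exactly; every other pair is concordant and potent by construction, so
    curation outcomes are known pair-for-pair before curation runs.
    """
    rng = np.random.default_rng(spec.seed)

    family_target = {
        f: f"T{f:02d}" for f in range(spec.n_targets)
    }
    target_classes = {
        family_target[f]: TARGET_CLASSES[f % len(TARGET_CLASSES)]
        for f in range(spec.n_targets)
    }
    family_scaffolds = {
        f: _family_scaffolds(f, spec.scaffolds_per_target)
        for f in range(spec.n_targets)
    }

    # ligands: decorated analogs per scaffold
    ligand_smiles: dict[str, str] = {}
    ligand_family: dict[str, int] = {}
    ligand_scaffold: dict[str, str] = {}
    taken: set[str] = set()
    lig_counter = 0
    for f in range(spec.n_targets):
        for scaf in family_scaffolds[f]:
            for _ in range(spec.ligands_per_scaffold):
                smi = _decorate(scaf, rng, taken, family_decorations(f))
                if smi is None:
                    raise RuntimeError(
                        f"could not generate a fresh analog of {scaf}"
                    )
                lid = f"L{lig_counter:04d}"
                lig_counter += 1
                ligand_smiles[lid] = smi
                ligand_family[lid] = f
                ligand_scaffold[lid] = scaffold_key(smi)

    # pair assignments: own family target, plus extra targets for the
    # promiscuous minority
    ligand_ids = sorted(ligand_smiles)
    pair_targets: dict[str, set[str]] = {
        lid: {family_target[ligand_family[lid]]} for lid in ligand_ids
    }
    n_prom = int(round(spec.promiscuous_fraction * len(ligand_ids)))
    prom_ids = rng.choice(len(ligand_ids), size=n_prom, replace=False)
    for idx in sorted(int(i) for i in prom_ids):
        lid = ligand_ids[idx]
        others = [
            family_target[f]
            for f in range(spec.n_targets)
            if family_target[f] not in pair_targets[lid]
        ]
        extra = rng.choice(
            len(others), size=spec.targets_per_promiscuous - 1, replace=False
        )
        pair_targets[lid].update(others[int(i)] for i in extra)

    pairs = sorted(
        (lid, tid) for lid in ligand_ids for tid in pair_targets[lid]
    )

    # exact discordant / weak counts
    n_pairs = len(pairs)
    n_disc = int(round(spec.discordant_fraction * n_pairs))
    n_weak = int(round(spec.weak_fraction * n_pairs))
    special = rng.choice(n_pairs, size=n_disc + n_weak, replace=False)
    disc_set = {pairs[int(i)] for i in special[:n_disc]}
    weak_set = {pairs[int(i)] for i in special[n_disc:]}

    records: list[BioactivityRecord] = []
    pair_outcome: dict[tuple[str, str], CurationDecision] = {}
    for lid, tid in pairs:
        n_rep = int(
            rng.choice(spec.replicate_counts, p=spec.replicate_probs)
        )
        if (lid, tid) in disc_set:
            outcome = CurationDecision.DISCARD_DISCORDANT
            base = float(
                np.clip(10 ** rng.normal(spec.activity_log10_mean,
                                         spec.activity_log10_sd), 1.0, 500.0)
            )
            values = _sample_replicates(base, max(2, n_rep), rng)
            values[-1] *= 30.0  # outlier: spread is >= 30/10^0.3 ~ 15x
        elif (lid, tid) in weak_set:
            outcome = CurationDecision.DISCARD_WEAK
            base = float(rng.uniform(3000.0, 50000.0))
            values = _sample_replicates(base, n_rep, rng)
        else:
            outcome = CurationDecision.KEEP
            base = float(
                np.clip(10 ** rng.normal(spec.activity_log10_mean,
                                         spec.activity_log10_sd), 1.0, 500.0)
            )
            values = _sample_replicates(base, n_rep, rng)
        pair_outcome[(lid, tid)] = outcome
        for r, nm in enumerate(values):
            in_uM = rng.random() < 0.5
            records.append(
                BioactivityRecord(
                    ligand_id=lid,
                    smiles=ligand_smiles[lid],
                    target_id=tid,
                    activity_type=ACTIVITY_TYPES[
                        int(rng.integers(len(ACTIVITY_TYPES)))
                    ],
                    value=nm / 1e3 if in_uM else nm,
                    unit="uM" if in_uM else "nM",
                    source=f"src{r}",
                    target_class=target_classes[tid],
                )
            )

    truth = FixtureGroundTruth(
        spec=spec,
        ligand_smiles=ligand_smiles,
        ligand_family=ligand_family,
        ligand_scaffold=ligand_scaffold,
        family_target=family_target,
        family_scaffolds=family_scaffolds,
        target_classes=target_classes,
        pair_outcome=pair_outcome,
        pair_targets=pair_targets,
    )
    return records, truth


def generate_queries(
    truth: FixtureGroundTruth, holdout_fraction: float, seed: int
) -> list[ValidationQuery]:
    """Held-out decorated analogs per family, with their answer key.

    Queries are fresh decorations of the family scaffolds that do not
    occur in the reference library, so they are true external analogs;
    each query's known targets are its family's target.
    """
    if not 0 <= holdout_fraction <= 1:
        raise ValueError("holdout_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    taken = set(truth.ligand_smiles.values())
    queries: list[ValidationQuery] = []
    q_counter = 0
    for f in sorted(truth.family_target):
        family_ligands = [
            lid for lid, fam in truth.ligand_family.items() if fam == f
        ]
        if not family_ligands:
            raise ValueError(f"family {f} has no ligands to hold out against")
        n_queries = int(round(holdout_fraction * len(family_ligands)))
        scaffolds = truth.family_scaffolds[f]
        for _ in range(n_queries):
            scaf = scaffolds[int(rng.integers(len(scaffolds)))]
            smi = _decorate(scaf, rng, taken, family_decorations(f))
            if smi is None:
                raise RuntimeError(
                    f"could not generate a fresh query analog of {scaf}"
                )
            queries.append(
                ValidationQuery(
                    ligand_id=f"Q{q_counter:04d}",
                    smiles=smi,
                    known_targets=frozenset({truth.family_target[f]}),
                )
            )
            q_counter += 1
    return queries
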