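"""Molecular standardization, fingerprints, Tanimoto similarity, and scaffolds.

Eight 2D fingerprint types are supported, each folded to a fixed bit length
(1024 bits for all hashed types, 166 for the predefined MACCS substructure
keys).  Fingerprints are held as dense ``numpy`` boolean vectors so that a
whole library can be stacked into a matrix and compared against a query in a
single vectorized pass.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from enum import Enum

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

#: Scaffold-map key used for molecules with no ring system (empty Murcko
#: framework).  Keeping them under one explicit key makes the scaffold map a
#: partition of the ligand set.
ACYCLIC_SCAFFOLD_KEY = "<acyclic>"


class FingerprintKind(str, Enum):
    """The eight 2D fingerprint types used for target fishing."""

    ATOMPAIR = "AtomPair"
    AVALON = "Avalon"
    ECFP4 = "ECFP4"
    FCFP4 = "FCFP4"
    RDKIT = "RDKitPath"
    LAYERED = "Layered"
    MACCS = "MACCS"
    TORSION = "Torsion"

    @classmethod
    def parse(cls, name: str) -> "FingerprintKind":
        for kind in cls:
            if kind.value.lower() == name.lower():
                return kind
        raise ValueError(f"unknown fingerprint kind: {name!r}")


#: Bit lengths per kind.  All hashed fingerprints are folded to 1024 bits;
#: MACCS is the fixed 166-key substructure set.
N_BITS: dict[FingerprintKind, int] = {
    FingerprintKind.ATOMPAIR: 1024,
    FingerprintKind.AVALON: 1024,
    FingerprintKind.ECFP4: 1024,
    FingerprintKind.FCFP4: 1024,
    FingerprintKind.RDKIT: 1024,
    FingerprintKind.LAYERED: 1024,
    FingerprintKind.MACCS: 166,
    FingerprintKind.TORSION: 1024,
}

ALL_KINDS: tuple[FingerprintKind, ...] = tuple(FingerprintKind)


@dataclass(frozen=True)
class FingerprintConfig:
    kind: FingerprintKind
    n_bits: int = -1  # -1 -> canonical length for the kind

    def __post_init__(self) -> None:
        if self.n_bits == -1:
            object.__setattr__(self, "n_bits", N_BITS[self.kind])
        if self.n_bits != N_BITS[self.kind]:
            raise ValueError(
                f"{self.kind.value} fingerprints use {N_BITS[self.kind]} bits, "
                f"got {self.n_bits}"
            )


@dataclass(frozen=True, eq=False)
class Fingerprint:
    """A fixed-length binary fingerprint for one molecule."""

    config: FingerprintConfig
    bits: np.ndarray

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return self.config == other.config and np.array_equal(
            self.bits, other.bits
        )

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=bool)
        if bits.ndim != 1 or bits.size != self.config.n_bits:
            raise ValueError(
                f"expected {self.config.n_bits} bits, got shape {bits.shape}"
            )
        object.__setattr__(self, "bits", bits)


class FingerprintError(RuntimeError):
    """Raised when a fingerprint cannot be computed for a molecule."""


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_mol(mol: Chem.Mol) -> Chem.Mol:
    """Standardize a molecule before identity checks and fingerprinting.

    Keeps the largest organic fragment, neutralizes charges where the
    valence allows, and re-canonicalizes.
    """
    mol = _LARGEST_FRAGMENT.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    Chem.SanitizeMol(mol)
    return mol


def standardize_smiles(smiles: str) -> str | None:
    """Canonical SMILES of the standardized structure, or None if unparseable."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    try:
        return Chem.MolToSmiles(standardize_mol(mol))
    except Exception:
        return None


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


# ---------------------------------------------------------------------------
# Fingerprint computation
# ---------------------------------------------------------------------------

def _generators() -> dict[FingerprintKind, object]:
    fg = rdFingerprintGenerator
    return {
        FingerprintKind.ATOMPAIR: fg.GetAtomPairGenerator(fpSize=1024),
        FingerprintKind.ECFP4: fg.GetMorganGenerator(radius=2, fpSize=1024),
        FingerprintKind.FCFP4: fg.GetMorganGenerator(
            radius=2,
            fpSize=1024,
            atomInvariantsGenerator=fg.GetMorganFeatureAtomInvGen(),
        ),
        FingerprintKind.RDKIT: fg.GetRDKitFPGenerator(fpSize=1024),
        FingerprintKind.TORSION: fg.GetTopologicalTorsionGenerator(fpSize=1024),
    }


_GENERATORS = _generators()


def _bitvect_to_array(bv, n_bits: int) -> np.ndarray:
    arr = np.zeros(n_bits, dtype=bool)
    arr[list(bv.GetOnBits())] = True
    return arr


def compute_fingerprint(
    mol: Chem.Mol, config: FingerprintConfig | FingerprintKind
) -> Fingerprint:
    """Compute one fingerprint for a (standardized) molecule.

    ECFP4/FCFP4 are circular fingerprints of radius 2 (diameter 4).  The
    RDKit MACCS implementation reserves bit 0, which is never set; it is
    dropped so the vector has exactly the 166 defined keys.
    """
    if isinstance(config, FingerprintKind):
        config = FingerprintConfig(config)
    kind = config.kind
    try:
        if kind in _GENERATORS:
            bv = _GENERATORS[kind].GetFingerprint(mol)
            bits = _bitvect_to_array(bv, 1024)
        elif kind is FingerprintKind.AVALON:
            bv = pyAvalonTools.GetAvalonFP(mol, nBits=1024)
            bits = _bitvect_to_array(bv, 1024)
        elif kind is FingerprintKind.LAYERED:
            bv = Chem.LayeredFingerprint(mol, fpSize=1024)
            bits = _bitvect_to_array(bv, 1024)
        elif kind is FingerprintKind.MACCS:
            bv = MACCSkeys.GenMACCSKeys(mol)
            bits = _bitvect_to_array(bv, 167)[1:]
        else:  # pragma: no cover - exhaustive over the enum
            raise ValueError(kind)
    except Exception as exc:
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else Chem.MolToSmiles(mol)
        raise FingerprintError(
            f"failed to compute {kind.value} fingerprint for {name}: {exc}"
        ) from exc
    return Fingerprint(config=config, bits=bits)


def fingerprint_matrix(
    smiles_list: list[str], kind: FingerprintKind
) -> np.ndarray:
    """Stack fingerprints of many molecules into an (n, n_bits) bool matrix."""
    n_bits = N_BITS[kind]
    mat = np.zeros((len(smiles_list), n_bits), dtype=bool)
    cfg = FingerprintConfig(kind)
    for i, smi in enumerate(smiles_list):
        mat[i] = compute_fingerprint(mol_from_smiles(smi), cfg).bits
    return mat


def matrix_content_hash(matrix: np.ndarray, ids: list[str]) -> str:
    """Content hash tying a fingerprint matrix to its ligand ordering."""
    h = hashlib.sha256()
    h.update("\n".join(ids).encode())
    h.update(np.packbits(matrix, axis=None).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Tanimoto similarity
# ---------------------------------------------------------------------------

def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b|.

    Defined as 0 when both vectors are all-zero: a featureless fragment
    should not look identical to another featureless fragment.
    """
    if a.config != b.config:
        raise ValueError(
            f"fingerprint configs differ: {a.config} vs {b.config}"
        )
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    return inter / union if union else 0.0


def tanimoto_to_matrix(query: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Tanimoto of one query bit vector against each row of a bool matrix.

    All-zero/all-zero pairs get similarity 0 (union == 0 guard).
    """
    q = np.asarray(query, dtype=bool)
    inter = matrix @ q.astype(np.int64)
    union = np.count_nonzero(matrix, axis=1) + np.count_nonzero(q) - inter
    out = np.zeros(matrix.shape[0], dtype=float)
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


# ---------------------------------------------------------------------------
# Murcko scaffolds
# ---------------------------------------------------------------------------

def murcko_scaffold(smiles_or_mol: str | Chem.Mol) -> str:
    """Canonical Bemis-Murcko framework SMILES; '' for acyclic molecules."""
    mol = (
        mol_from_smiles(smiles_or_mol)
        if isinstance(smiles_or_mol, str)
        else smiles_or_mol
    )
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


def scaffold_key(smiles_or_mol: str | Chem.Mol) -> str:
    """Scaffold map key: the canonical framework, or the shared acyclic key."""
    scaf = murcko_scaffold(smiles_or_mol)
    return scaf if scaf else ACYCLIC_SCAFFOLD_KEY
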