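"""Target scoring and ranking for a query molecule.

A query is compared against every reference ligand of every target with the
Tanimoto coefficient; each target is then scored under one of three schemes:

* ``MaxTc``  — similarity of the single most similar ligand (KNN with K=1);
* ``KNNTc``  — mean similarity of the K most similar ligands (K in
  {3, 5, 7, 9} in practice);
* ``MeanTc`` — mean similarity over all of the target's ligands.

Targets are ranked by descending score with a deterministic tie-break on
target id, producing a :class:`PredictionList`.  Every entry also carries
its top-1 similarity (``best_similarity``) because confidence thresholds
filter on the nearest-ligand similarity regardless of the scoring scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from rdkit import Chem

from .chem import (
    FingerprintKind,
    compute_fingerprint,
    fingerprint_matrix,
    matrix_content_hash,
    mol_from_smiles,
    tanimoto_to_matrix,
)
from .curation import ReferenceLibrary


class SchemeKind(str, Enum):
    MAX_TC = "MaxTc"
    KNN_TC = "KNNTc"
    MEAN_TC = "MeanTc"


@dataclass(frozen=True)
class ScoringScheme:
    """MaxTc / KNNTc(K) / MeanTc.  MaxTc is KNNTc with K=1."""

    kind: SchemeKind
    k: int | None = None

    def __post_init__(self) -> None:
        if self.kind is SchemeKind.KNN_TC:
            if self.k is None or self.k < 1:
                raise ValueError("KNNTc requires K >= 1")
        elif self.k is not None:
            raise ValueError(f"{self.kind.value} does not take K")

    @classmethod
    def parse(cls, text: str) -> "ScoringScheme":
        """Parse 'maxtc', 'mean', 'knn:K', or 'KNNTc:K' style spellings."""
        t = text.strip().lower()
        if t in {"maxtc", "max"}:
            return cls(SchemeKind.MAX_TC)
        if t in {"meantc", "mean"}:
            return cls(SchemeKind.MEAN_TC)
        if t.startswith(("knn:", "knntc:")):
            return cls(SchemeKind.KNN_TC, k=int(t.split(":", 1)[1]))
        raise ValueError(f"cannot parse scoring scheme {text!r}")

    def __str__(self) -> str:
        if self.kind is SchemeKind.KNN_TC:
            return f"{self.k}NNTc"
        return self.kind.value


MAX_TC = ScoringScheme(SchemeKind.MAX_TC)
MEAN_TC = ScoringScheme(SchemeKind.MEAN_TC)


@dataclass(frozen=True)
class SimilarityProfile:
    """Per-target descending similarity lists for one query/fingerprint.

    ``per_target`` maps target_id to a list of (similarity, ligand_id)
    sorted by similarity descending (ligand id ascending on ties); the list
    covers every reference ligand of the target.
    """

    query_id: str
    kind: FingerprintKind
    per_target: dict[str, list[tuple[float, str]]]


@dataclass(frozen=True)
class PredictionEntry:
    rank: int
    target_id: str
    score: float
    best_similarity: float
    best_ligand_id: str


@dataclass(frozen=True)
class PredictionList:
    """Ranked targets for one query, descending score."""

    query_id: str
    scheme: str
    kind: str
    entries: tuple[PredictionEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def target_order(self) -> list[str]:
        return [e.target_id for e in self.entries]

    def top(self, n: int) -> tuple[PredictionEntry, ...]:
        return tuple(e for e in self.entries if e.rank <= n)


class LibraryFingerprints:
    """Fingerprint matrix cache for one library and one fingerprint kind.

    Rows follow ``ligand_ids`` (sorted ligand ids); a content hash ties the
    matrix to that ordering so stale caches are detectable.
    """

    def __init__(self, library: ReferenceLibrary, kind: FingerprintKind):
        self.kind = kind
        self.ligand_ids: list[str] = sorted(library.ligands)
        smiles = [library.ligands[lid] for lid in self.ligand_ids]
        self.matrix = fingerprint_matrix(smiles, kind)
        self.row_of = {lid: i for i, lid in enumerate(self.ligand_ids)}
        self.content_hash = matrix_content_hash(self.matrix, self.ligand_ids)


def similarity_profile(
    query: str | Chem.Mol,
    library: ReferenceLibrary,
    kind: FingerprintKind,
    *,
    query_id: str = "query",
    cache: LibraryFingerprints | None = None,
    exclude_ligands: frozenset[str] | set[str] = frozenset(),
) -> SimilarityProfile:
    """Exact all-pairs query-vs-library similarities, grouped per target.

    ``exclude_ligands`` removes reference ligands before scoring (used by
    leave-one-out validation to hold the query itself out).  Targets left
    with zero ligands are omitted from the profile.
    """
    if cache is None:
        cache = LibraryFingerprints(library, kind)
    elif cache.kind is not kind:
        raise ValueError(f"cache holds {cache.kind}, requested {kind}")
    mol = mol_from_smiles(query) if isinstance(query, str) else query
    qbits = compute_fingerprint(mol, kind).bits
    sims = tanimoto_to_matrix(qbits, cache.matrix)

    per_target: dict[str, list[tuple[float, str]]] = {}
    for tid, lids in library.target_index.items():
        entries = [
            (float(sims[cache.row_of[lid]]), lid)
            for lid in lids
            if lid not in exclude_ligands
        ]
        if not entries:
            continue
        entries.sort(key=lambda e: (-e[0], e[1]))
        per_target[tid] = entries
    return SimilarityProfile(query_id=query_id, kind=kind, per_target=per_target)


def score_target(similarities: list[float], scheme: ScoringScheme) -> float:
    """Score one target from its descending similarity list."""
    if not similarities:
        raise ValueError("cannot score a target with no reference ligands")
    if scheme.kind is SchemeKind.MAX_TC:
        return similarities[0]
    if scheme.kind is SchemeKind.MEAN_TC:
        return float(np.mean(similarities))
    # KNNTc: K beyond the ligand count falls back to all available ligands
    k = min(scheme.k, len(similarities))
    return float(np.mean(similarities[:k]))


def rank_targets(
    scores: dict[str, float],
    *,
    query_id: str = "query",
    scheme: str = "",
    kind: str = "",
    best: dict[str, tuple[float, str]] | None = None,
    ascending: bool = False,
) -> PredictionList:
    """Total order over scored targets with a deterministic tie-break.

    Descending score by default (ascending for rank-sum fusion); ties break
    on target id ascending, giving reproducible ordinal ranks 1..T.
    """
    if not scores:
        raise ValueError("no scored targets to rank")
    sign = 1.0 if ascending else -1.0
    ordered = sorted(scores.items(), key=lambda kv: (sign * kv[1], kv[0]))
    entries = []
    for rank, (tid, score) in enumerate(ordered, start=1):
        bsim, blig = best[tid] if best else (float("nan"), "")
        entries.append(
            PredictionEntry(
                rank=rank,
                target_id=tid,
                score=float(score),
                best_similarity=float(bsim),
                best_ligand_id=blig,
            )
        )
    return PredictionList(query_id=query_id, scheme=scheme, kind=kind,
                          entries=tuple(entries))


def predict_targets(
    query: str | Chem.Mol,
    library: ReferenceLibrary,
    kind: FingerprintKind,
    scheme: ScoringScheme = MAX_TC,
    *,
    query_id: str = "query",
    cache: LibraryFingerprints | None = None,
    exclude_ligands: frozenset[str] | set[str] = frozenset(),
) -> PredictionList:
    """Full pipeline for one query: profile, score, rank."""
    profile = similarity_profile(
        query, library, kind,
        query_id=query_id, cache=cache, exclude_ligands=exclude_ligands,
    )
    return score_profile(profile, scheme)


def score_profile(profile: SimilarityProfile, scheme: ScoringScheme) -> PredictionList:
    scores: dict[str, float] = {}
    best: dict[str, tuple[float, str]] = {}
    for tid, entries in profile.per_target.items():
        sims = [s for s, _ in entries]
        scores[tid] = score_target(sims, scheme)
        best[tid] = entries[0]
    return rank_targets(
        scores,
        query_id=profile.query_id,
        scheme=str(scheme),
        kind=profile.kind.value,
        best=best,
    )
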