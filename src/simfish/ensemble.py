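"""Multi-fingerprint ensemble fusion.

Two fusion rules combine per-fingerprint target scores for one query:

* z-score sum — each member's raw scores are standardized over the scored
  targets (z = (x - mu)/sigma, population standard deviation) and the
  per-target z-values are summed; higher is better.
* rank sum — each member contributes its ordinal rank for the target and
  the sums are ranked ascending (a target ranked first everywhere wins).

With eight fingerprint kinds there are 2^8 - 1 - 8 = 247 subsets of size
two or more, enumerated deterministically for ensemble scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .chem import FingerprintKind
from .scoring import PredictionList, rank_targets


class FusionMethod(str, Enum):
    ZSCORE_SUM = "zscore_sum"
    RANK_SUM = "rank_sum"


@dataclass(frozen=True)
class EnsembleConfig:
    members: tuple[FingerprintKind, ...]
    method: FusionMethod

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("ensemble members must be distinct")
        if not 2 <= len(self.members) <= 8:
            raise ValueError("ensembles combine between 2 and 8 fingerprints")
        object.__setattr__(self, "members", tuple(self.members))

    @property
    def label(self) -> str:
        return "+".join(k.value for k in self.members)


@dataclass(frozen=True)
class StandardizedScores:
    """Per-target z-values for one query under one fingerprint."""

    kind: FingerprintKind
    z: dict[str, float]
    mu: float
    sigma: float


def zscore_standardize(
    scores: dict[str, float], kind: FingerprintKind | None = None
) -> StandardizedScores:
    """Standardize per-target scores to zero mean and unit population SD.

    Different fingerprints occupy different similarity ranges, so raw
    scores are not directly comparable across members; z-scoring over the
    scored targets puts them on one scale.  A degenerate member whose
    scores are all equal carries no ranking information and maps to all
    zeros.
    """
    if len(scores) < 2:
        raise ValueError("z-standardization needs at least 2 scored targets")
    values = np.array(list(scores.values()), dtype=float)
    mu = float(values.mean())
    sigma = float(values.std())  # population SD
    if sigma <= 1e-12 * max(1.0, abs(mu)):  # constant scores up to rounding
        sigma = 0.0
    if sigma > 0:
        z = {t: (x - mu) / sigma for t, x in scores.items()}
    else:
        z = {t: 0.0 for t in scores}
    return StandardizedScores(kind=kind, z=z, mu=mu, sigma=sigma)


def _common_targets(target_sets: Sequence[set[str]]) -> set[str]:
    common = set.intersection(*map(set, target_sets))
    if any(s != common for s in target_sets):
        raise ValueError(
            "ensemble members scored different target sets; fusion is "
            "restricted to targets scored by every member"
        )
    return common


def fuse_zscore(
    member_scores: dict[FingerprintKind, StandardizedScores],
    config: EnsembleConfig,
    *,
    query_id: str = "query",
    best: dict[str, tuple[float, str]] | None = None,
) -> PredictionList:
    """Sum member z-values per target and rank descending."""
    if config.method is not FusionMethod.ZSCORE_SUM:
        raise ValueError("config method must be zscore_sum")
    missing = [k for k in config.members if k not in member_scores]
    if missing:
        raise ValueError(f"missing member scores for {missing}")
    targets = _common_targets([set(member_scores[k].z) for k in config.members])
    fused = {
        t: sum(member_scores[k].z[t] for k in config.members) for t in targets
    }
    return rank_targets(
        fused, query_id=query_id, scheme="zscore_sum", kind=config.label, best=best
    )


def fuse_rank(
    member_lists: dict[FingerprintKind, PredictionList],
    config: EnsembleConfig,
    *,
    query_id: str = "query",
    best: dict[str, tuple[float, str]] | None = None,
) -> PredictionList:
    """Sum member ordinal ranks per target; smaller sums rank first."""
    if config.method is not FusionMethod.RANK_SUM:
        raise ValueError("config method must be rank_sum")
    missing = [k for k in config.members if k not in member_lists]
    if missing:
        raise ValueError(f"missing member lists for {missing}")
    rank_maps = {
        k: {e.target_id: e.rank for e in member_lists[k].entries}
        for k in config.members
    }
    targets = _common_targets([set(m) for m in rank_maps.values()])
    fused = {t: float(sum(rank_maps[k][t] for k in config.members)) for t in targets}
    return rank_targets(
        fused, query_id=query_id, scheme="rank_sum", kind=config.label,
        best=best, ascending=True,
    )


def enumerate_combinations(
    kinds: Iterable[FingerprintKind] | None = None,
) -> list[tuple[FingerprintKind, ...]]:
    """All multi-fingerprint subsets (size >= 2) in deterministic order.

    For n distinct kinds this yields 2^n - 1 - n subsets; with the full
    eight-fingerprint panel, 247.
    """
    pool = tuple(kinds) if kinds is not None else tuple(FingerprintKind)
    if len(set(pool)) != len(pool):
        raise ValueError("fingerprint kinds must be distinct")
    out: list[tuple[FingerprintKind, ...]] = []
    for m in range(2, len(pool) + 1):
        out.extend(combinations(pool, m))
    return out
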