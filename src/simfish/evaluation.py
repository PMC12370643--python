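"""Leave-one-out-like cross-validation and target-fishing metrics.

A validation set is drawn per target by stratified scaffold sampling: for a
target with fewer than 70 distinct Murcko scaffolds, 30% of its scaffolds
are sampled (at least one) and one ligand is taken per sampled scaffold;
for a target with 70 or more scaffolds, 20 scaffolds are sampled.  Each
selected ligand becomes one target-fishing event: it is removed from the
reference side of the library, predicted against the remainder, and its
curated targets are the ground truth.

Metrics are micro-averaged over events at a rank cutoff n (optionally with
a similarity threshold tau on the best-neighbor similarity):

    RE_n = TP_n / (TP_n + FN_n)      recall over known pairs
    PR_n = TP_n / (TP_n + FP_n)      precision over retained predictions
    F1   = 2 * RE_n * PR_n / (RE_n + PR_n)

and the enrichment fold over random picking is RE_n / (n / T) for a
library of T predictable targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .chem import FingerprintKind, scaffold_key
from .curation import ReferenceLibrary
from .ensemble import (
    EnsembleConfig,
    FusionMethod,
    fuse_rank,
    fuse_zscore,
    zscore_standardize,
)
from .scoring import (
    MAX_TC,
    LibraryFingerprints,
    PredictionList,
    ScoringScheme,
    score_profile,
    similarity_profile,
)

#: Scaffold-count boundary of the two sampling regimes.
SCAFFOLD_REGIME_BOUNDARY = 70
#: Fraction of scaffolds sampled below the boundary.
SCAFFOLD_SAMPLE_FRACTION = 0.30
#: Fixed scaffold sample size at or above the boundary.
SCAFFOLD_SAMPLE_FIXED = 20


@dataclass(frozen=True)
class ValidationQuery:
    """One held-out query ligand with its known targets."""

    ligand_id: str
    smiles: str
    known_targets: frozenset[str]

    def __post_init__(self) -> None:
        if not self.known_targets:
            raise ValueError("a validation query needs at least one known target")


@dataclass(frozen=True)
class TFEvent:
    """One target-fishing event: a query, its truth, and its prediction."""

    query: ValidationQuery
    prediction: PredictionList


@dataclass(frozen=True)
class MetricsReport:
    n: int
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f1: float
    n_events: int
    tau: float | None = None
    stratum: str | None = None


def f1_score(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision; 0 when both vanish."""
    if recall + precision == 0:
        return 0.0
    return 2 * recall * precision / (recall + precision)


def scaffold_map(library: ReferenceLibrary) -> dict[str, str]:
    """Murcko scaffold key for every ligand (a partition of the ligand set)."""
    return {lid: scaffold_key(smi) for lid, smi in library.ligands.items()}


def scaffold_sample_size(n_scaffolds: int) -> int:
    """How many scaffolds to sample for a target with n distinct scaffolds."""
    if n_scaffolds < 1:
        return 0
    if n_scaffolds >= SCAFFOLD_REGIME_BOUNDARY:
        return SCAFFOLD_SAMPLE_FIXED
    return max(1, math.ceil(SCAFFOLD_SAMPLE_FRACTION * n_scaffolds))


def select_validation_set(
    library: ReferenceLibrary,
    seed: int,
    scaffolds: dict[str, str] | None = None,
) -> list[ValidationQuery]:
    """Stratified scaffold sampling of validation queries, seeded.

    One ligand is drawn per sampled scaffold per target.  A ligand drawn
    for several targets is deduplicated into a single query carrying all
    of its known targets, so each query contributes one event per known
    target when metrics are pooled.
    """
    if scaffolds is None:
        scaffolds = scaffold_map(library)
    rng = np.random.default_rng(seed)
    selected: set[str] = set()
    for tid in sorted(library.target_index):
        lids = library.target_index[tid]
        if not lids:
            continue
        by_scaffold: dict[str, list[str]] = {}
        for lid in sorted(lids):
            by_scaffold.setdefault(scaffolds[lid], []).append(lid)
        keys = sorted(by_scaffold)
        n_sample = scaffold_sample_size(len(keys))
        chosen = rng.choice(len(keys), size=n_sample, replace=False)
        for idx in sorted(chosen):
            group = by_scaffold[keys[idx]]
            selected.add(group[int(rng.integers(len(group)))])
    return [
        ValidationQuery(
            ligand_id=lid,
            smiles=library.ligands[lid],
            known_targets=library.known_targets_of(lid),
        )
        for lid in sorted(selected)
    ]


def _exclusion_set(
    library: ReferenceLibrary, query: ValidationQuery, mode: str
) -> frozenset[str]:
    if mode == "id":
        return frozenset({query.ligand_id})
    if mode == "structure":
        return frozenset(
            lid for lid, smi in library.ligands.items() if smi == query.smiles
        ) | {query.ligand_id}
    raise ValueError(f"unknown exclusion mode {mode!r} (use 'id' or 'structure')")


def predict_event(
    query: ValidationQuery,
    library: ReferenceLibrary,
    *,
    kind: FingerprintKind | None = None,
    scheme: ScoringScheme = MAX_TC,
    ensemble: EnsembleConfig | None = None,
    caches: dict[FingerprintKind, LibraryFingerprints] | None = None,
    exclusion: str = "id",
) -> TFEvent:
    """Predict one event with the query held out of the reference side."""
    exclude = _exclusion_set(library, query, exclusion)
    caches = caches or {}
    kinds = ensemble.members if ensemble is not None else (kind,)
    if any(k is None for k in kinds):
        raise ValueError("either a fingerprint kind or an ensemble is required")

    profiles = {}
    for k in kinds:
        if k not in caches:
            caches[k] = LibraryFingerprints(library, k)
        profiles[k] = similarity_profile(
            query.smiles, library, k,
            query_id=query.ligand_id, cache=caches[k], exclude_ligands=exclude,
        )

    if ensemble is None:
        profile = profiles[kind]
        if not profile.per_target:
            prediction = PredictionList(query.ligand_id, str(scheme),
                                        kind.value, ())
        else:
            prediction = score_profile(profile, scheme)
        return TFEvent(query=query, prediction=prediction)

    # ensemble: fuse on targets scored by every member (members share the
    # same library, so the per-target sets coincide in practice)
    common = set.intersection(*(set(p.per_target) for p in profiles.values()))
    if not common:
        return TFEvent(
            query=query,
            prediction=PredictionList(query.ligand_id, ensemble.method.value,
                                      ensemble.label, ()),
        )
    # best-neighbor similarity per target: the strongest nearest-ligand
    # evidence over the member fingerprints (thresholds act on this)
    best = {
        t: max(
            (profiles[k].per_target[t][0] for k in ensemble.members),
            key=lambda e: e[0],
        )
        for t in common
    }
    if ensemble.method is FusionMethod.ZSCORE_SUM:
        member_scores = {}
        for k in ensemble.members:
            # member scores restricted to the common target set
            raw = {
                t: score_profile_score(profiles[k].per_target[t], scheme)
                for t in common
            }
            member_scores[k] = zscore_standardize(raw, k)
        prediction = fuse_zscore(member_scores, ensemble,
                                 query_id=query.ligand_id, best=best)
    else:
        member_lists = {}
        for k in ensemble.members:
            raw = {
                t: score_profile_score(profiles[k].per_target[t], scheme)
                for t in common
            }
            member_lists[k] = score_list_from_scores(
                raw, query_id=query.ligand_id, scheme=str(scheme), kind=k.value
            )
        prediction = fuse_rank(member_lists, ensemble,
                               query_id=query.ligand_id, best=best)
    return TFEvent(query=query, prediction=prediction)


def score_profile_score(
    entries: list[tuple[float, str]], scheme: ScoringScheme
) -> float:
    from .scoring import score_target

    return score_target([s for s, _ in entries], scheme)


def score_list_from_scores(scores, *, query_id, scheme, kind):
    from .scoring import rank_targets

    return rank_targets(scores, query_id=query_id, scheme=scheme, kind=kind)


def run_loo_cv(
    library: ReferenceLibrary,
    queries: list[ValidationQuery],
    *,
    kind: FingerprintKind | None = None,
    scheme: ScoringScheme = MAX_TC,
    ensemble: EnsembleConfig | None = None,
    exclusion: str = "id",
    caches: dict[FingerprintKind, LibraryFingerprints] | None = None,
) -> list[TFEvent]:
    """Run the leave-one-out-like validation over all queries.

    Each query ligand is excluded from every target's reference list before
    scoring; targets left without ligands are unpredictable for that event
    and any known target among them contributes a false negative.
    """
    caches = caches if caches is not None else {}
    return [
        predict_event(
            q, library,
            kind=kind, scheme=scheme, ensemble=ensemble,
            caches=caches, exclusion=exclusion,
        )
        for q in queries
    ]


def _retained(event: TFEvent, n: int, tau: float | None):
    entries = event.prediction.top(n)
    if tau is not None:
        entries = tuple(e for e in entries if e.best_similarity >= tau)
    return entries


def compute_metrics(
    events: list[TFEvent], n: int, tau: float | None = None,
    stratum: str | None = None,
) -> MetricsReport:
    """Micro-averaged RE_n / PR_n / F1 over events.

    Per event the retained predictions are the top-n ranks, further
    filtered to best-neighbor similarity >= tau when a threshold is given;
    TP/FP/FN counts are pooled over all events before the ratios are taken.
    """
    if n < 1:
        raise ValueError("rank cutoff n must be >= 1")
    tp = fp = fn = 0
    for event in events:
        known = event.query.known_targets
        retained = {e.target_id for e in _retained(event, n, tau)}
        tp += len(retained & known)
        fp += len(retained - known)
        fn += len(known - retained)
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    return MetricsReport(
        n=n, tp=tp, fp=fp, fn=fn,
        recall=recall, precision=precision, f1=f1_score(recall, precision),
        n_events=len(events), tau=tau, stratum=stratum,
    )


def enrichment_fold(re_n: float, n: int, n_targets: int) -> float:
    """Fold enrichment of RE_n over random picking of n from T targets."""
    if not 0 <= re_n <= 1:
        raise ValueError("recall must lie in [0, 1]")
    if not 1 <= n <= n_targets:
        raise ValueError("need 1 <= n <= number of targets")
    return re_n / (n / n_targets)


#: Default cumulative baskets for the reference-ligand-count strata.
LIGAND_COUNT_BASKETS = (1, 2, 5, 10, 20, 50)


def _pair_recall_report(
    events: list[TFEvent],
    n: int,
    tau: float | None,
    keep_pair,
    stratum: str,
) -> MetricsReport:
    """Recall restricted to known (query, target) pairs selected by keep_pair.

    Precision has no pair-level analogue (retained non-known predictions do
    not belong to a known-pair stratum), so FP is 0 and PR/F1 are NaN here.
    """
    tp = fn = 0
    n_events = 0
    for event in events:
        known = [t for t in event.query.known_targets if keep_pair(event, t)]
        if not known:
            continue
        n_events += 1
        retained = {e.target_id for e in _retained(event, n, tau)}
        hit = sum(1 for t in known if t in retained)
        tp += hit
        fn += len(known) - hit
    recall = tp / (tp + fn) if tp + fn else 0.0
    return MetricsReport(
        n=n, tp=tp, fp=0, fn=fn,
        recall=recall, precision=float("nan"), f1=float("nan"),
        n_events=n_events, tau=tau, stratum=stratum,
    )


def stratify_metrics(
    events: list[TFEvent],
    strata: str,
    *,
    n: int = 10,
    tau: float | None = None,
    library: ReferenceLibrary | None = None,
    baskets: tuple[int, ...] = LIGAND_COUNT_BASKETS,
) -> list[MetricsReport]:
    """Metrics broken down by a confidence-relevant stratification.

    ``strata`` selects the breakdown:

    * ``"query_promiscuity"`` — events grouped by their number of known
      targets (full micro metrics per group);
    * ``"target_ligand_count"`` — recall over known pairs whose target has
      at least c reference ligands, for each cumulative basket c;
    * ``"target_class"`` — recall over known pairs grouped by the target's
      class annotation.
    """
    if strata == "query_promiscuity":
        groups: dict[int, list[TFEvent]] = {}
        for ev in events:
            groups.setdefault(len(ev.query.known_targets), []).append(ev)
        return [
            replace(
                compute_metrics(groups[k], n, tau),
                stratum=f"known_targets={k}",
            )
            for k in sorted(groups)
        ]
    if strata == "target_ligand_count":
        if library is None:
            raise ValueError("target_ligand_count strata need the library")
        counts = {t: len(lids) for t, lids in library.target_index.items()}
        return [
            _pair_recall_report(
                events, n, tau,
                lambda ev, t, c=c: counts.get(t, 0) >= c,
                stratum=f"target_ligands>={c}",
            )
            for c in baskets
        ]
    if strata == "target_class":
        if library is None:
            raise ValueError("target_class strata need the library")
        classes = sorted(
            {c for c in library.targets.values() if c is not None}
        )
        return [
            _pair_recall_report(
                events, n, tau,
                lambda ev, t, cls=cls: library.targets.get(t) == cls,
                stratum=f"class={cls}",
            )
            for cls in classes
        ]
    raise ValueError(f"unknown strata key {strata!r}")
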