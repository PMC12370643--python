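"""Validation-set sampling, leave-one-out CV, and pooled metrics."""

import numpy as np
import pytest

from simfish import (
    BioactivityRecord,
    MetricsReport,
    TFEvent,
    ValidationQuery,
    build_library,
    compute_metrics,
    enrichment_fold,
    f1_score,
    run_loo_cv,
    select_validation_set,
    stratify_metrics,
)
from simfish.chem import FingerprintKind
from simfish.evaluation import scaffold_sample_size
from simfish.scoring import PredictionEntry, PredictionList


def make_event(known, ranked):
    """Synthetic event: ranked = [(target_id, best_similarity), ...]."""
    entries = tuple(
        PredictionEntry(
            rank=i + 1, target_id=t, score=s, best_similarity=s,
            best_ligand_id="L",
        )
        for i, (t, s) in enumerate(ranked)
    )
    return TFEvent(
        query=ValidationQuery(
            ligand_id="Q", smiles="C", known_targets=frozenset(known)
        ),
        prediction=PredictionList("Q", "MaxTc", "ECFP4", entries),
    )


# ---------------------------------------------------------------------------
# validation-set sampling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n_scaffolds,expected",
    [(10, 3), (70, 20), (1, 1), (69, 21), (100, 20), (3, 1), (4, 2)],
)
def test_scaffold_sample_size_regimes(n_scaffolds, expected):
    assert scaffold_sample_size(n_scaffolds) == expected


def test_select_validation_set_seeded_and_scaffold_distinct(clean_library):
    qs1 = select_validation_set(clean_library, seed=1)
    qs2 = select_validation_set(clean_library, seed=1)
    assert [q.ligand_id for q in qs1] == [q.ligand_id for q in qs2]
    # clean fixture: 5 targets x 4 scaffolds -> ceil(0.3*4)=2 ligands each
    assert len(qs1) == 10
    from simfish.chem import scaffold_key

    per_target: dict[str, set[str]] = {}
    for q in qs1:
        for t in q.known_targets:
            scaf = scaffold_key(q.smiles)
            assert scaf not in per_target.get(t, set())
            per_target.setdefault(t, set()).add(scaf)


def test_shared_ligand_becomes_single_event_with_all_targets(noisy_library):
    qs = select_validation_set(noisy_library, seed=3)
    ids = [q.ligand_id for q in qs]
    assert len(ids) == len(set(ids))
    for q in qs:
        assert q.known_targets == noisy_library.known_targets_of(q.ligand_id)
        assert q.known_targets <= set(noisy_library.targets)


# ---------------------------------------------------------------------------
# leave-one-out exclusion semantics
# ---------------------------------------------------------------------------

def _lib_with_twin():
    smi_a = "Cc1ccc2ccccc2c1O"
    records = [
        BioactivityRecord("L1", smi_a, "T1", "Ki", 50, "nM", "s"),
        BioactivityRecord("L1b", smi_a, "T1", "Ki", 60, "nM", "s"),  # twin
        BioactivityRecord("L2", "OCCN", "T2", "Ki", 50, "nM", "s"),
        BioactivityRecord("L3", "c1ccc2c(c1)OCO2", "T3", "Ki", 50, "nM", "s"),
    ]
    return build_library(records)


def test_query_as_only_ligand_makes_target_unpredictable():
    lib = _lib_with_twin()
    q = ValidationQuery("L2", lib.ligands["L2"], frozenset({"T2"}))
    [event] = run_loo_cv(lib, [q], kind=FingerprintKind.ECFP4)
    assert "T2" not in event.prediction.target_order()
    m = compute_metrics([event], n=len(lib.targets))
    assert m.fn == 1  # the known target can only be a false negative


def test_identifier_exclusion_keeps_structural_twin():
    lib = _lib_with_twin()
    q = ValidationQuery("L1", lib.ligands["L1"], frozenset({"T1"}))
    [event] = run_loo_cv(lib, [q], kind=FingerprintKind.ECFP4, exclusion="id")
    entry = next(e for e in event.prediction.entries if e.target_id == "T1")
    assert entry.best_similarity == pytest.approx(1.0)
    assert entry.best_ligand_id == "L1b"


def test_structure_exclusion_also_removes_twin():
    lib = _lib_with_twin()
    q = ValidationQuery("L1", lib.ligands["L1"], frozenset({"T1"}))
    [event] = run_loo_cv(
        lib, [q], kind=FingerprintKind.ECFP4, exclusion="structure"
    )
    assert "T1" not in event.prediction.target_order()


def test_loo_queries_never_hit_themselves(clean_library):
    qs = select_validation_set(clean_library, seed=1)
    events = run_loo_cv(clean_library, qs, kind=FingerprintKind.ECFP4)
    for ev in events:
        for e in ev.prediction.entries:
            assert e.best_ligand_id != ev.query.ligand_id


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_perfect_single_event_metrics():
    ev = make_event({"A"}, [("A", 0.9)])
    m = compute_metrics([ev], n=1)
    assert (m.recall, m.precision, m.f1) == (1.0, 1.0, 1.0)


def test_metrics_hand_count_two_events():
    # event A: 1 known target at rank 1; event B: 2 known at ranks 3 and 12
    t = [f"X{i}" for i in range(15)]
    ev_a = make_event({"K1"}, [("K1", 0.9)] + [(x, 0.1) for x in t[:11]])
    ranked_b = [(x, 0.2) for x in t[:2]] + [("K2", 0.8)]
    ranked_b += [(x, 0.2) for x in t[2:10]] + [("K3", 0.7)]
    ev_b = make_event({"K2", "K3"}, ranked_b)
    m = compute_metrics([ev_a, ev_b], n=10)
    assert (m.tp, m.fp, m.fn) == (2, 18, 1)
    assert m.recall == pytest.approx(2 / 3)
    assert m.precision == pytest.approx(0.1)


def test_metrics_rejects_bad_cutoff():
    with pytest.raises(ValueError):
        compute_metrics([], n=0)


def test_recall_non_decreasing_in_n(clean_events):
    recalls = [compute_metrics(clean_events, n).recall for n in (1, 2, 3, 5, 10)]
    assert all(a <= b + 1e-12 for a, b in zip(recalls, recalls[1:]))


def test_full_rank_no_threshold_gives_full_recall(clean_events):
    # clean fixture: every known target is predictable for every event
    n_targets = max(len(ev.prediction) for ev in clean_events)
    m = compute_metrics(clean_events, n=n_targets, tau=0.0)
    assert m.recall == 1.0


def test_micro_totals_conserved(clean_events):
    total_known = sum(len(ev.query.known_targets) for ev in clean_events)
    for n in (1, 3, 10):
        for tau in (None, 0.3, 0.9):
            m = compute_metrics(clean_events, n, tau=tau)
            assert m.tp + m.fn == total_known


def test_f1_bounds_against_means():
    for re, pr in [(0.2, 0.9), (0.5, 0.5), (0.75, 0.3)]:
        f1 = f1_score(re, pr)
        assert f1 <= np.sqrt(re * pr) + 1e-12
        assert f1 <= (re + pr) / 2 + 1e-12


def test_metrics_match_naive_set_algebra_oracle():
    """Pooled aggregation equals per-event set algebra on 200 random events."""
    rng = np.random.default_rng(42)
    targets = [f"T{i:02d}" for i in range(20)]
    events = []
    for _ in range(200):
        order = rng.permutation(targets)
        sims = np.sort(rng.random(len(targets)))[::-1]
        known = set(rng.choice(targets, size=int(rng.integers(1, 4)),
                               replace=False))
        events.append(make_event(known, list(zip(order, sims))))

    for n in (1, 5, 10):
        for tau in (None, 0.5):
            tp = fp = fn = 0
            for ev in events:
                retained = {
                    e.target_id
                    for e in ev.prediction.entries
                    if e.rank <= n and (tau is None or e.best_similarity >= tau)
                }
                known = set(ev.query.known_targets)
                tp += len(retained & known)
                fp += len(retained - known)
                fn += len(known - retained)
            m = compute_metrics(events, n, tau=tau)
            assert (m.tp, m.fp, m.fn) == (tp, fp, fn)
            assert m.recall == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)
            assert m.precision == pytest.approx(
                tp / (tp + fp) if tp + fp else 0.0
            )


# ---------------------------------------------------------------------------
# enrichment fold
# ---------------------------------------------------------------------------

def test_enrichment_fold_random_baseline_is_one():
    for n, t in [(1, 100), (10, 1460), (5, 5)]:
        assert enrichment_fold(n / t, n, t) == pytest.approx(1.0)


def test_enrichment_fold_validates_inputs():
    with pytest.raises(ValueError):
        enrichment_fold(1.2, 1, 10)
    with pytest.raises(ValueError):
        enrichment_fold(0.5, 11, 10)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def test_single_promiscuity_stratum_equals_global():
    events = [
        make_event({"A"}, [("A", 0.9), ("B", 0.2)]),
        make_event({"B"}, [("A", 0.8), ("B", 0.7)]),
    ]
    [report] = stratify_metrics(events, "query_promiscuity", n=1)
    base = compute_metrics(events, 1)
    assert report.stratum == "known_targets=1"
    assert (report.tp, report.fp, report.fn) == (base.tp, base.fp, base.fn)


def test_promiscuity_strata_event_counts():
    ev1 = [make_event({"A"}, [("A", 0.9)]) for _ in range(4)]
    ev5 = [
        make_event(
            {f"K{i}" for i in range(5)},
            [(f"K{i}", 0.8) for i in range(5)],
        )
        for _ in range(3)
    ]
    reports = stratify_metrics(ev1 + ev5, "query_promiscuity", n=10)
    by_label = {r.stratum: r for r in reports}
    assert by_label["known_targets=1"].n_events == 4
    assert by_label["known_targets=5"].n_events == 3


def test_target_class_recall_recombines_to_global(clean_library, clean_events):
    global_m = compute_metrics(clean_events, n=10)
    reports = stratify_metrics(
        clean_events, "target_class", n=10, library=clean_library
    )
    total_pairs = sum(r.tp + r.fn for r in reports)
    weighted = sum(r.recall * (r.tp + r.fn) for r in reports) / total_pairs
    assert weighted == pytest.approx(global_m.recall)
    assert total_pairs == global_m.tp + global_m.fn


def test_target_ligand_count_baskets(noisy_library):
    qs = select_validation_set(noisy_library, seed=2)
    events = run_loo_cv(noisy_library, qs, kind=FingerprintKind.ECFP4)
    reports = stratify_metrics(
        events, "target_ligand_count", n=10, library=noisy_library,
        baskets=(1, 10),
    )
    assert [r.stratum for r in reports] == [
        "target_ligands>=1", "target_ligands>=10",
    ]
    # the >=1 basket covers every known pair
    assert reports[0].tp + reports[0].fn == sum(
        len(ev.query.known_targets) for ev in events
    )
    assert reports[1].tp + reports[1].fn <= reports[0].tp + reports[0].fn


def test_unknown_strata_key_rejected(clean_events):
    with pytest.raises(ValueError):
        stratify_metrics(clean_events, "by_phase_of_moon")
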