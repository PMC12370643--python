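"""Target scoring schemes, ranking, and the brute-force oracle."""

import numpy as np
import pytest
from rdkit import Chem

from simfish import (
    BioactivityRecord,
    build_library,
    rank_targets,
    score_target,
    similarity_profile,
)
from simfish.chem import FingerprintKind, compute_fingerprint, tanimoto
from simfish.scoring import (
    MAX_TC,
    MEAN_TC,
    LibraryFingerprints,
    ScoringScheme,
    SchemeKind,
    predict_targets,
)


def _scheme_knn(k):
    return ScoringScheme(SchemeKind.KNN_TC, k=k)


@pytest.mark.parametrize(
    "sims,scheme,expected",
    [
        ([0.9, 0.5, 0.1], MAX_TC, 0.9),
        ([0.9, 0.5, 0.1], _scheme_knn(3), 0.5),
        ([0.9, 0.5, 0.1], _scheme_knn(5), 0.5),  # K beyond list falls back
        ([0.9, 0.5, 0.1], MEAN_TC, 0.5),
        ([0.7], _scheme_knn(9), 0.7),
        ([0.8, 0.4], MEAN_TC, 0.6),
    ],
)
def test_score_target_schemes(sims, scheme, expected):
    assert score_target(sims, scheme) == pytest.approx(expected)


def test_score_target_rejects_empty_list():
    with pytest.raises(ValueError):
        score_target([], MAX_TC)


def test_scheme_parsing_spellings():
    assert ScoringScheme.parse("maxtc") == MAX_TC
    assert ScoringScheme.parse("mean") == MEAN_TC
    assert ScoringScheme.parse("knn:5").k == 5
    with pytest.raises(ValueError):
        ScoringScheme.parse("best")


def test_rank_targets_order_and_tiebreak():
    pred = rank_targets({"A": 0.8, "B": 0.6})
    assert pred.target_order() == ["A", "B"]
    assert [e.rank for e in pred.entries] == [1, 2]

    tied = rank_targets({"B": 0.7, "A": 0.7})
    assert tied.target_order() == ["A", "B"]  # id ascending on ties

    # insertion order never matters
    again = rank_targets(dict([("A", 0.7), ("B", 0.7)]))
    assert again.target_order() == tied.target_order()


def _tiny_library():
    records = []
    smiles = {
        "L1": "c1ccc2ccccc2c1O",
        "L2": "Cc1ccc2ccccc2c1",
        "L3": "OCCN",
    }
    for lid, smi in smiles.items():
        records.append(
            BioactivityRecord(
                ligand_id=lid, smiles=smi, target_id="T1" if lid != "L3" else "T2",
                activity_type="Ki", value=50, unit="nM", source="s",
            )
        )
    # L2 also binds T2: shared (multi-target) ligand
    records.append(
        BioactivityRecord(
            ligand_id="L2", smiles=smiles["L2"], target_id="T2",
            activity_type="Ki", value=50, unit="nM", source="s",
        )
    )
    return build_library(records)


def test_profile_self_query_hits_one():
    lib = _tiny_library()
    profile = similarity_profile(lib.ligands["L1"], lib, FingerprintKind.ECFP4)
    assert profile.per_target["T1"][0][0] == pytest.approx(1.0)
    assert profile.per_target["T1"][0][1] == "L1"


def test_shared_ligand_appears_in_both_target_lists():
    lib = _tiny_library()
    profile = similarity_profile("c1ccccc1", lib, FingerprintKind.ECFP4)
    assert "L2" in [lid for _, lid in profile.per_target["T1"]]
    assert "L2" in [lid for _, lid in profile.per_target["T2"]]
    for entries in profile.per_target.values():
        sims = [s for s, _ in entries]
        assert sims == sorted(sims, reverse=True)


def test_profile_matches_brute_force_double_loop(noisy_library):
    """Vectorized similarity search equals per-pair set arithmetic."""
    lib = noisy_library
    kind = FingerprintKind.ECFP4
    query = "Cc1ccc2ccccc2c1O"
    profile = similarity_profile(query, lib, kind)

    qfp = compute_fingerprint(Chem.MolFromSmiles(query), kind)
    qbits = set(np.flatnonzero(qfp.bits))
    for tid, entries in profile.per_target.items():
        expected = []
        for lid in lib.target_index[tid]:
            lfp = compute_fingerprint(Chem.MolFromSmiles(lib.ligands[lid]), kind)
            lbits = set(np.flatnonzero(lfp.bits))
            union = len(qbits | lbits)
            sim = len(qbits & lbits) / union if union else 0.0
            expected.append((sim, lid))
        expected.sort(key=lambda e: (-e[0], e[1]))
        assert [lid for _, lid in entries] == [lid for _, lid in expected]
        for (s, _), (es, _) in zip(entries, expected):
            assert s == pytest.approx(es, abs=1e-12)


def test_maxtc_equals_knn1_and_meantc_equals_large_k(noisy_library):
    """Scheme identities over random queries on the synthetic library."""
    rng = np.random.default_rng(0)
    lib = noisy_library
    ligand_ids = sorted(lib.ligands)
    cache = LibraryFingerprints(lib, FingerprintKind.ECFP4)
    max_ligands = max(len(v) for v in lib.target_index.values())
    for _ in range(20):
        query = lib.ligands[ligand_ids[int(rng.integers(len(ligand_ids)))]]
        p_max = predict_targets(query, lib, FingerprintKind.ECFP4, MAX_TC,
                                cache=cache)
        p_knn1 = predict_targets(query, lib, FingerprintKind.ECFP4,
                                 _scheme_knn(1), cache=cache)
        p_mean = predict_targets(query, lib, FingerprintKind.ECFP4, MEAN_TC,
                                 cache=cache)
        p_knn_big = predict_targets(query, lib, FingerprintKind.ECFP4,
                                    _scheme_knn(max_ligands + 5), cache=cache)
        assert p_max.target_order() == p_knn1.target_order()
        assert p_mean.target_order() == p_knn_big.target_order()
        for a, b in zip(p_max.entries, p_knn1.entries):
            assert a.score == pytest.approx(b.score)
        for a, b in zip(p_mean.entries, p_knn_big.entries):
            assert a.score == pytest.approx(b.score)


def test_irrelevant_target_never_reorders_existing_ones():
    lib = _tiny_library()
    query = lib.ligands["L1"]
    before = predict_targets(query, lib, FingerprintKind.ECFP4, MAX_TC)
    # add a target whose only ligand shares no bits with the query
    records = [
        BioactivityRecord(
            ligand_id=it.ligand_id, smiles=lib.ligands[it.ligand_id],
            target_id=it.target_id, activity_type="Ki",
            value=it.activity_nM, unit="nM", source="s",
        )
        for it in lib.interactions
    ]
    records.append(
        BioactivityRecord(
            ligand_id="L9", smiles="[SiH4]", target_id="T9",
            activity_type="Ki", value=10, unit="nM", source="s",
        )
    )
    bigger = build_library(records)
    after = predict_targets(query, bigger, FingerprintKind.ECFP4, MAX_TC)
    old_order = [t for t in after.target_order() if t != "T9"]
    assert old_order == before.target_order()


def test_best_similarity_carried_under_knn_scheme():
    lib = _tiny_library()
    pred = predict_targets(lib.ligands["L1"], lib, FingerprintKind.ECFP4,
                           _scheme_knn(3))
    entry = next(e for e in pred.entries if e.target_id == "T1")
    assert entry.best_similarity == pytest.approx(1.0)  # top-1 Tc, not the mean
    assert entry.best_ligand_id == "L1"
    assert entry.score < 1.0
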