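"""Shared fixtures: synthetic libraries generated once per session."""

from __future__ import annotations

import pytest

from simfish import (
    FixtureSpec,
    build_library,
    generate_library,
    generate_queries,
    run_loo_cv,
)
from simfish.chem import FingerprintKind

#: Noisy default conditions: promiscuity, discordant and weak pairs present.
NOISY_SPEC = FixtureSpec(seed=7)

#: Clean, well-separated conditions: no promiscuity, every pair kept.
CLEAN_SPEC = FixtureSpec(
    n_targets=5,
    scaffolds_per_target=4,
    ligands_per_scaffold=5,
    promiscuous_fraction=0.0,
    discordant_fraction=0.0,
    weak_fraction=0.0,
    seed=11,
)


@pytest.fixture(scope="session")
def noisy_fixture():
    records, truth = generate_library(NOISY_SPEC)
    return records, truth


@pytest.fixture(scope="session")
def noisy_library(noisy_fixture):
    records, _ = noisy_fixture
    return build_library(records)


@pytest.fixture(scope="session")
def clean_fixture():
    records, truth = generate_library(CLEAN_SPEC)
    return records, truth


@pytest.fixture(scope="session")
def clean_library(clean_fixture):
    records, _ = clean_fixture
    return build_library(records)


@pytest.fixture(scope="session")
def clean_events(clean_fixture, clean_library):
    """Held-out analog queries predicted against the clean library (ECFP4)."""
    _, truth = clean_fixture
    queries = generate_queries(truth, holdout_fraction=0.3, seed=5)
    return run_loo_cv(clean_library, queries, kind=FingerprintKind.ECFP4)
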