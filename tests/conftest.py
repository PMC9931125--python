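"""Shared fixtures: small planted fixtures generated fresh per session."""

import pytest

from moanet import FixtureSpec, TrainingConfig, generate_fixture


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    """A 20-node planted fixture: fast enough for annealing tests."""
    return FixtureSpec(
        n_nodes=20,
        m=3,
        effectors_per_motive=(3, 3),
        n_shared_effectors=0,
        motive_names=None,
        targets_per_drug=(1, 1),
        n_bioflags_per_drug=1,
        n_rules=8,
        n_terms=6,
        term_size_range=(3, 8),
        seed=1,
    )


@pytest.fixture(scope="session")
def small_fixture(small_spec):
    return generate_fixture(small_spec)


@pytest.fixture(scope="session")
def default_fixture():
    """The full-scale default fixture (200 nodes, 66 unique effectors)."""
    return generate_fixture(FixtureSpec(seed=0))


@pytest.fixture()
def quick_config() -> TrainingConfig:
    """Config scaled for the 20-node fixture."""
    return TrainingConfig(target_size=5, max_attempts=30, n_iterations=800, seed=0)
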