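"""Shared fixtures: small synthetic genome studies reused across modules."""

from __future__ import annotations

import pytest

from retrophylo import SpeciesTreeSpec, default_element_library
from retrophylo.pipeline import run_synthetic_pipeline


@pytest.fixture(scope="session")
def library():
    return default_element_library()


@pytest.fixture(scope="session")
def tree():
    return SpeciesTreeSpec(tau=0.451, truncated_fraction=0.1)


@pytest.fixture(scope="session")
def zero_mut_tree():
    return SpeciesTreeSpec(
        tau=0.451,
        branch_sub_rate={b: 0.0 for b in ("L1", "L2", "L3", "O", "internal")},
        truncated_fraction=0.1,
    )


@pytest.fixture(scope="session")
def small_pipeline(tree):
    """60 kb genomes, 30 insertions, substitution rate 0.01/branch."""
    return run_synthetic_pipeline(tree, n_events=30, ancestral_length=60_000, seed=5)


@pytest.fixture(scope="session")
def zero_mut_pipeline(zero_mut_tree):
    """Mutation-free study: every downstream stage should be exact."""
    return run_synthetic_pipeline(
        zero_mut_tree, n_events=30, ancestral_length=60_000, seed=5
    )
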