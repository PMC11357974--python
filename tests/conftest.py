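"""Shared fixtures: one study-scale synthetic population reused suite-wide."""

from __future__ import annotations

import pytest

import sclcphen as sp

STUDY_N = 31_912
STUDY_SEED = 1234
SPLIT_SEED = 42


@pytest.fixture(scope="session")
def registry():
    return sp.builtin_registry()


@pytest.fixture(scope="session")
def study_config():
    return sp.default_config(n_patients=STUDY_N, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_population(study_config):
    return sp.generate_population(study_config)


@pytest.fixture(scope="session")
def study_cohort(study_population, registry):
    return sp.apply_inclusion(study_population, sp.InclusionCriteria(), registry)


@pytest.fixture(scope="session")
def study_flags(study_cohort, study_population, registry):
    return sp.build_utilization(study_cohort, study_population.claims, registry, window="post180")


@pytest.fixture(scope="session")
def study_split(study_cohort):
    return sp.split_sample(study_cohort, 0.25, seed=SPLIT_SEED)
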