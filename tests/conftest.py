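"""Shared fixtures: feature tables built once per session from stock cohorts."""

import numpy as np
import pytest
from hypothesis import settings

from exgauss_workload import (
    default_workload_config,
    dominant_feature_config,
    generate_cohort,
    null_config,
    strongly_separated_config,
)
from exgauss_workload.features import build_dataset
from exgauss_workload.pipeline import feature_table_for

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def wk_table():
    """Feature table from the default workload cohort (30 subjects, 90 rows)."""
    return feature_table_for(default_workload_config, 14)


@pytest.fixture(scope="session")
def null_table():
    """Feature table from a no-signal cohort (identical level generators)."""
    return feature_table_for(null_config, 11)


@pytest.fixture(scope="session")
def sep_table():
    """Feature table from the strongly separated cohort."""
    return feature_table_for(strongly_separated_config, 12)


@pytest.fixture(scope="session")
def dom_table():
    """Feature table from the dominant-feature cohort (tau of response time)."""
    return feature_table_for(dominant_feature_config, 13)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-subject workload cohort for cheap structural tests."""
    return generate_cohort(default_workload_config(master_seed=42, n_subjects=6))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return build_dataset(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
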